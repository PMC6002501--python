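"""Parametric electrode-in-box solid geometry.

The study system is a planar multi-contact stimulation electrode (thin
platinum pads embedded in a silicone sheet) centred in a grounded conductive
box of muscle-conductivity medium.  Everything downstream (meshing, field
solves, axon placement) is derived from the axis-aligned solid model built
here; nothing is read from disk.

Coordinate convention (documented once, used everywhere): the substrate top
surface lies in the ``z = 0`` plane at the box centre, contacts are exposed
toward ``+z``, contact centres lie on the x axis (bipolar) or on a 2x2 grid
in the x-y plane (multipolar).  All lengths are millimetres; the field
solver converts to SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import yaml

__all__ = [
    "ElectrodeSpec",
    "BoxSpec",
    "GeometryModel",
    "GeometryError",
    "build_geometry",
    "bipolar_spec",
    "multipolar_spec",
]


class GeometryError(ValueError):
    """Raised for invalid or mutually inconsistent geometric specifications."""


Box = Tuple[float, float, float, float, float, float]  # x0,x1,y0,y1,z0,z1


@dataclass(frozen=True)
class ElectrodeSpec:
    """Planar electrode: rectangular contacts embedded in an insulating sheet.

    Defaults reproduce the bipolar rat-scale paddle: two 1.5 x 1 x 0.025 mm
    platinum contacts at 2 mm centre-to-centre pitch in a 5 x 5 x 0.05 mm
    silicone substrate.
    """

    contact_length: float = 1.5          # mm, along x
    contact_width: float = 1.0           # mm, along y
    contact_thickness: float = 0.025     # mm, along z
    contact_pitch: float = 2.0           # mm centre-to-centre
    n_contacts: int = 2                  # 2 (bipolar) or 4 (2x2 grid)
    substrate_length: float = 5.0        # mm, along x
    substrate_width: float = 5.0         # mm, along y
    substrate_thickness: float = 0.05    # mm
    contact_profile: str = "flush"       # "flush" | "raised_half"
    workplane_seams: bool = True         # internal insulating planes between contacts

    def __post_init__(self) -> None:
        if self.n_contacts not in (2, 4):
            raise GeometryError("n_contacts must be 2 or 4")
        if self.contact_profile not in ("flush", "raised_half"):
            raise GeometryError(f"unknown contact_profile {self.contact_profile!r}")
        if self.contact_thickness <= 0 and self.contact_profile == "raised_half":
            raise GeometryError("raised profile requires positive contact thickness")
        if self.contact_thickness > self.substrate_thickness:
            raise GeometryError("contact_thickness must not exceed substrate_thickness")
        # contacts must fit inside the substrate footprint with positive margin
        if self.n_contacts == 2:
            x_extent = self.contact_pitch + self.contact_length
            y_extent = self.contact_width
        else:
            x_extent = self.contact_pitch + self.contact_length
            y_extent = self.contact_pitch + self.contact_width
        if x_extent >= self.substrate_length or y_extent >= self.substrate_width:
            raise GeometryError("contacts do not fit inside the substrate footprint")
        gap = self.contact_pitch - self.contact_length
        if gap <= 0:
            raise GeometryError("contacts overlap: pitch must exceed contact length")

    @property
    def raise_height(self) -> float:
        """Protrusion above the substrate surface (mm); half the thickness."""
        return self.contact_thickness / 2 if self.contact_profile == "raised_half" else 0.0

    def contact_centers(self) -> List[Tuple[float, float]]:
        h = self.contact_pitch / 2
        if self.n_contacts == 2:
            return [(-h, 0.0), (h, 0.0)]
        return [(-h, -h), (h, -h), (-h, h), (h, h)]

    def exposed_area_per_contact(self) -> float:
        """Area (mm^2) of the contact surface in electrical contact with the medium."""
        top = self.contact_length * self.contact_width
        if self.contact_profile == "flush":
            return top
        perim = 2 * (self.contact_length + self.contact_width)
        return top + perim * self.raise_height


@dataclass(frozen=True)
class BoxSpec:
    """Grounded conductive box containing the electrode."""

    edge_length: float = 20.0                    # mm
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def bounds(self) -> Box:
        cx, cy, cz = self.center
        h = self.edge_length / 2
        return (cx - h, cx + h, cy - h, cy + h, cz - h, cz + h)

    def outer_surface_area(self) -> float:
        return 6 * self.edge_length**2


@dataclass
class GeometryModel:
    """Solid model: named axis-aligned volumes plus seam-plane definitions.

    ``contact_boxes[k]`` is the k-th contact volume; ``seam_planes`` are the
    internal insulating workplane definitions (axis, coordinate) that split
    the substrate between contacts.
    """

    electrode: ElectrodeSpec
    box: BoxSpec
    substrate_box: Box = field(init=False)
    contact_boxes: List[Box] = field(init=False)
    seam_planes: List[Tuple[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        e = self.box.bounds
        el = self.electrode
        sub = (
            -el.substrate_length / 2, el.substrate_length / 2,
            -el.substrate_width / 2, el.substrate_width / 2,
            -el.substrate_thickness, 0.0,
        )
        if not (e[0] < sub[0] and sub[1] < e[1] and e[2] < sub[2] and sub[3] < e[3]
                and e[4] < sub[4] and sub[5] < e[5]):
            raise GeometryError("electrode is not fully contained in the box")
        self.substrate_box = sub
        zt = el.raise_height                       # top of contact
        zb = zt - el.contact_thickness             # bottom of contact
        self.contact_boxes = [
            (cx - el.contact_length / 2, cx + el.contact_length / 2,
             cy - el.contact_width / 2, cy + el.contact_width / 2, zb, zt)
            for cx, cy in el.contact_centers()
        ]
        for b in self.contact_boxes:
            if not (sub[0] < b[0] and b[1] < sub[1] and sub[2] < b[2] and b[3] < sub[3]
                    and sub[4] < b[4]):
                raise GeometryError("contact volume escapes the substrate")
        if el.workplane_seams:
            self.seam_planes = [("x", 0.0)]
            if el.n_contacts == 4:
                self.seam_planes.append(("y", 0.0))
        else:
            self.seam_planes = []

    # --- exact volumes used as oracles by the mesh module -----------------
    def contact_volume(self, k: int) -> float:
        b = self.contact_boxes[k]
        return (b[1] - b[0]) * (b[3] - b[2]) * (b[5] - b[4])

    def substrate_volume(self) -> float:
        s = self.substrate_box
        vol = (s[1] - s[0]) * (s[3] - s[2]) * (s[5] - s[4])
        # subtract the embedded part of each contact
        for b in self.contact_boxes:
            depth = min(b[5], s[5]) - b[4]
            vol -= (b[1] - b[0]) * (b[3] - b[2]) * depth
        return vol

    def medium_volume(self) -> float:
        total = self.box.edge_length**3
        raised = sum(
            (b[1] - b[0]) * (b[3] - b[2]) * max(b[5], 0.0) for b in self.contact_boxes
        )
        s = self.substrate_box
        sub_total = (s[1] - s[0]) * (s[3] - s[2]) * (s[5] - s[4])
        return total - sub_total - raised

    def region_volumes(self) -> dict:
        out = {"medium": self.medium_volume(), "substrate": self.substrate_volume()}
        for k in range(self.electrode.n_contacts):
            out[f"contact_{k}"] = self.contact_volume(k)
        return out

    def to_yaml(self) -> str:
        d = {
            "electrode": {k: getattr(self.electrode, k) for k in (
                "contact_length", "contact_width", "contact_thickness",
                "contact_pitch", "n_contacts", "substrate_length",
                "substrate_width", "substrate_thickness", "contact_profile",
                "workplane_seams")},
            "box": {"edge_length": self.box.edge_length,
                    "center": list(self.box.center)},
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeometryModel":
        d = yaml.safe_load(text)
        ebox = d.get("box", {})
        return build_geometry(
            ElectrodeSpec(**d["electrode"]),
            BoxSpec(edge_length=ebox.get("edge_length", 20.0),
                    center=tuple(ebox.get("center", (0.0, 0.0, 0.0)))),
        )


def build_geometry(electrode: ElectrodeSpec, box: BoxSpec) -> GeometryModel:
    """Validate the specs and assemble the solid model."""
    return GeometryModel(electrode=electrode, box=box)


def bipolar_spec(contact_profile: str = "flush",
                 workplane_seams: bool = True) -> ElectrodeSpec:
    """The study's two-contact paddle."""
    return ElectrodeSpec(contact_profile=contact_profile,
                         workplane_seams=workplane_seams)


def multipolar_spec() -> ElectrodeSpec:
    """The 2x2 four-contact extension on a 10 x 5 mm substrate."""
    return ElectrodeSpec(n_contacts=4, substrate_length=10.0, substrate_width=5.0)
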