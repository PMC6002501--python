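# Methods

`stimfem` re-implements, as one tested pipeline, a comparison of the ways a
metal stimulating electrode can be represented in a volume-conductor finite
element model, measured by what each representation does to the activation
thresholds of model axons. This note records the models, the numerical
choices, and what the defaults do and do not emulate.

## The conduction problem

Tissue is treated as a purely resistive volume conductor: at every instant
the extracellular potential satisfies `div(sigma grad V) = 0` (quasi-static
approximation; capacitive and dispersive tissue behaviour and the
electrode–tissue interface are out of scope). The study system is a planar
two-contact paddle electrode — 1.5 × 1 × 0.025 mm platinum contacts at 2 mm
centre-to-centre pitch, embedded flush in a 5 × 5 × 0.05 mm silicone sheet —
centred in a 20 mm grounded cube of muscle-conductivity medium. A 2 × 2
four-contact variant extends the sheet to 10 × 5 mm. Conductivities:
silicone 1e-12 S/m, medium 0.2 S/m, platinum 9.43e6 S/m.

Four source representations are implemented:

* **PCS** — point current source: a shape-function-weighted delta load at
  the contact-volume centre (must sit inside a conductive domain);
* **BCS** — boundary current source: uniform inward Neumann density
  `I / exposed_area` over the exposed contact faces (top face for flush
  contacts; top plus four 12.5 µm side strips for raised contacts);
* **FP** — floating potential: all exposed-surface degrees of freedom tied
  to one auxiliary unknown (exactly isopotential) delivering a prescribed
  net current;
* **EP** — electric potential: Dirichlet 1 V on the contact surface,
  rescaled exactly by the measured delivered current (linearity makes the
  two-solve calibration a single solve).

Inactive contacts carry a condition of continuity (floating) or, for the
"Superposition B" comparison, a ground. Insulating surfaces — the
substrate–medium boundary and the internal "workplane" plane that splits
the substrate between contacts — are represented as mesh *cracks*
(duplicated vertices), which model a perfect insulator exactly and can be
re-tied per case without re-meshing.

## Meshing

The geometry is meshed by laying a graded tensor-product grid whose tick
planes contain every material interface, then splitting each hexahedral
cell into six conforming tetrahedra. Elements are quadratic (P2) by
default. Resolution profiles set the in-plane edge over the electrode
footprint and (finer) over the contact zone, the vertical edge above the
contact plane and (finer) through the closest axon plane, the wall edge,
and the growth rate. `default`
(`h_contact = 0.17, h_plane = 0.55, h_z_near = 0.026, h_z = 0.08,
h_wall = 1.7 mm, growth = 0.7 /mm`; ~2.6×10⁵ tetrahedra full-domain) is
chosen so that (a) the thin contact domains keep at least two element
layers through their 25 µm thickness and (b) all nine activation thresholds
change <1 % under ~2.3× element refinement (`fine`) and under doubling the
outer-domain volume. A dedicated `audit` profile weights resolution toward
the grounded walls and the contact fringe instead — that is where direct
current-density integrals converge — and is used for the delivered-current
verification suite. `coarse` and `tiny` exist for tests of properties that
are exact at any resolution. One mesh is built per geometry family (flush,
raised, no-thin-domain, four-contact) and reused verbatim across all
boundary-condition cases of that family, so threshold differences between
such cases cannot come from the mesh.

Every two-contact case in the shipped matrices is mirror-symmetric about
the y = 0 plane (contacts centred on the x axis, fibers at y = 0), so
those cases are solved on the y ≥ 0 half domain with a natural symmetry
plane at y = 0; prescribed currents are halved internally and measured
currents doubled back, leaving potentials and all reported quantities on
the full-model scale (verified against full-domain solves). Four-contact
grids use the full domain because their single-contact unit solves break
the symmetry.

## Linear solver

The assembled system spans 19 orders of magnitude in conductivity
(silicone to platinum). It is symmetrically diagonal-scaled and solved by
conjugate gradients with a symmetric two-level V(1,1) preconditioner:
Chebyshev(4) smoothing plus an exact SuperLU solve of the Galerkin-projected
vertex (P1) subproblem under a geometric nested-dissection ordering.
Critically, the coarse basis is augmented with the indicator vectors of
each connected high-conductivity (platinum) component and each floating
silicone block: these are the near-null-space modes the contrast creates,
and without deflating them CG diverges. Small systems are factorised
directly. The solve is deterministic; tolerance 1e-10 on the preconditioned
residual plus one polishing restart.

## Delivered-current audits

The delivered current is recovered four ways: (1) direct quadrature of
`-sigma grad V . n` over the grounded outer boundary, (2) the same integral
spelled component-wise, (3) the reaction forces (constrained-row residuals,
which satisfy discrete conservation exactly), and (4) the flux through an
axis-aligned box beyond the contact. The box margin defaults to 0.5 mm
rather than something tighter because the contact edge carries an
inverse-square-root current-density singularity; a surface inside that
fringe integrates noisy recovered fluxes, and the verification suite
evaluates the box at 2 mm on the `audit` profile, where the four methods
agree within 0.5 % (the box needs a full-domain mesh — on a half model its
surface would pass through the on-plane point source). The fifth figure —
the direct integral over the contact surface itself — is a known
under-estimator at desk-scale resolution (≈0.7 of the true current,
converging from below under refinement); the audit reports it as the
deliberately-included "what a naive check would give" column, mirroring the
failure mode this integral is known for, and it is excluded from the 0.5 %
agreement contract of the four accurate methods.

## Axon model

Fibers are MRG-type double-cable myelinated axons, 20 mm long, at 2, 5.7
and 10 µm fiber diameter, placed parallel to the contact axis at 0.05, 0.75
and 2 mm above the contact plane and centred on the array midpoint (a node
of Ranvier sits at the midpoint; for 2 and 5.7 µm a node also falls exactly
over a contact centre). Each internode comprises 2 MYSA, 2 FLUT and 6 STIN
compartments; nodes carry fast Na, persistent Na and slow K channels plus
leak; internodal axolemma is passive; myelin is a linear RC (per-lamella
0.1 µF/cm² and 0.001 S/cm², two membranes per lamella) in series with an
explicit periaxonal space. Geometric and electrical parameters follow the
published tables for 5.7–16 µm. Two in-package choices:

* **2 µm entry.** The published table stops at 5.7 µm and linear
  extrapolation turns unphysical (negative internodal length). The 2 µm
  row uses the ~100 × diameter internodal-spacing rule (200 µm) with
  calibres and lamellae count continuing the table's trends
  (axon 1.2 µm, node 0.7 µm, 10 µm juxtaparanode, 30 lamellae). The
  geometry object is flagged `extrapolated`.
* **Fiber tiling.** A 20 mm fiber is not an integer (odd-node) multiple of
  every internodal spacing; the internode count is rounded to the nearest
  even integer and the six STIN lengths stretched uniformly so the chain
  tiles 20 mm exactly with a node at the midpoint (exact for 5.7 and 2 µm;
  the 10 µm internode becomes 1111 µm instead of 1150 µm).
* **h-gate calibration.** With the transcribed rate functions
  (q10-corrected to 36 °C) the assembled cable conducts decrementally
  (safety factor just below one) even though the isolated node fires full
  action potentials and the wave speed matches the published ~36 m/s at
  5.7 µm — verified with two independent integrators (the package's
  backward-Euler scheme and a dense stiff-ODE oracle). The package
  therefore scales both h rate constants by 0.5 (τ_h doubled, steady-state
  h unchanged), which restores constant-amplitude regenerative conduction
  at the published velocity and leaves the resting state unchanged. All
  reported quantities are *relative* threshold errors between field
  configurations at fixed fiber placement, which are insensitive to this
  calibration (`MembraneParameters.h_rate_scale` exposes it).

Extracellular coupling applies the sampled unit-field potential (1 mA
solution, scaled linearly by the stimulus amplitude) at each compartment
centre. Integration is backward Euler with Rush–Larsen gating on a
pentadiagonal double-cable system: dt = 2 µs during the 200 µs/phase
cathodic-first biphasic pulse and 10 µs afterwards, 5 ms total; halving dt
moves thresholds by <1 µA. Before stimulation each fiber is relaxed for
50 ms to its true resting equilibrium (the nominal −80 mV with steady-state
gates carries a small residual drift). Activation is an upward 0 mV
crossing of the membrane potential at sentinel nodes three nodes from
either fiber end, excluding stimulation- and termination-site artifacts.
During threshold searches a run ends as soon as the activation decision is
certain: at the crossing itself, or — for subthreshold runs — once 2.5 ms
have passed with every node below −45 mV (the sentinel crossing occurs
within 1.3 ms at threshold in the slowest configuration, so the trajectory
can only decay from there); full-duration integration is used whenever a
trajectory is recorded.

## Threshold search and error statistics

Thresholds are found by doubling an initial 1 mA upper bound until
suprathreshold (declaring "unexcitable" beyond 1 A), then bisecting to 1 µA
and reporting the smallest tested suprathreshold amplitude (ceiling
convention, fixed for bit-for-bit reproducibility). Case errors are
absolute percent deviations from the gold standard (thin platinum contacts,
silicone substrate, point source), summarised as mean ± sample SD over the
nine diameter × distance combinations; the source text does not state
signed versus absolute, and absolute matches its uniformly positive values.
The mesh-convergence metric alone bisects to 1/16 µA, because a <1 % change
in a ~16 µA threshold is invisible at the 1 µA reporting resolution.

## What the defaults do and do not emulate

The generator reproduces the study conditions exactly: box, sheet and
contact dimensions, conductivities, the case matrices, the stimulus, the
fiber set and distances. It does not model image-derived anatomy
(spinal cord, brain), cylindrical leads, recessed contacts, the
electrode–tissue interface impedance, or the commercial-solver anomalies
the study reports (the spurious grounding of the inactive contact under an
EP source in the all-platinum scheme, and the 0.42 mA contact-surface
integral); cases exercising those anomalies are flagged
`known_solver_artifact` in the shipped tables and excluded from equivalence
checks. Absolute thresholds differ from the original COMSOL + NEURON stack
(different discretisations on both sides of the coupling); all acceptance-
bearing quantities are relative errors, which the passing tests show to be
robust at desk scale — they do not validate absolute thresholds against
experiment.

## Known limitations

* The raised-versus-flush contact comparison yields a mean threshold
  difference of about 1 % here. Published figures for this comparison are
  larger with a standard deviation as large as the mean, consistent with
  adaptive re-meshing contributing discretisation noise of the same order
  as the physical effect; this mesher adds a single tick plane for the
  raised geometry and keeps everything else identical, so the difference
  reported is almost purely physical — and accordingly smaller.

* Direct boundary-flux quadrature at the default profile recovers ~99.5 %
  of the delivered current (the reaction method is exact); reaching 0.1 %
  with direct quadrature would need far finer wall resolution than the
  desk-scale budget.
* The contact-surface direct integral is structurally inaccurate at any
  desk-scale resolution (edge singularity) and is reported as a diagnostic,
  not used for verification.
* The h-gate calibration above means the nodal kinetics are not a verbatim
  transcription; chronaxie-sensitive absolute quantities inherit that
  choice.
* The periaxonal space widths (2–4 nm) make the double cable stiff; the
  implicit integrator handles this, but explicit integration of the model
  is impractical.
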