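# Methods

`rbc_cbmm` simulates a pair of deformable red blood cells (an RBC doublet)
whose adhesion is mediated by fibrinogen cross-bridges, including a mobile
cross-bridge population whose surface density is transported over each cell
membrane. This note records the model equations as implemented, the
numerical scheme, the desk-scale (scaled-down) conditions, and the design
choices made where the problem was genuinely open.

## Membrane model

Each cell is a closed triangulated surface (default: a biconcave discocyte
of diameter 7.8 um built from a Fibonacci point set; surface area ~133 um²,
volume ~93 um³). The reference geometry recorded at construction is the
stress-free state. The strain energy has four parts:

* **Cytoskeleton shear** — worm-like-chain springs with a power-law
  repulsive core on every edge (maximum extension ratio l_max/l0 = 2.2,
  repulsion exponent 2). Per-edge coefficients are set from the resting
  shear modulus Es0 = 6.54 uN/m through the standard small-strain relation
  for a hexagonal spring network, so the network reproduces Es0 regardless
  of mesh resolution.
* **Bending** — dihedral-angle energy k_b (1 − cos(θ − θ0)) per edge with
  k_b = 2 E_b / √3, E_b = 2.4e-19 J; θ0 is the as-built dihedral (the
  discocyte is the minimum of the bending energy).
* **Area penalties** — quadratic penalties on total area (ka = 0.288 N/m)
  and per-triangle area (kd = 0.144 N/m). The effective area
  compressibility K0 = 2 Es0 + ka + kd = 0.432 N/m is validated at
  configuration load.
* **Volume penalty** — U = kΩ (V − V0)² / (2 V0) with kΩ = 220. The
  printed unit of kΩ is inconsistent with any quadratic volume penalty by
  one length exponent; we read it as J/m³ (= N/m²), the only reading that
  makes the standard penalty dimensionally correct.

Membrane viscosity enters as pairwise dissipative forces on edges,
F = −η_T v_ij − η_C (v_ij·ê)ê, with η_m = √3 η_T + √3 η_C/4 and
η_C = η_T/3 (hence η_T = 12 η_m /(13√3)), η_m = 0.7 uN·s/m. The printed
source relation is typographically ambiguous; this reading is the standard
one in the dissipative-particle membrane literature and the alternative
plain reading is switchable (`eta_relation="plain"`).

## Adhesion and friction

Adhesion is a Morse-type potential per vertex,
U_i = Γ [e^{2β(r0−r)} − 2 e^{β(r0−r)}] A_i for r ≤ r_cutoff (well depth
Γ·A_i at the zero-force separation r0), with A_i the median-dual area.
The signed force along the approach direction is the energy derivative,
F_i = Γ A_i 2β [e^{β(r0−r)} − e^{2β(r0−r)}] (positive = attraction),
applied along the
vertex-to-vertex direction for specific bridges (VTV) and along the
normal-distance direction to the nearest element for non-specific bridges
(VTS). The total affinity composes as Γ_affin = Γ_iFgR + Γ_iFg +
(N1 + N2)·Γ_mFg, where N1, N2 are the mobile-Fg densities of the two
surfaces; with Γ_mFg = 0 the model reduces to the uniform affinity model
(UAM). Pathophysiological states scale the equilibrium density (N*) and
the per-density affinity (Γ*): Γ_affin = Γ_iFg + N*(N_b1+N_b2)Γ*Γ_mFg,b.

Each cell's vertices carry their own Morse force against the pairing
surface. To conserve linear momentum exactly, the implementation evaluates
both one-sided interactions (source-vertex force plus a barycentric
reaction on the nearest pairing element) and averages the two; for nearly
parallel surfaces this equals the per-vertex force on both cells while
keeping the pair's total momentum change at rounding level.

Intercellular friction assumes a Couette profile of gap plasma
(μ_gap = 3.6 cP) between the glycocalyx-reduced surfaces: per interacting
vertex the tangential relative velocity is opposed by
μ_gap A_i v_t / (r_sep − 2 r_glyco), r_glyco = 5 nm. As printed the
friction expression has units of stress; multiplying by the median-dual
area (like every other per-vertex interaction) yields the nodal force. The
gap denominator is clamped below at 1 nm (configurable) to avoid a
singularity at contact; friction is applied only within the adhesion
cutoff, where a gap flow is defined.

## Mobile-Fg transport

The normalized mobile-bridge density N obeys
dN/dt = D ∇²N − ∇·(V_drift N) + S_adsorp on each deforming membrane,
solved in the material frame (mesh vertices are Lagrangian markers, so
only the drift relative to the surface convects N). V_drift is
friction-induced sliding of adsorbed mFg:
0.5 (V_neighbor − V_surface)(δ_Fg − δ_gap)/δ_Fg for gaps smaller than the
mFg hydrodynamic size δ_Fg = 45 nm, zero otherwise, projected onto the
tangent plane. The adsorption source S = J_constant + J_diffus acts on
exposed surface (r_sep ≥ δ_Fg) and vanishes identically at the equilibrium
density N0. Note that the two printed fluxes combine algebraically to
S = D (N0 − N)/(1.4 δ_Fg)², independent of the surface-to-bulk ratio φ0;
the implementation keeps the printed two-term form.

Discretization: finite volumes on the median-dual cells with a
cotangent-weighted Laplacian (negative weights clamped to zero to preserve
the maximum principle) and first-order upwind fluxes across dual edges for
the drift. Fluxes are antisymmetric, so total amount Σ N_i A_i is
conserved to rounding with the source off; the step sub-cycles internally
to respect the explicit positivity bound. Area change of the control
volumes transports amount (N·A_i), with N recovered by dividing by the
updated area.

## Time integration and the quasi-static regime

Vertices follow Newton's second law with semi-implicit (symplectic) Euler:
the velocity is updated from the total force, then the position moves with
the updated velocity. The vertex mass is fictitious: the protocols are
quasi-static (loading at 0.15 um/s), so the physical inertia of a cell is
irrelevant and the mass is chosen purely so that the explicit integration
is stable at a workable step while the inertial response time m/c (c the
local damping from membrane viscosity and gap friction) stays far below
every protocol timescale (~0.2 s against 20-40 s windows). Overdampedness
is verified empirically: halving the mass or the step leaves formation
kinematics unchanged.

Two numerical conditioning choices make this regime reachable with an
explicit integrator:

* the area penalties are scaled by `penalty_scale` (default 1e-3) in the
  force evaluation. At the ~1 uN/m tensions the protocols generate, the
  scaled penalties still hold area strains near 1e-2 %, two orders below
  the 2% drift tolerance, while reducing the stiffest mode by 1000x;
* `stable_dt` bounds the step by both the stiffest edge spring and the
  explicit damping limit of the edge dashpots.

Measured drifts over full protocol runs are ≤ 0.1% in volume and area.

Measured desk-scale outcomes at these conditions: the formation-rate
ladder at total affinities 0.5/1.0/1.5 uJ/m² gives 0.11/0.17/0.22 um/s —
strictly increasing, with the same pairwise ratios as the ~0.2-0.4 um/s
rates observed for doublet formation in plasma but uniformly about 0.6x
their magnitude, a contact-line resolution effect (the rates climb from
642- to 842-vertex meshes; at 1000 vertices metastable arrests distort the
80%-of-final metric).  The disaggregation contrast at 642 vertices: the
uniform-affinity run peaks near 24 pN and declines (stage II) to
separation; the low-diffusivity mobile-bridge run accumulates gap density
(N_ave 2 → 6+) and peaks near 28 pN, inside the published 29 ± 3 pN trap
escape band; the high-diffusivity run collapses onto the uniform-affinity
curve within 10% of peak.

## Protocols

**Formation.** Two discocytes start in near point contact at the
zero-force separation and evolve with no external load. The second cell is
tilted 25° about the axis perpendicular to the sliding direction with its
center offset 0.85 diameters, so the two faces meet in a "V" that can
close by face-on-face zipping — the configuration from which spontaneous
sliding growth (the experimentally observed sliding phase) proceeds. From
an untilted stacked contact at this resolution the contact is confined to
the rim annulus and the doublet arrests in a metastable partial overlap;
the tilted start removes that lattice artifact. The readouts are the
silhouette-overlap length along the sliding axis and the adhesive contact
area (Σ A_i within the cutoff, averaged over the cells). The formation
rate is the overlap growth from the start to 80% of the final (maximum)
overlap divided by the time to reach it.

**Disaggregation.** A crescent doublet (70% diameter overlap in the study
runs, representing doublets formed to equilibrium; at 50% the early
response is pure reorientation without interface slip and mobile bridges
cannot accumulate before the contact depletes) is relaxed briefly, then distal vertex patches (2% of the area at each far end) are
displaced kinematically at 0.15 um/s in opposite directions along the
sliding axis. The trap tension F_OT is the total constraint reaction on a
patch (averaged over each sampling interval); the axial adhesion force and
the average gap bridge density N_ave (area-weighted sum of both surfaces'
densities over in-contact vertices) are recorded against the applied
displacement. Runs end at complete separation or at a configured escape
threshold. Stage segmentation splits the smoothed force-displacement curve
at its global maximum (stage I rising, stage II declining).

## Scaled-down (desk-scale) conditions

Reference resolution is ~5000 vertices per cell (mean adhesion-vertex
spacing ~183 nm, matching the receptor-density argument for ~200 nm).
Desk-scale runs use 842-vertex cells with 24 s windows for the
formation-rate ladder and 642-vertex cells with 40 s windows for
disaggregation (pathophysiology ordering at 442 vertices and 14 s). Because contact
growth proceeds by a zipping front that must capture the next vertex ring
within the Morse reach, coarse meshes stretch `r_cutoff` and the decay
length 1/β by the spacing ratio (`resolution_scaled`); the affinity
(energy per area), the zero-force separation and all friction constants
are untouched, so energetics and the Couette gap physics are preserved and
the transformation is the identity at reference resolution.  The same
spacing ratio stretches the mobile-Fg gap-law size δ_Fg (drift weight and
adsorption switch), since the separation distribution inside the contact
dilates with the Morse width.  The reach scaling applies to the
surface-based VTS interaction only: for VTV the ratio of cutoff to
receptor (vertex) spacing is itself the modeled physics — sparse receptors
beyond reach cannot recruit — so specific-bridge runs keep the physical
100 nm cutoff.

What desk-scale passing shows — and what it does not: the scaled runs
reproduce the composition algebra exactly, the formation-rate ordering and
magnitudes approximately, and the qualitative UAM/CBMM disaggregation
contrast. They do not resolve the contact rim at the receptor spacing, and
absolute peak forces carry O(20-30%) resolution sensitivity.

## Known limitations

* No bulk fluid: all dissipation is membrane viscosity plus intercellular
  friction, as in the source model.
* Cross-bridge formation/cleavage kinetics are not modelled; the effective
  mobile-Fg diffusivity absorbs them.
* The VTV pairing is recomputed each step (nearest vertex), not a
  persistent bond list.
* Single constant pulling rate; no shear-flow or multi-cell protocols.
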