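# Methods

## Host frame and descriptor conventions

All binding-geometry descriptors are measured against one frame per
structure, anchored on the ring of glycosidic oxygens of the cyclodextrin:

* **Origin** — the unweighted centroid of the glycosidic oxygens. They are a
  geometric plane anchor, so no mass weighting is applied; the *guest*
  centre of mass is mass-weighted (standard atomic masses; an unknown
  element symbol is an error rather than a silent unit-mass fallback).
* **z-axis** — the least-squares plane normal of the glycosidic oxygens
  (smallest singular vector of the centred coordinates), sign-fixed to point
  from the secondary-rim (O2/O3) oxygen centroid toward the primary-rim
  (O6) centroid. The x-axis points toward unit 1's glycosidic oxygen
  projected into the plane; y completes a right-handed frame.
* **Signed COM distance** *d* — magnitude is the guest-COM-to-origin
  distance; the sign is negative exactly when the guest COM is farther from
  the primary-rim oxygen centroid than from the secondary-rim one (guest on
  the secondary side). The tie (equidistant, e.g. a guest at the origin of a
  symmetric host) is reported as +0.
* **Orientation** *θ* — the angle in [0°, 180°] between the user-designated
  B→A guest atom vector and +z. Which two guest atoms define the vector is
  deliberately an explicit input (`SelectionSpec.guest_vector`): no
  heuristic guess would survive contact with arbitrary guests.
* **Tilt** *τ* — per glucose unit, a least-squares plane is fitted to the
  six heavy pyran-ring atoms (O5, C1–C5; hydrogens are not used). The ring
  normal is oriented to have a non-negative component along the unit's
  outward radial direction (ring centroid − origin, projected into the
  frame plane), and τ is the angle between that normal and +z. A stave of a
  perfect cylinder gives τ = 90°; values below 90° mean the secondary rim
  opens outward, values above it mean the unit leans secondary-rim-edge
  inward. This radial orientation is what keeps τ on a single (0°, 180°)
  branch — a plain plane–plane angle would fold at 90° and could not
  represent ensembles straddling it.
* **Circularity** — project the glycosidic oxygens into the frame plane,
  take the 2×2 covariance (population normalisation; the eigenvalue *ratio*
  is normalisation-independent), and report sqrt(λ_min/λ_max): the axis
  ratio of the best-fit ellipse, 1 for a perfect circle. Published uses of
  the distortion parameter do not print a formula; this form is
  affine-sensible and matches the "1 = perfectly circular" convention, but
  agreement with other codes' third decimal is not guaranteed.
* **Hydrogen bonds** — donors are O/N atoms with an H within 1.2 Å in the
  same fragment; acceptors are O/N of the opposite fragment; a donor–acceptor
  pair counts once (both donation directions are scanned) when D–A ≤ 3.5 Å
  and the H–D–A angle ≤ 30°. These defaults mirror the common
  MD-toolchain criteria and are configurable; counting requires explicit
  hydrogens and errors otherwise.
* **Binding mode** — UNBOUND when |d| > 6.5 Å (the cutoff that separates
  the bound peak from dissociated excursions in COM-distance
  distributions), otherwise BS for θ < 90° and BP for θ ≥ 90°. The exact
  90° tie breaks to BP so the classifier is total; the case has measure
  zero.

The host reference point is the glycosidic-oxygen centroid rather than the
whole-host COM; for cyclodextrins the difference is sub-Ångström, and the
oxygen-ring construction is the analysis definition of the cavity axis.

## Topology detection

Glucose units are residues containing the six pyran-ring atom names;
glycosidic oxygens are O4 atoms bridging C1 of one residue and C4 of
another within a 1.8 Å covalent-distance criterion (used when bond records
are absent — extracted ligands usually lack them). The bridging links must
form a single cycle over all units; units are numbered by traversing that
cycle from the lowest residue index in the direction of increasing indices,
giving a deterministic labelling. Ambiguous bridging or a unit count
outside {6, 7, 8} raises an error that points at the explicit-hints escape
hatch, and hints always win verbatim.

## Trajectory statistics

Histograms are density-normalised (default widths 0.25 Å for distances, 5°
for angles — published distributions are smooth at roughly this
resolution; both configurable). Uncertainties come from block averaging:
the series is cut into `n_blocks` equal contiguous blocks (default 5, a
conventional choice; the remainder is dropped from the end) and the sample
SD of the block means is reported. Mode occupancies are
permutation-invariant; transition counts, deliberately, are not. The
frame-subsampling helper's default cadence (1001 frames at 10 ps) matches
the usual end-state-analysis extraction window and is a preset, not a
hard-coded rule.

## EDA-FF

The inter-fragment energy is summed over all atom pairs with no cutoff and
no exclusions — the fragments are distinct molecules. The Coulomb constant
is Amber's 332.0522 kcal·Å/(mol·e²) (the parameter sets this package is
aimed at are Amber-family; the alternative CODATA-style 332.0637 changes
host–guest totals by well under 0.1 kcal/mol). LJ combination follows the
Amber convention ε_ij = sqrt(ε_i ε_j), Rmin_ij = Rmin_i/2 + Rmin_j/2. The
attractive term carries the factor 2 of the standard
ε[(Rmin/r)¹² − 2(Rmin/r)⁶] form, so that the pair potential reaches its
minimum −ε at exactly Rmin — a form without that factor (available via
`literal_lj=True` for sensitivity checks) would vanish at Rmin instead,
contradicting Rmin's definition as the potential minimum. RESP2-style
charge blending is q = δ·q_water + (1−δ)·q_gas with δ = 0.5 by default.

Charges and LJ parameters are always inputs: ESP fitting (MK, CHELPG,
RESP) and force-field assignment are upstream tools' jobs.

## sobEDAw recombination

Given component energies (els, x, rep, orb, dftc, dc), the weight
ω = exp[−r(dc/els − a)](1−c) + c moves a dc/els-dependent fraction of the
DFT correlation energy into the dispersion term:

    E_xrep = (x + rep) + (1 − ω)·dftc
    E_disp = dc + ω·dftc

E_xrep + E_disp is independent of (r, a, c) — ω only re-apportions — and
the interaction energy is the ω-free six-term sum. The only built-in
(r, a, c) preset is (2.571, 0.071, 0.575) for B3LYP-D3(BJ)/6-31+G(d,p);
other levels of theory need user-supplied parameters because the weights
are fitted per level. ω is undefined for els = 0 and errors. The
binding-free-energy ledger G_bind = E_int + (def_H + def_G) +
(polar + nonpolar) + G_corr is pure bookkeeping; phase labels (gas/water)
carry no physics.

## MM–PBSA ledger

E_bind = (E_bonded,H + E_bonded,G) + E_vdW + E_elec + G_polar + G_nonpolar.
The entropy term −TΔS is an explicit optional field defaulting to absent;
without it the result is labelled a binding *energy* (e_bind) and never a
free energy — the two are not conflated. Per-frame series inputs get
block-averaged SDs. Polar/nonpolar solvation terms are consumed as numbers;
no PB or SASA solver is included.

## Bundled tables and consistency checking

The three published component tables for the α/β/γ-CD:DOPO complexes ship
as plain CSV and are treated as one-decimal-rounded inputs. The
consistency checker recomputes every printed aggregate from its printed
*immediate* inputs (e.g. E_bind from the printed E_MM and G_sol, G_bind
from the printed E_int, def, and sol) so a rounding deviation low in the
ledger does not cascade upward, and classifies deviations: ≤ 0.05 kcal/mol
passes, ≤ 0.15 kcal/mol is flagged as rounding of an unrounded sum (several
cells in the MM–PBSA and sobEDAw tables re-sum 0.1 off their printed value,
e.g. the α-CD BS E_MM and the α-CD BS gas interaction energy), and larger
deviations fail. The γ-CD water columns of the EDA-FF table genuinely fail
additivity — elec + rep + disp misses the printed total by −1.8 kcal/mol
(BS rows) and +0.9/1.0 (BP rows) uniformly across all five charge methods,
which points at a mistranscribed shared repulsion or dispersion entry — and
the checker reports them as failures rather than papering over them.

## Synthetic generators

`build_cd` places glycosidic oxygens at equal parameter angles on an
ellipse (axis ratio = the requested ellipticity, so the circularity
descriptor recovers it exactly: equally spaced angles give a diagonal
covariance with eigenvalues a²/2 and (ell·a)²/2). Each unit's planar
hexagonal pyran ring is centred between consecutive oxygens with its plane
normal constructed at exactly the requested tilt under the analyzer's
radial convention, and its C4/C1 vertices land within the 1.8 Å bridging
criterion of the owning and next unit's O4, so distance-based topology
detection recovers the generator's serial lists exactly; infeasible
radius/unit-count combinations error out. Rim oxygens sit ±1.3 Å (default)
above/below the base plane. Defaults (7 units, 5 Å radius, tilt 80°)
mirror a β-CD-like host: free-CD tilt ensembles centre near 80° and
crystal-structure values sit in the mid-80s.

`place_guest` rigidly maps a canonical guest template (B→A vector along
+z) into the host frame, so `describe_frame` inverts the construction to
1e-6 in d and θ. The guest template is a rigid planar three-ring scaffold
with a phosphorus-bearing ring B — fixture geometry, not chemistry.

`simulate_descriptor_trajectory` evolves a hidden Markov chain over
(BS, BP, UNBOUND) and draws per-frame (d, θ) from state Gaussians. The
default states place BS at (−1.0 Å, 20°) and BP at (+1.2 Å, 152°) — the
docking/MD-derived poses of the β- and γ-CD complexes — with unbound
excursions near 9 Å, sticky transitions (self-probabilities 0.95–0.97 at a
10 ps frame step) so dwells last hundreds of ps, and noise SDs (0.4 Å, 6°)
small against the state separations. θ draws are clipped to [0°, 180°].
The emitted state log is the ground truth for occupancy-recovery tests;
structure emission through `place_guest` is optional and bypassable for
speed.

What the generator does **not** emulate: solvent, host flexibility beyond
the fixed tilt (no per-frame host deformation), guest internal degrees of
freedom, autocorrelated noise within a state, or any force-field
energetics of the emitted structures. Passing recovery tests therefore
demonstrates the correctness of the descriptor and bookkeeping arithmetic
under known ground truth — not the realism of any particular MD ensemble.

## Problem sizes and numerical choices

Statistical recovery tests use 10⁴-frame state logs (structure emission
bypassed) and compare against the generator's log exactly, and against
stationary values within 3σ of the correlated-chain sampling error
inflated by (1+ρ)/(1−ρ) for the chain's second eigenvalue ρ. The
pairwise-decomposition oracle (a naive double loop) runs on ≥10 random
5–6×4–5-atom systems plus one 60×40 system at 1e-10 agreement. Plane fits
reject inputs whose second singular value vanishes (collinear oxygens,
degenerate rings); coincident inter-fragment atoms (r < 1e-6 Å) are
rejected rather than summed. PDB round trips preserve coordinates to the
format's 1e-3 Å precision.

## Known limitations

* Descriptor agreement with other toolchains' τ/circularity conventions is
  documented but not guaranteed beyond ±2° / ±0.02-level differences;
  crystal-structure inputs were not exercised here (they require
  downloads), only the synthetic ground-truth path.
* XYZ input carries no residue information, so topology detection on XYZ
  requires explicit hints.
* The EDA-FF module evaluates fixed geometries; it does not optimise or
  sample them, so published decomposition tables can only be checked for
  internal additivity, not regenerated from structures without the original
  QM geometries and fitted charges.
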