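# Methods

## The projection approximation and its estimator

The collision cross-section of a rigid body in the projection
approximation (PA) is the mean, over uniformly distributed orientations,
of the area of the projected union of its hard spheres. `ccsbuild`
estimates it by Monte Carlo: `n_rotations` random rotations (uniform over
SO(3), quaternion sampling via `scipy.spatial.transform.Rotation`), and
per orientation a uniform point sample of size `n_points` over the tight
bounding box of the projected disks. The point-in-union test is
JIT-compiled (numba) with the disks sorted along one projection axis so
each point only checks nearby disks; a pure-numpy fallback produces
bit-identical results when numba is unavailable.

The reported `mc_stderr` is the between-orientation standard error. Two
variance regimes matter:

- *point-sampling noise*, ∝ n_points^(−1/2) per orientation — small at the
  default 4000 points (≈ 0.8% per orientation for a sphere, ≈ 0.05% after
  300 orientations);
- *orientation-profile noise* for aspherical bodies (the projected area
  genuinely varies with orientation, by 5–10% for elongated units),
  ∝ n_rotations^(−1/2); this dominates for atomic models.

Defaults `n_rotations = 300`, `n_points = 4000` keep the single-sphere
error well below 1%. All estimates are deterministic for a fixed seed.

The PA ignores scattering and therefore systematically underestimates
measured CCS; every estimate carries a multiplicative `scale`
(default 1.0), and `calibrate_scale` fits one global factor by least
squares on (computed, measured) pairs. Collision radii default to a single
2.2 Å for all heavy atoms with a per-element YAML override; the global
scale factor absorbs the residual calibration, so the exact radius choice
is not load-bearing.

## Missing-mass accounting and the decision tree

Chain masses use average amino-acid residue masses with one water per
chain (a monoisotopic table is available behind a flag). A residue is
*present* iff at least one heavy atom is observed; alternate locations
keep the highest-occupancy conformer, insertion codes count as distinct
residues, and only the first NMR model is read. When both SEQRES and a
user FASTA are given the FASTA wins, because the biologically full-length
sequence can exceed the crystallized construct. The missing fraction is
f = (m_full − m_present)/m_full, and the 5% linear-scaling rule uses the
full biological sequence by default (the construct-only alternative is a
caller choice of `full_sequence`).

Linear scaling multiplies the CCS by m_full/m_present. Read literally the
rule is linear in the mass ratio; the constant-density geometric
alternative (mass ratio)^(2/3) is exposed as `exponent=2/3`. At f < 5% the
two differ by < 1.7%, below typical experimental error, so the choice is
not critical.

Routing: f = 0 → `complete`; f < 0.05 → `linear_scaled`; otherwise
`homology` iff a template has sequence identity > 30% **and** structural
completeness < 95%, else `coarse_grained`. Structural completeness is
defined here as 100×(1 − f_missing) of the template. Two regions the rule
set leaves open are routed to `coarse_grained` with an explanatory
rationale: a good template that is already ≥ 95% complete, and a large gap
with no template information. The homology path does not build models —
template-based model construction is an external step — it validates and
ingests a user-supplied model and then continues as `complete`.

## Coarse graining

Domain decomposition uses a Gaussian network (Kirchhoff/graph Laplacian)
on Cα atoms with an 8 Å contact cutoff. Residues are clustered (k-means)
on the two slowest nontrivial modes *weighted by 1/λ*: the thermal
amplitude weighting makes genuinely soft inter-domain modes dominate over
localized surface modes, which otherwise corrupt the clustering whenever a
flexible tail or linker contributes a low-frequency localized mode.
Automatic selection takes the largest k ≤ 3 whose domains each hold ≥ 15%
of residues **and** whose clusters are well separated in mode space
(silhouette ≥ 0.6); compact single-domain structures fall through to
k = 1. A disconnected contact network raises an error suggesting a larger
cutoff.

Each domain becomes one sphere at its mass-weighted center with radius
√(Ω_domain/π) and the domain's residue mass (sphere masses therefore sum
to the observed residue mass; the per-chain water stays in the chain-level
accounting). Sphere placement is deterministic by construction — centers
of mass rather than a trained placement — and the calibration step absorbs
shape differences: one **global** radius factor (preserving relative
domain sizes) is bisected until the CG model's PA CCS matches the atomic
model's within half the stated 1% tolerance. The bisection evaluates the
atomic target and every CG trial over the *same* orientation sample
(paired Monte Carlo). This is a pure variance-reduction device: the
orientation profile shared by the two similar shapes cancels in the
difference being driven to zero, which is what makes a sub-percent match
measurable at moderate sampling; it does not bias either estimate.

The missing-residue sphere has radius (3m/(4πρ))^{1/3} with ρ pooled over
the resolved spheres (Σm / Σ(4/3)πr³). Its center is restricted to the
plane spanned by the model-COM→anchor axis and a fixed perpendicular,
parameterized by overlap o ∈ [0,1] (center distance
r_a + r_m − o·r_a, so o = 0 is external tangency) and angle θ over that
great circle, on a 21×36 grid by default. The grid argmin of
|CCS − experimental| is selected; ties prefer the most compact (largest
overlap) placement. If even the most compact placement overshoots the
experimental CCS by more than the tolerance (the experimental relative
error, else 10%), the scan is returned inside an infeasibility error. The
(overlap, θ) frame is a convention; only the achieved CCS is identifiable
from a single scalar restraint, so the scan records the whole grid.
Multi-sphere ("string of beads") representations of missing segments are
out of scope.

## Archetypal topologies

Copies of the building block are placed with nearest-neighbour bounding
spheres tangent, with a default 10% allowed overlap mimicking packed
interfaces. Linear chains and regular rings use the bounding-sphere
diameter as contact distance; rings need n ≥ 3 and double-tiered rings
(two staggered (n/2)-gons) even n ≥ 6. Stacked and edge-to-edge variants
translate along the block's principal axes (longest axis = end-to-end,
middle = edge-to-edge, shortest = face-to-face), with contact distance set
by the block's extent along that axis; `stack_end` rotates alternate
copies 180° about the stacking axis to capture head-to-head vs
tail-to-tail arrangements. The axial/lateral naming is a documented
convention — the literature distinguishes these stackings verbally.

The `collapsed` lower bound packs copies greedily (contact points over a
direction set, minimizing the sum of pairwise center distances) followed
by a deterministic contraction/repulsion refinement, at the *tightest*
legitimate contact distance — the block's smallest axis extent — because a
lower bound packed at bounding-sphere tangency would sit above the
face-stacked archetype for flat blocks. Exact optimality is not required
of a bound. Linear is then the maximum and collapsed the minimum CCS at
every n, which the tests assert within Monte-Carlo error.

## Crystal-symmetry mining

REMARK 290 SMTRY rows are parsed as Cartesian operators; user-supplied
fractional operators are orthogonalized through the cell. Operators ×
lattice translations within ±`shell` cells (default 1) give the block of
copies; identical transforms are deduplicated and the identity copy is
always first. Space-group-name→operator synthesis is deliberately not
implemented — operators must come from the file or the caller.

Candidates for an n-mer are connected subsets of copies containing the
reference copy (neighbour = COM distance ≤ 1.2 × block diameter, a
documented default; the paper-scale quantity here is "near-touching").
Subsets grow best-first on partial compactness, which is admissible and
monotone, so completed subsets pop in ascending compactness order and the
first `max_candidates` are exactly the most compact — verified against
exhaustive enumeration on every block small enough to brute-force.
Candidates whose copies interpenetrate by more than 5% of a copy's sphere
volume are discarded.

Stepwise series selection enforces nesting (each selected n-mer extends
the selected (n−1)-mer by one copy). Extensions are scored against the
measured CCS for that order; those outside the experimental tolerance are
rejected, and among the joint solutions within one tolerance of the best
fit the most compact packing wins, with point-group symmetry (checked
against C2/C3/D2/D3 by mapping the COM set onto itself within 1 Å) as the
secondary criterion. Compactness ranks ahead of symmetry deliberately:
on a crystal lattice many extensions differ in CCS by far less than any
experimental error (a dimer along **a** vs **b** can differ by 0.1%), so a
raw argmin over noisy CCS values is ill-posed, and a symmetric-but-
extended chain inside the noise window must not displace the compact motif
that distinguishes the measured architecture. When an order has no
measurement, selection falls back to (compactness, symmetry). A failed
order returns the partial series with a diagnostic instead of guessing.

## The synthetic data generator

`synthetic.make_unit` emits Cα-only poly-alanine PDB units: one CA per
residue, dart-thrown at ~0.8 Da/Å³ inside a globular, dumbbell
(two lobes + 5-residue linker) or trilobe envelope, with SEQRES for the
full sequence and a C-terminal fraction of residues declared but absent —
the shape of real truncated constructs. Operator sets: identity only, P1
(lattice translations only) and a 4-operator orthorhombic screw set.
Cell lengths are 1.06/1.13/1.22 × the unit's extent along each axis, so
lattice neighbours pack near-touching without clashing and the three
directions are geometrically distinct.

Planted CCS tables are computed from a known architecture — either an
archetype or the geometrically preferred (compactness-then-symmetry
greedy) nested series of symmetry copies — then perturbed by a uniform
multiplicative factor within ±noise; reported relative errors are
max(3%, noise + 2%), capped at the typical 10% experimental uncertainty.
Closed-loop tests then require the pipeline to reselect the planted
member sets exactly, which succeeds for noise within the reported error
and collapses to a flagged "no consistent model" at 25% noise.

What the generator does *not* emulate: real side chains and packing
interfaces (mass bookkeeping only needs consistent residue masses),
conformational change between oligomer orders (the method itself assumes
rigid building blocks), heteromeric mixtures, and measurement artifacts
beyond multiplicative noise. Passing closed-loop tests therefore
demonstrates the machinery — mass accounting, CCS estimation, mining,
nested selection — not the biological correctness of any particular
assignment on real data, which still hinges on the quality of the
experimental CCS values and of the deposited coordinates.

## Problem sizes and numerical choices

Default test and acceptance scales: units of 100–120 residues, oligomers
to 8 building blocks (≈ 800 pseudo-atoms), 300–3000 orientations per CCS
estimate depending on the precision the comparison needs, 20 structures ×
2 models for the calibration benchmark. Bisection brackets [0.5, 2] with
geometric expansion and at most 60 steps; degenerate inputs (empty
models, non-positive radii or masses, missing anchors, disconnected
networks, fractional operators without a cell) raise typed errors rather
than propagating NaNs. Reports serialize with sorted keys and no
timestamps, so a rerun with the same config and seed is byte-identical.

## Known limitations

- The PA scale factor is data-driven; without calibration pairs the
  default 1.0 reproduces *relative* trends but not absolute magnitudes.
- Point-group detection is template-limited (C2/C3/D2/D3) and operates on
  copy centers of mass, not full coordinates.
- The collapsed archetype is a heuristic bound, not a global optimum.
- Homology models are consumed, never constructed.
- mmCIF, electron density and multi-model NMR averaging are out of scope.
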