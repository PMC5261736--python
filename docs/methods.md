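# Methods

This note documents the models, numerical choices and limitations of
`dockpot` in one place.  Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Scoring model

All potentials are linear: the score of a decoy is `f · σ`, where `f` is
a per-decoy feature vector fixed by the geometry and the atom typing, and
`σ` are trainable parameters.  Lower (more negative) scores mean better
poses.  Linearity is the load-bearing design decision: it lets feature
vectors be precomputed once per decoy ("feature grids"), after which
re-scoring an ensemble under any parameter set is one matrix–vector
product, and it makes both a rank-based stochastic trainer and plain
least-squares regression applicable to the same representation.

Atom types come from a pluggable typing table mapping
`(residue, atom name)` to an integer in `[0, λ)`.  Unordered type pairs
are indexed canonically (`index(a,b) = index(b,a)`, a bijection onto
`[0, λ(λ+1)/2)`).  The shipped default is a 27-type grouped all-atom
table over the 20 standard amino acids: 4 backbone heavy types, 19
side-chain heavy types grouped by the chemical character of the five
residue classes (non-polar, polar, aromatic, positively charged,
negatively charged), and 4 grouped hydrogen types (backbone, aliphatic,
polar, aromatic).  With 23 heavy types, BSA potentials have 23
parameters.  The grouping is this package's own reconstruction of a
chemical-character typing; it is not a transcription of any published
table, and tests only rely on its declared dimensions and coverage.

### Feature forms

* **step** — per (pair index, bin): the number of receptor–ligand atom
  pairs whose distance lies in the half-open bin `[lo, hi)`.  A distance
  exactly on an edge belongs to the upper bin; this convention is frozen
  by tests because oracle equality demands an exact rule.  Pairs beyond
  the last edge are ignored.
* **vdw** — per pair index, `Σ max(r, r_clash)⁻⁸` and
  `Σ max(r, r_clash)⁻⁶` over cross pairs with `r < r_cut`.  The clash
  floor (default 2 Å) shifts too-close contacts up to 2 Å so that atom
  overlaps — common when coarse-grained sampling output is rescored
  atomistically — do not dominate the sums.  The cutoff (default 12 Å)
  makes neighbour search well defined; the neglected `r⁻⁶` tail beyond
  12 Å is negligible against interface terms.  Scoring uses
  `E = α f₈ − β f₆` with `α = ε σ⁸`, `β = ε σ⁶`; the stored flat vector
  is `(α, −β)` so the dot-product convention holds, and the physical
  view inverts exactly as `σ = √(α/β)`, `ε = β/σ⁶`.  The single-pair
  closed form (zero at `r = σ`, minimum `−(27/256) ε` at
  `r = σ√(4/3)`) is verified against a dense grid search.
* **bsa** — per heavy atom type, the solvent-accessible surface area
  lost on complexation, summed over atoms of that type on *both*
  partners.  SASA uses a deterministic quadrature: a fixed golden-spiral
  point set (default 960 points/atom) on each expanded sphere
  (radius + 1.4 Å probe); a point is accessible if outside every other
  expanded sphere.  Reference state: each partner isolated in its docked
  internal conformation, so for rigid-body decoys BSA depends only on
  the interface.  Per-atom burial is clamped at zero (with a shared
  point set it is non-negative anyway), and the per-type totals satisfy
  the identity `Σ BSA = SASA_R + SASA_L − SASA_complex` exactly.
  Per-element radii: H 1.20, C 1.70, N 1.55, O 1.52, S/P 1.80 Å
  (1.80 default).  Accuracy versus an independent latitude–longitude
  quadrature is within 2% at the default resolution.

Feature grids persist as a binary matrix plus a JSON header (form, bin
edges, λ, typing-table hash, decoy ids); save/load is bit-exact, and any
append or scoring across mismatched forms or tables raises a layout
error.

## Quality assessment

Fnat is the fraction of native interface residue contacts (heavy-atom
cross distance < 5 Å — the community convention; configurable) present
in the decoy.  Lrmsd superposes the decoy receptor onto the native
receptor (Kabsch SVD, proper rotation enforced) and takes the RMSD over
ligand heavy atoms.  Irmsd selects native interface residues (any heavy
atom within 10 Å of the partner), takes their backbone atoms (N, CA, C,
O) and reports the RMSD after superposition on those same atoms.

Star classes: 3 if `Irmsd < 1 and Fnat > 0.5`; else 2 if
`Irmsd < 2 and Fnat > 0.3`; else 1 if `Irmsd < 4 and Fnat > 0.1`; else
0.  All inequalities are strict and frozen by boundary tests.  The upper
Fnat bound sometimes quoted for the one-star class is read as the
hand-off to the higher classes, not an exclusion: a pose with Fnat 0.4
and Irmsd 3 Å is acceptable, not incorrect.

Training weights: a raw weight per decoy (star class, Fnat, 1 on an
inserted native, or any callable), normalised to sum 1 within each
complex so that complexes with many near-natives do not dominate the
target.  A complex whose raw weights are all zero is flagged unusable
rather than failing.

## Monte-Carlo annealing trainer

The target `t = Σ_c Σ_i wq_{i,c} · wr(rank_i)` is maximised; `wr` rises
from the last rank to 1 at rank 1, linearly (`(n−r+1)/n`) or
quadratically (its square).  Each step perturbs one uniformly chosen
parameter additively by ±Uniform(0, d), re-scores every training complex
(one matrix–vector product each), re-ranks, and accepts with probability
`min(1, exp(Δt/T))`.  Moves live in the natural space of each form —
raw values for step/BSA, (σ, ε) for vdw, clamped to σ ∈ [1.5, 6] Å,
ε ∈ [0, 50].

Temperature follows a "ziczac" schedule: an exponential envelope from
T₀ = 50 down to T_end = T₀/1000 = 0.05 over the step budget (default
300,000 steps for step/BSA, 100,000 for vdw), modulated by
`sin²(πks/S + π/2)` to swing between the envelope and envelope/ρ
(defaults ρ = 3, k = 10 oscillations).  The exact oscillating form is
this package's reconstruction of the schedule family it implements: it
starts on the envelope at T₀, ends at T_end for even k, and never
leaves the band `[T_hi/ρ, T_hi]` — all three properties are tested.

Move-size adaptation multiplies d by 1.1 (0.9) when the trailing
100-step acceptance exceeds (falls below) 0.3.  d is deliberately
unclamped: rank-based targets are invariant to positive rescaling of
the parameters, so during the hot phase acceptance stays high and d
grows; the resulting large single-coordinate moves act as an effective
re-randomisation search over scoring directions.  Clamping d (tested at
3 and 10) roughly halved planted-recovery performance, so the clamp was
rejected.

Early stopping: the run ends when the best-so-far target improves by
less than 1e-6 (relative) over a trailing 2,000-step window — but the
check is only armed once the decay envelope is within a factor 2 of
T_end.  A flat record during the hot phase is expected (new records of
a near-random walk become logarithmically rare) and does not indicate
convergence; arming the test early truncated 20,000-step runs at about
2,200 steps and destroyed recovery.

Runs are bit-reproducible from the seed: a single PRNG stream drives
move selection, magnitudes and acceptance draws, and the trace records
per-step target, temperature, acceptance, move size and best-so-far.

## Regression trainer

Targets: `y = −q` for quality-increasing assessments (stars, Fnat);
`y = −1/q` for deviation assessments (Irmsd, Lrmsd), with `q ≤ 1e-3`
mapped to 0 to avoid blow-up.  Feature rows are divided by their own sum
("fraction normalisation") so complexes with large interfaces do not
dominate; all-zero rows stay zero and are flagged.  Fits: ordinary least
squares, or non-negative least squares for vdw — there the design matrix
is `[f₈, −f₆]` so the non-negativity constraint lands on the physical
`(α, β)`.

Cross-validation splits *complexes* (not decoys) into k folds
(default 5, matching a five-set protocol; with hundreds of training
complexes, literal leave-one-out would produce as many sets as
complexes, so k-fold is the operative reading).  Step/BSA: each per-fold
parameter set is divided by the standard deviation of its own entries —
the one scalar per set under which "scale by the standard deviation" is
well defined — then averaged elementwise.  vdw: the set with the best
validation score is kept, since (σ, ε) averages across folds are not
meaningful parameters.

## Evaluation

Top-N success: fraction of complexes with at least one qualifying decoy
(native, or ≥ 1 star) at rank ≤ N.  Enrichment at percentile q: the
fraction of all near-natives ranked within the best `ceil(q·n)` decoys
(minimum slice 1, so small sets never yield empty slices).  Complexes
without any near-native are excluded from enrichment averages (no
definable fraction) but count as failures in success rates.  Ranking is
by ascending score with stable input-order tie-breaks, so top-N metrics
are reproducible.  The random baseline re-estimates every metric over
seeded uniformly random rankings; it matches the hypergeometric closed
form for top-N success and the percentile itself for enrichment, within
sampling error — both verified.

Contribution analysis: for parameter `σ_AB` and a decoy class with mean
feature `nc^class`, the class contribution is
`p = σ_AB · nc^class / nc^tot` (0 when `nc^tot = 0`); the
discriminating contribution is returned both as
`σ_AB · |nc^near − nc^incor| / nc^tot` and as the signed difference
`p^incor − p^near`.  Parameters whose sign contradicts the ordering of
the class means are flagged false-positive/negative contributions.

## Synthetic fixtures

The generator stands in for large external decoy benchmarks.  A toy
complex is two clash-free clusters of pseudo-atom beads (one bead per
residue, atom name CA, element radius 1.8 Å) slid into contact along one
axis until the minimum cross-partner distance lies in [2, 4] Å, with at
least 3 interface contacts at 5 Å.  Bead types (default λ = 4) are
random, except that interface beads are the "sticky" type 0 with
probability 0.55 — emulating the compositional bias of real interfaces
(e.g. hydrophobic enrichment), which is the transferable signal a
cross-complex potential can legitimately learn.  Decoys are rigid-body
ligand perturbations from four magnitude tiers (rotation/translation up
to 3°/0.3 Å, 8°/1 Å, 20°/2.5 Å, 180°/30 Å at fractions
0.05/0.05/0.10/0.80), every decoy re-slid into surface contact — a
rigid-body sampler only emits touching poses, and detached poses would
otherwise produce degenerate all-zero feature rows — and the ensemble
order is shuffled so input order carries no quality information (stable
rank tie-breaks must not silently favour near-natives).  Default sizes
(10–14 complexes, 30-bead partners, 300–500 decoys) keep a full
train-and-evaluate cycle in seconds.

A planted linear potential (step form, parameters drawn once from the
seed) defines ground-truth energies `f · σ_planted` (noise optional,
default 0: the planted model is the exact ground truth and decoy
geometry supplies the variation).  "Planted-good" decoys are exactly the
lowest decile of energies (stable tie-break).  Recovery experiments then
have a known answer: OLS on the noiseless benchmark recovers the planted
parameters to machine precision, and 20,000-step annealing on 10
training complexes places ≥ 80% of planted-good decoys in the top 10%
of held-out complexes, far above the ~10% random expectation.

What the fixtures do *not* emulate: real side-chain geometry and
chemistry (beads are single spheres of one radius), sampler-specific
decoy artefacts, conformational change on binding, and realistic
near-native scarcity (the default tiers give ~30% starred decoys versus
well under 1% in practice).  Passing the fixture-based tests therefore
demonstrates correctness of the machinery and recoverability of planted
signal — not benchmark-level performance on real docking sets, which
requires real decoy ensembles.

## Known limitations

* The default typing table is a chemically sensible reconstruction, not
  a published standard; users with a preferred scheme should load their
  own TSV.
* Irmsd uses backbone atoms N/CA/C/O of native-interface residues;
  structures without those names (other than the bead fixtures, which
  use CA) need a custom backbone set.
* SASA is quadrature-based; areas are deterministic but carry ~1–2%
  quadrature error at default resolution.
* The annealing target recomputes full rankings each step; this is
  simple and fast at desk scale but not the asymptotically cheapest
  update.
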