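# Methods

This note documents the statistical models implemented in `archasym`,
the numerical choices behind them, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Landmark data model

A configuration is one digitisation of one side of one individual: an
`n_points × dims` coordinate matrix plus metadata (individual, biotype,
lineage, site, side ∈ {L, R}, digitising session, dental formula).  The
default scheme is the 33-point 3D arch scheme: fixed landmarks
{1, 2, 3, 4, 18, 19, 33} and two 13-point semi-landmark chains,
4–[5…17]–18 (outer ridge) and 19–[20…32]–33 (inner curve).  Landmark
indices are 1-based at every public interface.  Schemes are fully
configurable; nothing anatomical is hard-coded, and replicate counts
other than 2 are accepted wherever the design stays balanced.

The canonical file format is a long CSV (one row per landmark) with full
`repr` float precision, so write→read round trips are bit-exact; a
column-mapping argument absorbs externally named columns, and `.xlsx`
input is read through the same path.  A minimal TPS reader supports 2D
fixtures.

## Superimposition

GPA centers each configuration, scales it to unit centroid size
(scaling is on by default — the matching-symmetry decomposition
downstream assumes size-free shape variables; pass `do_scale=False` for
size-and-shape analysis), and iteratively rotates all configurations to
the running consensus until the consensus root-mean-square change is
below `tol` (default 1e-6, `max_iter` 100, error on non-convergence).
Only proper rotations (SVD solution with determinant correction) are
used; reflection is always an explicit, separate operation so that
side-matching is controlled rather than absorbed silently.

Bending energy uses the thin-plate-spline kernel `U(r) = r² log r` in 2D
and `U(r) = −r` in 3D; the energy matrix is the upper-left block of the
inverted TPS system, symmetrised, and energies are reported as the
absolute value of the quadratic form (the 3D kernel's sign convention
would otherwise flip it).  The matrix is positive-semidefinite and
annihilates affine displacement fields; both properties are tested.

Sliding is linearised: each semi-landmark moves only along its unit
tangent, estimated by central difference between its chain neighbours
(anchors included, so every semi-landmark has two neighbours).  The
optimal slide amounts solve the normal equations of the quadratic
bending-energy objective against the current consensus; fixed landmarks
never move.  Slide and re-superimposition alternate for up to 5 cycles
or until the consensus stabilises at 1e-6.  Within a cycle the exact
quadratic minimiser cannot increase the energy measured against that
cycle's consensus; a guard keeps the previous positions in the
(numerically impossible) case it would.

Tangent projection removes the component of each flattened
configuration along the unit consensus vector; the consensus maps to
zero and the projection is idempotent.

## Matching symmetry and the Procrustes ANOVA

Right-side configurations are reflected by negating the first (x)
coordinate, then both sides are jointly superimposed, slid (the second
superimposition re-slides semi-landmarks by default; configurable) and
projected.  Sliding uses the joint consensus of both sides; this is a
deliberate choice — a side-specific consensus would absorb part of any
directional asymmetry into the sliding step.

The ANOVA decomposes tangent-space sums of squares sequentially over
the balanced crossed design (n individuals × 2 sides × r sessions):

| effect            | df          | tested against     |
|-------------------|-------------|--------------------|
| Individual        | n − 1       | Individual × Side  |
| Side (DA)         | 1           | Individual × Side  |
| Individual × Side (FA) | n − 1  | Measurement error  |
| Measurement error | 2n(r − 1)   | —                  |

Degrees of freedom are counted per effect (not multiplied by the shape
dimension), MS = SS/df, and the SS add exactly to the total.  P-values
use residual randomisation under the reduced model (RRPP): for each
term, the model without that term is fitted, its residual rows permuted
and added back, and the term's F recomputed; P = (#{F* ≥ F} + 1)/(n_perm
+ 1) with 999 permutations by default.  Unbalanced designs are rejected
rather than approximated, and the FA test demands ≥ 2 sessions because
measurement error is its error term.

Variance components can be recovered by inverting the expected mean
squares (σ̂²_ME = MS_E, σ̂²_FA = (MS_IS − MS_E)/r, σ̂²_ind =
(MS_I − MS_IS)/2r).  Superimposition projects each configuration's
deviation onto the 3k − 7 dimensions orthogonal to the similarity group,
so per-coordinate components are attenuated by (3k − 7)/3k (≈ 0.93 at
k = 33); the recovery test accounts for this factor and uses a
fixed-landmark scheme, since sliding deliberately discards along-curve
variation and would (correctly) remove further component mass.

### Per-landmark tests

For each landmark, the per-individual replicate-averaged L − reflected-R
deviation (a 3-vector) is the response.  Site enters as a conditioning
factor in centered dummy coding, which absorbs between-site deviation
differences without touching the overall mean; the statistic is the
Ezekiel-adjusted pure fraction of uncentered variance explained by the
mean offset.  The permutation null flips the sign of each individual's
site-adjusted deviation: under the no-asymmetry hypothesis the
deviations are symmetrically distributed around zero, and sign flips are
the exchangeability that nulls a mean — permuting residual rows, as RRPP
does elsewhere, would leave the column means untouched and cannot test
this hypothesis.  Raw and Benjamini–Hochberg-adjusted P are reported; α
defaults to 0.05 everywhere.  With a single site the test degrades to
the uncontrolled version with a warning.  Note that a displacement
confined to one landmark in the generating space spreads to all
landmarks through superimposition (the "Pinocchio effect"), so
neighbouring landmarks of a true signal may also reach significance;
the affected landmark still carries the largest effect size.

## RDA, variance partitioning, trajectories

RDA is multivariate least squares of the column-centered response on
full-rank dummy-coded constraints (QR with rank detection, so the R² is
invariant to the coding); R²_adj uses the Ezekiel formula
1 − (1 − R²)(n − 1)/(n − p − 1), which may legitimately be negative.
Partial RDA reports the pure fraction R²(X+Z) − R²(Z) with the
Peres-Neto adjusted difference, and permutes residuals of the
conditioning-only model; with no conditioning factor it reduces exactly
(bit-for-bit at equal seeds) to plain RDA.  The two-factor variance
partition reports pure, shared and residual fractions; the shared
fraction is not permutable and carries no P.

Trajectory analysis compares, for every pair of groups, the difference
vector between group mean shapes: its norm (magnitude) and the angles
between contrast vectors.  Nulls come from reshuffling group labels;
with `exhaustive=True` every distinct label assignment is enumerated
(exact P, feasible only for tiny samples).  This two-point
(static-contrast) form is the appropriate reduction when groups are
compared at a single state each, which is the use case here; multi-state
trajectories (size/shape of a path) are not implemented.
Homogeneous-subset letters join contrasts by single linkage over
non-significant pairwise differences at α = 0.05.

## Dental statistics

Simpson's diversity is the plug-in D = 1 − Σ pᵢ² (the probability two
random individuals differ in formula); the finite-sample variant
1 − Σ nᵢ(nᵢ−1)/(N(N−1)) is available behind a flag but is not the
default, because the plug-in form is what the published tables this
package reproduces used.  The χ² test is Pearson's without continuity
correction by default (again matching the published usage); a
dual-route unit test checks it against the literal Σ(O−E)²/E.  Formula
strings accept hyphen, en-dash or em-dash between sides and are
canonicalised to the en-dash.  `archasym.reference_data` ships the
published count tables (per-lineage hybrid counts, parental counts, and
the historical survey 2×2) as ready inputs; the hybrid pooled total is
152 as the lineage table sums, and this package uses that table as the
source of record.

## Synthetic data generator

The generator is the package's ground-truth instrument.  Per
individual: shape = unit-size crescent template + site displacement +
iid N(0, σ²_ind) per coordinate; the left side adds the directional
offset (to every individual, or only to alternative-formula individuals
when coupling is on) plus an N(0, σ²_FA) deviation; the right side is
the mirrored shape with its own FA deviation; every digitising session
adds N(0, σ²_ME).  All effects are applied in raw coordinate space
before superimposition, so the pipeline must recover them through GPA
exactly as with real data.  Dental formulae are per-individual Bernoulli
draws with site-specific probabilities, shared deterministically (via a
derived seed) between the formula and shape generators.

Defaults: σ_ind = 0.010, σ_FA = 0.004, σ_ME = 0.002 (fractions of the
unit template size), DA magnitude 0.008 per displaced landmark.  These
were fixed once so that the DA and FA tests at 35 individuals have high
(~0.8+) power — the regime the analysis is designed for — and are not
tuned per test.  The default DA offset is projected into the subspace
where a directional signal is identifiable: orthogonal to the template's
similarity transforms (which superimposition removes) and to the curve
tangents at the semi-landmarks (whose along-curve positions sliding
treats as arbitrary).  The `study_mimic_dataset` fixture reproduces the
study's design dimensions — 66 clonal individuals across 7 sites, 2
sides × 2 sessions, 33 landmarks — with synthetic values.

What the generator does **not** emulate: correlated (non-isotropic)
landmark noise, allometry, digitisation drift between sessions,
heavy-tailed error, antisymmetry, or any real arch geometry beyond a
smooth crescent.  Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to every real-data
pathology.

## Problem sizes used in the test suite

Monte-Carlo checks use deliberately compact designs: permutation-P
uniformity and null false-positive rates use 200 simulated datasets of
10–12 individuals with 99 permutations each; variance-component
recovery averages 500 datasets of 50 individuals at 33 landmarks;
DA-vector recovery uses one dataset of 200 individuals under the full
sliding pipeline.  These sizes give stable Monte-Carlo error for the
stated tolerances (KS 1% band, 10% component error, cosine 0.95).

## Known limitations

* Only matching symmetry (paired separate structures) is implemented;
  object symmetry (midplane mirroring within one structure) is out of
  scope.
* Procrustes distances are the full tangent-space approximation; no
  partial/size-and-shape distance variants.
* The per-landmark test is a documented interpretation (pRDA on
  deviations with sign-flip nulls); other constructions (e.g. per-landmark
  mixed models) could differ in power.
* Balanced designs only in the ANOVA; unbalanced data must be
  subsampled or completed upstream.
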