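# Methods

This note documents the statistical procedures `tdpq` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the conventions of the field
leave room.

## Target-decoy FDR

Identifications are scored by E-value (lower is better) and carry a decoy
flag tied to a `DECOY_` accession prefix. At a score threshold t the raw
FDR estimate is D(t)/max(1, T(t)) — decoys over targets among matches with
E-value ≤ t — and an item's q-value is the minimum raw FDR over thresholds
at or beyond its score, capped at 1. Ties in E-value are grouped before
ranking, so the result does not depend on input order. The same machinery
runs at two tiers: over all PrSMs (spectrum level, default 5%), and over
one best-scoring representative per proteoform cluster (proteoform level,
default 1%; 5% in SAAV searches, where the variant database is larger and
the proteoform count smaller).

The D/T estimator (rather than (D+1)/T) follows the convention of the
TopPIC tool family whose outputs this pipeline consumes. D/T is slightly
anti-conservative, with realized false-discovery proportion exceeding the
nominal level by roughly 1/T for an accepted list of T items; at the
proteoform tier this matters when accepted lists are short (hundreds), and
the calibration checks in the test suite therefore run at list sizes where
the bias is well inside binomial error. Decoys and targets are filtered in
one merged collection; per-condition filtering before merging is a
plausible alternative the pipeline does not implement.

## Proteoform clustering

PrSMs are grouped per protein accession; within a protein, clustering is
greedy: the unassigned PrSM with the lowest E-value (ties by lexicographic
spectrum id) seeds a cluster and absorbs every unassigned PrSM whose
neutral precursor mass lies within `mass_tol` of the seed. `mass_tol`
defaults to 2.2 Da, a window whose purpose is to absorb ±1- and ±2-Da
isotope errors from spectral deconvolution (averagine spacing 1.00235 Da);
the boundary is inclusive ("not larger than"). Consequences of the greedy
rule: the representative is by construction the best-scoring member, every
member is within `mass_tol` of the representative, any two members are
within 2·`mass_tol` of each other, and the result is invariant to input
row order. Decoy PrSMs are clustered by the identical procedure so
decoy-vs-target counting stays valid at the proteoform tier. Cross-protein
clustering (proteoform families spanning accessions) is out of scope.

## Label-free quantification

Per replicate run, a proteoform's abundance is the sum over fractions of
its feature intensity (the maximum is taken if several PrSMs of one
proteoform share a fraction, since they report the same feature); a
proteoform observed in no fraction of a run has a missing cell, not zero.
Representatives are matched across runs by re-clustering their union with
the same protein + mass-window rule (the cross-run tolerance defaults to
the clustering window, 2.2 Da); if several members of one run land in a
cluster the largest abundance is kept, a deterministic choice that avoids
double counting. Differential testing uses only rows quantified in every
run (complete cases) — no imputation.

Normalization follows the Perseus LFQ recipe: each row is divided by its
value in the reference run (rows with a zero or missing reference are
dropped with a warning), each column is divided by its median — making
every column median of the ratio matrix exactly 1, including the reference
column — and the matrix is log2-transformed. The procedure is
scale-equivariant: rescaling any input column by c > 0 leaves the final
log2 matrix unchanged. The reference ratio is computed after fraction
summation, the only order consistent with one value per run. Medians of
even-length columns are the mean of the central order statistics.

## S0-moderated permutation test

Per proteoform, with log2 abundances x (condition 1, n₁ ≥ 2 replicates)
and y (condition 2, n₂ ≥ 2):

    d = (x̄ − ȳ) / (s + s0),   s = s_p · sqrt(1/n₁ + 1/n₂)

where s_p is the pooled standard deviation. `s0` (default 1, on the log2
scale where the test runs) damps the significance of low-variance rows;
`s0 = 0` reduces d to Student's two-sample t exactly. Two-sided Student
p-values are reported alongside for the volcano plot.

Significance is decided by permutation FDR in the SAM family: group labels
are reassigned in every balanced way (all C(n₁+n₂, n₁) shuffles enumerated
when there are at most `n_permutations` of them — 20 for a 3-vs-3 design,
which makes q-values exactly reproducible; otherwise `n_permutations`
distinct shuffles are sampled from a seeded generator). For each row's
observed |d| the estimated FDR is

    q = median over shuffles of #{permuted |d| ≥ |d_row|} / #{observed |d| ≥ |d_row|}

capped at 1 and monotonized (non-decreasing as |d| decreases). The
*median* over shuffles, the SAM convention, is load-bearing: an exhaustive
balanced shuffle set contains the identity relabeling and its complement,
whose false-call counts equal the observed call count; a mean would
therefore floor every q-value at 2/(number of shuffles) ≈ 0.1 for 3-vs-3
and make an FDR threshold of 0.05 unreachable regardless of effect size.
The median ignores those two degenerate shuffles whenever the majority of
shuffles mix the groups. This is a reimplementation of the computation the
Perseus "S0 = 1, FDR = 0.05" settings imply, not a Perseus call; Perseus's
exact curved-threshold rule differs subtly across versions, and the SAM
formulation is adopted as the documented interpretation.

Under sparse signal the estimator is mildly conservative (realized FDP at
q ≤ 0.05 sits at or below nominal); on a complete null it flags essentially
nothing, since every candidate threshold estimates an FDR near 1.

## Profiling

*Overlap matrices* are asymmetric by design: the cell at column A, row B is
|A∩B|/|B|, the fraction of B's proteoforms recovered in A.

*PTM census.* Each proteoform's total variable-modification mass (named
modifications plus unexpected shifts; fixed carbamidomethylation excluded)
is assigned to the nearest nominal bin within `tol` (default 1.5 Da): +42
acetyl/trimethyl (isobaric at nominal mass; labelled as one bin), +80
phosphorylation, +160 double phosphorylation, +14 methylation, +16
oxidation, and the combination bins +122 (acetyl/trimethyl + phospho), +96
(phospho + oxidation), +58 (acetyl/trimethyl + oxidation). The +42 bin
additionally requires the modification span to include core position 1;
+42 masses elsewhere stay unassigned rather than miscounted. Categories are
disjoint; out-of-bin and unknown-mass proteoforms are tallied separately.
Note that a printed "78-Da" shift is 1.97 Da from nominal phosphorylation
and falls outside the default tolerance; the tolerance is configurable and
reported with every census.

*Family summaries* treat per-proteoform PrSM counts as a rough relative
abundance proxy. "Intact" means start ≤ 2 (N-terminal Met removal allowed)
and end equal to the protein length.

*Reporting* uses mean ± sample SD (n−1 denominator); the SD of a single
value is missing, not zero.

## SAAV confidence filter

Variant databases add one entry per single-residue substitution, accession
suffixed e.g. `_P72R`; reference entries are retained and variants are
validated against them first. Theoretical fragments are HCD b/y ions with
neutral monoisotopic masses (pyteomics residue table, water 18.010565 Da,
fixed Cys +57.02146 Da); a modification contributes to a fragment only when
the fragment fully contains its span, so b_k + y_{n−k} equals the peptide's
neutral mass exactly for unmodified sequences. Matching is within 15 ppm,
the precursor/fragment tolerance of the upstream search.

A variant proteoform identification is *confident* when it carries no
unexpected mass shift, or when every SAAV site has at least three matched
fragment ions whose cleavage lies strictly between the variant residue and
the nearer edge of the shift's localization interval — otherwise the shift
could sit on the variant residue itself and explain the mass without the
substitution. Ion species are counted (b and y at one cleavage count as
two), and only b/y ions are considered (collisional fragmentation).
An `either_side` mode that also counts ions between the site and the far
terminus is available behind a flag for sensitivity analyses. Sites falling
inside the shift interval have no separating cleavages and can never reach
three. Indels are accepted in variant tables but do not generate entries;
substitutions are the scope of this version.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale, with every draw from one seeded generator (same `SimConfig` ⇒
byte-identical tables):

- **Design**: 2 conditions × 3 replicates × 6 fractions by default.
- **Truth registry**: ~2.5 proteoforms per protein (1 + Poisson), spans and
  modification states drawn from a menu (unmodified, N-terminal acetyl,
  phospho shift, acetyl + phospho, oxidation), masses computed from the
  sequence and enforced ≥ 5 Da apart within a protein so that truth
  proteoforms are unambiguous at the 2.2-Da window.
- **E-values**: true hits log-uniform over 1e−12…1e−5; false targets and
  decoys share one log-uniform distribution over 1e−3…10. This
  exchangeability is exactly the assumption that makes D/T a valid FDR
  estimate, and is what the calibration tests exercise. Background records
  are target or decoy with probability 1/2 each.
- **Masses**: truth mass with Gaussian ppm noise (default SD 2 ppm) plus,
  with probability 0.02, a ±1.00235-Da isotope error — the error mode the
  2.2-Da window exists to absorb.
- **Intensities**: per-proteoform log2 abundance drawn from a normal whose
  central ~95% interval is `intensity_log2_mean_range` (default 18–26), a
  per-run log-normal effect (SD 0.15 log2 units), a unimodal Gaussian
  elution profile across fractions, and replicate noise of 0.35 log2 units
  (roughly a 25% relative SD). The per-run marginal intensity distribution
  is log-normal to within a Kolmogorov–Smirnov distance of 0.05.
- **Missingness** is logistic in log2 intensity (midpoint 15, slope 1), not
  missing-completely-at-random, so the complete-case filter is
  meaningfully exercised.
- **Spikes**: `n_differential` proteoforms get their condition-2 abundance
  shifted by the configured log2 fold changes.
- **SAAV fragment data**: each non-crossing theoretical fragment of a
  variant proteoform is emitted with probability `fragment_coverage_prob`
  and jittered uniformly within ±12 ppm (inside the 15-ppm matching
  tolerance). Fragments whose cleavage falls inside the shift interval are
  never emitted, since their true mass depends on the unknown shift
  position. The recorded ground-truth flanking count is the number of
  flanking theoretical fragments a 15-ppm matcher finds in the emitted
  list, recounted with a plain quadratic loop — this matching-based
  definition is used because distinct theoretical fragments of a large
  proteoform can coincide within tolerance, so an emission-based count
  would occasionally disagree with any mass-based filter.

What the generator does **not** emulate: isotope clusters or m/z peak
lists (no spectrum-level simulation), charge-state effects, retention/
migration-time structure, correlated noise between proteoforms of one
protein, shared-peptide ambiguity, chimeric spectra, or real E-value score
distributions — the published study does not characterize its E-value or
intensity distributions, so the defaults here are stated modeling
assumptions, not estimates from deposited data. Passing tests therefore
demonstrate the correctness and calibration of the *procedures* under the
stated assumptions, not performance on instrument data.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations sized for a
single CPU: FDR calibration pools 20 datasets of ~750 true proteoforms
(~20,000 PrSMs each); fold-change recovery pools 20 datasets of ~150
proteoforms; the differential-test checks pool 20 matrices of 500 rows.
Tolerances follow the quantity being checked: exact worked examples to
printed precision, machine precision (rtol 1e−13) for the s0 = 0 reduction
to Student's t, binomial-error bands for realized false-discovery
proportions (4 SE at the FDR tiers, which accommodates the documented
~1/T bias of D/T; one-sided 3 SE for the conservative permutation
estimator), and 3× the standard error of the seed means for fold-change
recovery. Degenerate inputs are defined, not special-cased: zero pooled
variance gives d = Δ/s0 (or ±∞ when s0 = 0 and Δ ≠ 0, and 0 when Δ = 0),
identical constant groups compare with t = 0, p = 1, and complete
separation of constants reports the floating-point underflow floor rather
than p = 0.
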