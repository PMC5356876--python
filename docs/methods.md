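# Methods

## Model and procedure

The pipeline treats drug repurposing as a signature-matching problem.
A disease state (here, the KRAS-mutant vs wild-type contrast in
colorectal tumours) is summarised as a signed, ordered gene signature;
a drug is summarised as one or more treatment-instance profiles, each a
signed-rank vector over a shared probe universe of size N (magnitude N
= most differentially expressed probe, sign = direction of change
under treatment). The connection score between an m-gene signature and
a profile is the signed-rank dot product normalised by its maximal
attainable value, maxraw = Σ_{j=0}^{m−1}(N − j), so scores lie in
[−1, 1] and −1 identifies a maximal reverser. This score is
antisymmetric under flipping all signature signs and invariant to
probe relabelling.

Because signature length materially affects which drugs surface, the
procedure does not commit to one signature: it runs connectivity
mapping for every nested prefix of the combined signature (top-1
through top-L genes) and aggregates evidence across lengths. Per
prefix, a drug's set score is the mean connection score over its
treatment instances, compared against an empirical null built from
random signatures of the same length (m probes drawn uniformly without
replacement, independent equiprobable signs). The two-sided p-value
uses the add-one correction (b + 1)/(n_perm + 1) and a drug is
significant at p ≤ 1/D (D = drugs in the database), which bounds the
expected number of false connections per database scan at one. Within
each significant list the drug at rank i of M (ranked by |z|) scores
sign(z)·(M − i + 1)/M; the L per-list scores are summed, the mean is
sum/L — the denominator is all L lists, not the lists where the drug
was significant — and drugs are prioritised by absolute mean score,
dropping exactly-zero sums.

The same normalised rank score (M − i + 1)/M drives the gene-level
combination across cohorts; the gene-level and drug-level ranking
formulas are deliberately identical, normalised by the length of the
list they come from so scores are comparable across lists of different
lengths.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 1/n per cohort | t-test significance cut; n = probes tested in that cohort |
| `fc_threshold` | 1.2 | fold-change filter (linear scale, either direction) |
| `floor` | 1.0 | linear intensities are clipped here before log2 |
| `n_perm` | 10 000 | permutation draws per signature length |
| drug significance | 1/D | per-scan expected false connections ≤ 1 |
| `top_k` | 30 | drugs inspected for theme enrichment |
| `abs_mean_threshold` | 0.25 | minimum \|mean score\| for screen validation |
| `copy_number_max` | 8 | cell lines above this are genetic outliers |

The t-test is Welch by default with a pooled-variance option; the
two readings differ only under group-variance imbalance. Fold change
is computed as 2^(Δ mean log2), i.e. the ratio of geometric means —
the linear-mean convention is a documented alternative that matters
only for strongly skewed probes.

## Tie-breaks and numerical choices

- Gene selection sorts by (p ascending, |log ratio| descending, probe
  id ascending); the tertiary key exists purely for determinism.
- Combined-signature ties in |total score| break by smallest
  per-cohort p, then probe id; drug-list ties in |z| break by
  |set score|, then drug id.
- Probes with zero variance in both groups and equal means get p = 1
  (a definite non-finding), not NaN.
- Null sampling without replacement is vectorised by taking the m
  smallest entries of a uniform random row (argpartition), which is
  distributionally exact.
- Per-drug set-score nulls are built by averaging r draws
  bootstrap-resampled from a pool of n_perm independent instance-null
  scores (r = replicate count; r = 1 uses the pool directly). Fresh
  draws per distinct r would multiply the permutation cost by the
  number of distinct replicate counts; resampling from a 10⁴-sized
  pool changes tail estimates by far less than their Monte-Carlo
  error.
- Per-prefix permutation seeds are derived from the master seed with a
  stable string hash, so nulls for different signature lengths are
  independent but every run is reproducible bit-for-bit.
- Signature probes absent from a reference profile raise an error
  rather than being dropped: the platforms this pipeline targets share
  one probe universe, so a mismatch indicates corrupt input.
- "Contributive" means strictly negative contribution (mean signed
  rank × regulation status); zero contributions are excluded. The
  contribution column is left unnormalised — only its sign matters for
  set membership — with a /N-normalised companion column for
  cross-database comparison.
- Ties in the screen validation (exactly equal MT and WT means) count
  as disagreement, the conservative reading. Only negatively scored
  predictions are evaluated, and the screen is intersected with the
  prediction table before the |mean score| threshold is applied.
- The pathway-enrichment background is an explicit parameter
  (defaulting to all tested probes that map to at least one pathway);
  published pathway p-values depend on an unstated background choice
  and are not comparison targets.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis
assumes: three patient cohorts with the study's group sizes (29/33,
30/40, 217/328 MT/WT samples), probe-level log2-normal noise
(homoscedastic within probe, sd 0.5), planted differentially expressed
probes with a ±1.0 log2 mean shift in the mutant group (80% shared
across cohorts, the remainder cohort-specific), a signed-rank
reference database in which reverser drugs carry the planted probes in
their top-magnitude block with opposite sign (planting probability 0.9
per probe per instance), drug-class labels in which the reversers plus
two decoys form one small class (seven members, mirroring the
seven-ARB background), and a 24 MT / 25 WT cell-line screen with a
−0.1 AUC shift for effective drugs at noise 0.1 and one planted
copy-number-9 outlier line. The desk-scale universe is 2000 probes /
200 drugs with replicate counts 3–20; `full_scale()` restores
22268 / 1354 with replicates up to 178 for benchmarking.

Deliberately not modelled: raw probe-level summarisation (inputs are
already-normalised linear intensities), heteroscedastic or heavy-tailed
expression noise, correlated probes, batch effects, the L1000 inference
step behind real reference profiles, and dose/time structure among a
drug's treatment instances. Passing tests therefore demonstrate that
the procedure recovers planted structure under its own model
assumptions and that its null calibration is correct; they do not
certify performance on real cohorts, where effect sizes are smaller and
noise is not i.i.d. log-normal.

Reverser planting operates directly on profile ranks rather than on a
simulated treatment response, because the pipeline consumes reference
profiles only through their signed ranks — rank-level planting is the
minimal model that exercises every consumer.

## Problem sizes

Tests and the acceptance script run the ensemble on the first 50
prefixes with n_perm = 2000 (the engine default stays 10 000), a size
at which one full synthetic study completes in a few seconds and the
20-seed recovery suite in about two minutes, while the 1/D = 1/200
significance level is still resolvable (minimum attainable p =
1/2001).

## Known limitations

- The set-score null resamples from a finite instance-null pool (see
  above); extreme quantiles beyond ~1/n_perm are not meaningful.
- Significance across the L prefix runs is not corrected jointly; the
  1/D rule controls false connections per run, and the sum-score
  aggregation is what suppresses drugs significant in only a few runs.
- With several strong reversers competing, their relative order within
  the top ranks is noise-driven (each list has M ≈ number of
  reversers, so lower-ranked reversers get small per-list scores);
  recovery claims concern the reverser/non-reverser separation, not
  the order among reversers.
- The drug-theme test treats themes as single-label and reports raw
  p-values, matching how such enrichment is usually quoted; multi-label
  drugs can be tested theme-by-theme but without multiplicity
  correction.
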