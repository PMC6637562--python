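# Methods

This note describes the statistical model implemented by `phosphogel`, the
assumptions behind it, the tunable parameters and the numerical and design
choices made where the procedure is genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A dual-stained 2-DE gel experiment produces, for each matched spot *s*,
sample group *g* and biological replicate *r*, two volumes in arbitrary
densitometry units: the phospho-stain signal *P* (Pro-Q Diamond) and the
total-protein signal *T* (SYPRO Ruby). Tables are long-format CSV
(`spot_id, group, replicate, channel, volume`); a spot absent from a gel is
a *missing row*, never a zero volume. Spot detection, matching and
background subtraction are upstream image-analysis steps (PDQuest-style
software); `phosphogel` starts from matched volume tables.

Two preprocessing operations are provided:

- **Total-valid-spot normalization** divides every present volume within a
  gel image (one group × replicate × channel) by the image's total present
  volume and multiplies by a reference constant (10⁶, the ppm convention;
  any constant cancels in PR). It is idempotent and removes any per-gel
  multiplicative factor.
- **Reproducibility filter**: per group and channel, a spot is kept only if
  detected in at least `min_reps` (default 2) of the replicates. The rule
  is applied per group, so group-unique spots survive in their group.
- **Fragment flagging** marks spots whose observed molecular mass falls
  below `ratio_threshold` (default 0.8) times the theoretical full-length
  mass. The comparison is the established exclusion rule; the 0.8 cutoff is
  this package's documented default, since no universal value exists.

## Phosphorylation rate and per-group inference

*PR = P/T* is computed per replicate on the replicates where the spot's
total signal is present; a replicate with total but no phospho signal
contributes PR = 0. A group counts as *phospho-positive* for a spot when
the phospho signal itself passes the reproducibility rule; a
phospho-negative group is summarized as mean PR = 0 with no CI ("N/A").
PR values above 1 are legal (the two stains have unrelated response
factors); values above 1.5 are logged as suspicious.

The mean PR over N replicates is interval-estimated with the
**bias-corrected percentile bootstrap**: draw `n_boot` resamples of size N
with replacement; let *p* be the proportion of resample means *strictly*
below the observed mean (ties are not half-counted), clamped to
[1/(2·n_boot), 1 − 1/(2·n_boot)] to keep *z₀ = Φ⁻¹(p)* finite; the bounds
are the empirical quantiles of the resample means at
*Φ(2z₀ ∓ z₍₁₊γ₎/₂)*. All-identical inputs return the degenerate interval.
`n_boot` defaults to 20,000. With m spots under simultaneous comparison the
per-spot confidence level is Bonferroni-adjusted to γ = 1 − α/m; m defaults
to the number of spots with phospho signal in at least one group.

**Significance rule** (per spot): both groups phospho-negative →
not evaluable; exactly one positive → significant iff that group's adjusted
CI excludes zero (CL > 0); both positive → significant iff the adjusted CIs
do not overlap. The CI-comparison operator is this package's design choice:
simultaneous-CI non-overlap is the natural decision rule matching how such
adjusted intervals are reported, but other operators are conceivable, so
the rule is stated here prominently rather than buried.

Two structural properties of this estimator are worth knowing:

- A percentile-type bootstrap interval never extends beyond the range of
  the resample means, so for N = 4 two independent same-distribution
  samples yield disjoint intervals with probability ≥ 2·(4!·4!)/8! ≈ 2.9%
  no matter how extreme the confidence level. The per-spot false-positive
  rate on null spots therefore floors near 3% — below the nominal α = 0.05,
  but not arbitrarily small.
- The N = 4 bootstrap-mean distribution has at most 256 atoms. Tail atoms
  can be far apart in value, so two runs (or a Monte-Carlo run and the
  exact enumeration of all 256 resamples) can legitimately differ by one
  atom when a quantile level falls near an atom boundary; the test suite
  checks Monte-Carlo/enumeration agreement up to that discreteness.

## Change coefficients

With group mean PRs (treated, control), *DPR* = PR_treated − PR_control:

- **FC** = PR_treated/PR_control; ratios below 1 are reported as −1/ratio,
  so |FC| ≥ 1 with +1 meaning no change; a zero in exactly one group gives
  ±∞; both zero is undefined. FC is reported because it is the conventional
  abundance statistic, and it degenerates exactly where dual-stain data
  live: group-unique spots.
- **RC** = DPR/|DPRₘₐₓ|, with DPRₘₐₓ the maximum signed DPR over the
  analyzed set, so RC ∈ [−1, +1] and the largest positive change gets
  exactly +1. By default the scaling set is the significant spots
  (configurable to all analyzed spots); on the reference dataset the
  significant set reproduces the published coefficients with DPRₘₐₓ = 0.94.
  Corner case: if the largest-magnitude change is negative the literal
  formula would leave RC unbounded, so the denominator falls back to
  max |DPR| (with a warning); signs are always preserved.

## Group-level statistics

Spot counts per group (reproducible, phospho-positive, shared, unique) obey
the identities asserted in code. Proportions of phospho-positive spots are
compared with a two-tailed Fisher exact test (sum-of-small-probabilities
convention — the dominant one; delegated to scipy and cross-checked in the
tests against exact rational enumeration). Mean-PR columns are compared
with a two-tailed Mann-Whitney U test: exact by enumeration for combined
n ≤ 12 without ties, otherwise the tie-corrected normal approximation.

## UPGMA clustering

Significant spots are clustered on *d(i, j) = ||RCᵢ| − |RCⱼ||*. Absolute
values are compared because a strong-change cluster legitimately mixes
directions: a spot unique to either group changes maximally, with opposite
RC signs (a signed-difference metric is available as an option). UPGMA
merges the closest pair at height d/2 and updates distances as the
size-weighted mean of cross pairs; ties break deterministically by the
lexicographically smallest member labels, producing an ultrametric,
permutation-invariant tree (cross-checked against scipy average linkage and
a brute-force re-averaging oracle). Cutting at the root yields the two
major clusters; cluster mean |RC| gets a BC bootstrap CI, by default at
99% (95% Bonferroni-adjusted is the supported alternative; with two
clusters the two conventions nearly coincide). Since the metric is 1-D,
clusters are always contiguous intervals of the sorted |RC| values — which
also means published cluster memberships computed from unrounded
coefficients need not be exactly reproducible from 2-decimal tables.

## Synthetic data generator

The generator emulates image-normalized dual-stain exports: per-spot
lognormal baseline total volumes (log-mean 8.0 ≈ 3000 units, log-SD 1.0,
matching the spread of ppm-normalized volumes over ~300 spots); per-gel ×
channel residual lognormal factors (SD 0.05 on the log scale — variation
left over *after* normalization); mean-one lognormal measurement noise
parameterized by a CV (default 0.1); per spot × group true phosphorylation
fractions (the noise-free PR) and detection probabilities (default 0.95;
missing measurements are missing rows). A spot's phospho channel is emitted
only when its fraction is positive. The `paper_like` preset mirrors the
reference study's bookkeeping: 320 spots, 46/41 phospho-positive (28
shared, 18/13 unique, the unique true fractions taken from the reference
mean PRs), one shared strongly-changed spot (0.08 vs 0.36), 27 shared null
spots, and group-absent spots tuned so ~314/~308 spots are reproducible per
group. Ground-truth significance labels use |Δfraction| ≥ 0.1 by default.

What the generator does *not* model: gel images and spot-matching errors,
correlated abundances between spots, heavier-tailed biological
replicate-to-replicate variation (the reference data's standard errors
suggest replicate CVs of 20–70%, larger than the default measurement CV),
or channel-specific response curves. Passing recovery tests therefore
demonstrate internal consistency of the pipeline under a plausible noise
model, not performance guarantees on any particular instrument's data.

A deliberate scale choice: generated tables are treated as already
channel-normalized, and the canonical synthetic pipeline does not re-run
total-valid-spot normalization. Re-normalizing per channel rescales every
PR in a gel by the gel's total-to-phospho signal-sum ratio; when the two
groups differ in phospho composition (they do, by design, in `paper_like`)
this injects a systematic between-group PR scale bias. That bias is an
inherent property of per-channel total normalization applied to dual-stain
ratios — worth knowing when analyzing real exports — and deliberately kept
out of the truth-recovery conditions, where it would corrupt null spots.
Normalization remains available (`--normalize`) for raw, unnormalized
imports.

## Reproducibility and sizes

All randomness flows through seeded numpy generators; identical
configuration and seed give byte-identical outputs (file headers carry the
config hash and seed, never timestamps). Default problem sizes — 320-spot
scenarios, 20,000 bootstrap resamples, 50-seed recovery experiments, exact
enumeration oracles at N = 4 and ≤ 5 leaves — are chosen so the whole
validation suite runs on a laptop in well under a minute per component.

## Known limitations

- The significance rule (CI non-overlap / CL > 0) is an inference from how
  adjusted simultaneous CIs are conventionally reported, not a uniquely
  determined procedure.
- Bonferroni over m spots is intentionally conservative; no FDR alternative
  is offered.
- The bootstrap at N = 4 is coarse (256 atoms): intervals are range-limited
  and quantiles discrete, with the consequences described above.
- Reported two-decimal tables cannot always be reproduced exactly from
  other rounded tables; recomputation from rounded inputs can differ by one
  unit in the last printed digit.
- No phosphosite-level inference; identification tables serve only as spot
  labels.
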