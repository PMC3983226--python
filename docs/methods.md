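# Methods

## Model

The unit of observation is a *kinase-substrate prediction*: a normalized
log score for one (phosphosite, kinase) pair. For each kinase the package
compares the empirical distribution of its scores on regulated sites
against its scores on a proteome-wide background of non-regulated sites
using the two-sample Kolmogorov–Smirnov (KS) statistics. The working
hypothesis is distributional: a kinase whose activity rose should be
over-represented among high-scoring predictions on the regulated set,
shifting that score distribution upward relative to its own background;
a kinase whose activity fell should show the opposite shift.

With right-continuous ECDFs F_x (regulated, n sites) and F_y (background,
m sites), evaluated at the pooled jump points:

- D⁺ = sup_t [F_y(t) − F_x(t)], large when regulated scores are
  stochastically larger (activation);
- D⁻ = sup_t [F_x(t) − F_y(t)] (inhibition);
- D = max(D⁺, D⁻).

Two-sided p-values use the Kolmogorov asymptotic series
Q(λ) = 2 Σ_{k≥1} (−1)^{k−1} exp(−2k²λ²) with the small-sample correction
λ = (√ne + 0.12 + 0.11/√ne)·D, ne = nm/(n+m), truncated when terms fall
below 1e−12 and clamped to (0, 1]. One-sided p-values use
exp(−2·ne·D_side²). An exact permutation route
(`ks_pvalue_permutation`) enumerates all C(n+m, n) assignments when
n+m ≤ 12 and otherwise samples with the add-one estimator
(1 + #hits)/(1 + #permutations); it serves as the oracle for the
analytic routes in the tests.

Family-wise control is Benjamini–Hochberg step-up over the two-sided
p-values of all tested kinases. A kinase is called **activated** when
q ≤ α and D⁺ > D⁻, **inhibited** when q ≤ α and D⁻ > D⁺, otherwise
**unchanged**; kinases with fewer than `min_sites` regulated predictions
are reported as `insufficient_data` and excluded from the BH family.

## Score normalization

Raw predictor scores are kinase-specific and mutually incomparable. Each
raw score is mapped against its kinase's proteome-wide raw-score
background of size N:

s = −log10( (#background ≥ raw + 1) / (N + 1) ).

Ties with background values count as exceedances (the conservative
choice) and the add-one term keeps s finite above the whole background.
The transform is rank-based, hence invariant under any strictly monotone
rescaling of raw scores, and under the null the normalized score obeys
P(s ≥ t) = 10^(−t) — i.e. s ~ Exp(ln 10) — identically for every kinase,
which is what makes cross-kinase pooling and a common background law
meaningful. A background floor (default 1000 values per kinase) ensures
percentile resolution up to s ≈ 3.

## Study merging and borderline curation

Phosphosite tables are merged on the (protein, position, residue) key
after optional identifier mapping into one accession namespace (mixed
namespaces raise an error rather than silently producing an empty
overlap). A *borderline* site is regulated in condition C in one study
and detected in C — with a recorded fold-change — but not called
regulated in the other. It is promoted to regulated iff that recorded
fold-change is **strictly greater** than `fold_threshold` (default 1.4).
Merging is otherwise a union: a site regulated in either study stays
regulated in the merged collection. An optional `demote_unconfirmed=True`
instead removes the flag when the second study fails to confirm;
promotion-only is the default because it preserves the additive
arithmetic of combined counts. Sites whose conflict carries no recorded
fold-change cannot be examined and are left as flagged by the reporting
study.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| `alpha` | 0.005 | stringent adjusted threshold; with ~120 tested kinases it keeps the expected number of false active calls per run below one (verified by simulation) |
| `min_sites` | 5 | below ~5 regulated predictions the KS statistic is too coarse (D quantized in steps of 1/n) for a meaningful call |
| `fold_threshold` | 1.4 | borderline promotion cut; strictly-greater semantics so a fold of exactly 1.4 does not promote |
| background floor | 1000 | percentile resolution to s ≈ 3 (10^−3 exceedance) |
| bin width (histograms) | 0.25 | quarter-decade resolution on the −log10 scale |

## Synthetic data: what it does and does not emulate

`SyntheticSpec` generates per-kinase proteome backgrounds (default 9500
sites, lognormal raw scores — though any strictly positive law gives
identical normalized scores, which the tests verify), self-normalized
background predictions, and regulated sets whose normalized scores are
location-shifted by a planted per-kinase amount (clamped at 0). It
emulates the *statistical geometry* of the problem: sample sizes, the
null score law, realistic effect sizes, kinome-scale multiplicity.

`generate_phosphosite_fixture` builds a deterministic two-study site-table
pair whose counts (totals, overlaps, borderline outcomes, residue and
multiplicity composition) match a published two-study integration,
serving as a reproducible stand-in for supplementary tables that cannot
be redistributed. `quantile_profile_samples` plays the analogous role for
archived per-kinase KS inputs: noise-free quantile grids of the null law,
with planted shifts, so classification counts are exactly reproducible.

Not emulated: sequence motifs (the `MotifModel` scorer is a toy test
double, not a predictor), correlations between kinases sharing substrate
sites, peptide-level detectability biases, fold-change error structure,
and site-localization uncertainty.

## Numerical choices

- ECDF suprema are computed at pooled jump points with `searchsorted`
  (O((n+m) log(n+m))), never on a grid.
- The Kolmogorov series is truncated at term < 1e−12; p-values clamped
  to (0, 1].
- Exceedance counting uses `searchsorted(side="left")` on the sorted
  background, so ties count as exceedances.
- Table IO round-trips floats exactly (`float_precision="round_trip"`),
  keeping rank-based statistics identical across write/read cycles.
- All generators use `numpy.random.default_rng` with
  `SeedSequence([seed, stream])` so sub-streams are independent and runs
  fully reproducible.
- BH is computed by the reverse-cummin construction in the sorted order
  and mapped back to input order.

## Limitations

- The KS test detects any distributional difference; the direction call
  (dominant one-sided statistic) is a heuristic summary, and mixed
  up/down substrate populations for one kinase can be misdirected.
- Scores on regulated sites are treated as independent draws; sites
  shared by paralogous kinases violate independence across kinases, so
  BH controls FDR only under the usual positive-dependence caveats.
- The asymptotic two-sided p-value is accurate near the decision
  threshold but deviates from the exact permutation distribution at
  mid-range p for small samples; calls at α = 0.005 are unaffected (the
  tests quantify this against exact enumeration).
- Normalization assumes the background is a fair sample of the
  non-regulated proteome for every kinase; compositional bias in the
  background propagates directly into the calls.
- The merge step trusts the source studies' site localization and
  regulation calls; it curates only the borderline overlap and never
  re-evaluates evidence.
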