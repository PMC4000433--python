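# Methods

## Model and procedure

`ofdr` tests `m` hypothesis sets. Set `i` holds a screening null `H_0(i)` —
the conjunction of the set's individual nulls — and `n(i)` individual
two-sided nulls with p-values `p_j(i)` and signed statistics. The general
two-step procedure applies BH at level `α` to screening p-values
`p_0(1)..p_0(m)`, then tests individual hypotheses inside each of the `R`
rejected sets with an FWER-controlling procedure at level `Rα/m`. Individual
hypotheses in unrejected sets are never tested (with `R = 0` the within-set
level would be 0, so step two is skipped outright).

Three instantiations are provided. The Bonferroni- and Holm-based variants
screen with `p_0(i) = n(i)·p_(1)(i)`; the Hochberg-based variant screens with
`p_0(i) = min_j (n(i)+1−j)·p_(j)(i)`, which never exceeds the Bonferroni
value, so its screened-in set is a superset. The second stage applies the
matching FWER procedure. All three control the OFDR, and — because
Bonferroni, Holm and Hochberg also control directional (type III) errors for
independent two-sided statistics — the mdFDR, at level `α` under independence
across sets. Hochberg's method additionally needs independence or positive
dependence *within* a set; for ordered-category contrasts sharing a baseline,
positive dependence is the natural expectation.

Directions are declared as the sign of the test statistic of each rejected
hypothesis. A rejected hypothesis with a zero statistic (measure zero for
continuous statistics) gets no direction and triggers a warning.

### Error metrics

Per replication with known truth: `R` rejected sets, `V` falsely rejected
sets (some true null inside rejected — the screening null counts, so a
rejected set with no false individual null is automatically in `V`), and `S`
correctly rejected sets with at least one directional error among their
rejected hypotheses. `V` and `S` are disjoint by construction, so the
realized proportions satisfy `V/max(R,1) ≤ (V+S)/max(R,1)` on every
replication, not only in expectation. Aggregation across replications is the
mean of per-replication proportions, with standard error `sd/√n_reps` —
matching the defining expectations.

Power (I) is the fraction of false individual nulls rejected *with the
correct declared direction*; power (II) the fraction of false-null sets whose
within-set decisions are entirely correct (every false null rejected with the
right direction, no true null rejected). Counting a wrong-direction rejection
as a success is the other defensible reading of "correctly rejected"; both
metrics expose it via `require_direction=False`. The direction-strict default
is the one consistent with a framework whose point is penalizing directional
errors.

## Numerical and tie-breaking choices

- Screening p-values are clipped to 1 for reporting; the clip never changes a
  BH decision since all BH thresholds are below `α < 1`.
- All step rules use `≤` comparisons, exactly as in the formal step-up /
  step-down definitions. Ties therefore cannot straddle a decision boundary:
  if `p_(k) = p_(k+1)` and index `k` satisfies its threshold, index `k+1`
  satisfies its own (the thresholds grow along the walk), so tied p-values
  are rejected or retained together and "reject the k smallest" coincides
  with "reject every p ≤ p_(k)". The vectorized implementations use the
  latter form; the test suite checks exact agreement with literal loop
  transcriptions of the textbook definitions and with statsmodels'
  `multipletests` on exhaustive small grids.
- BH, the three FWER procedures, and the error metrics are implemented twice
  internally: a per-set path for ragged collections (varying `n(i)`) and a
  vectorized matrix path used when all sets share a size. The two are
  asserted equal on random inputs.
- `simple_bh` (the pooled one-step comparator) has no screening p-value of
  its own; the reported per-set `p0` is the smallest BH-adjusted p-value in
  the set, preserving `rejected(i) ⇔ p0(i) ≤ α`. Its guarantee of rejecting
  at least as many sets as the Bonferroni-based two-step procedure holds for
  constant set size (the relevant design); with ragged sets a singleton set
  can screen in on a looser per-set threshold than the pooled one, and the
  test suite only asserts the constant-size claim.

## Synthetic data generator

The generator emulates a one-sample-per-time-point microarray time course:
`Z_ji ~ N(μ_ji, 1)` for time points `j = 1..6` and genes `i = 1..m`,
independent across time points, equicorrelated with coefficient `ρ` across
genes within a time point. Successive standardized differences
`δ_ij = (μ_{j+1,i} − μ_ji)/√2` define the q = 5 individual hypotheses; the
statistic `T_ij = (Z_{j+1,i} − Z_ji)/√2` is `N(δ_ij, 1)` with p-value
`2{1 − Φ(|T_ij|)}`. The √2 divisor is what makes a unit-variance difference
of two unit-variance observations, hence a standard normal null — stated
explicitly because the difference is sometimes typeset as a plain `/2`,
which would be inconsistent with the p-value formula.

Defaults are the study conditions: m = 1000 genes, α = 0.05, 1000
replications, `m − m0` false-null genes assigned 50%/25%/25% to effect
intervals (−0.75, 0.75), (−4.25, −2.75), (2.75, 4.25), each gene's q
components drawn i.i.d. uniform from its interval. Choices the design left
open, fixed here once:

- which genes are false null: uniformly at random each replication
  (exchangeable, hence immaterial to the aggregate metrics);
- mixture sizes when `m − m0` is not divisible: largest-remainder
  apportionment, remainder ties broken by the seeded generator;
- `μ_1 = 0` baseline (only differences matter);
- equicorrelation sampled by the single-factor construction
  `Z_j = μ_j + √ρ·W_j·1 + √(1−ρ)·ε_j` — exact in distribution, O(m) per
  draw instead of an m×m Cholesky;
- the false-null-gene grid for sweeps: 11 evenly spaced points from 0 to m by
  default, configurable (`run_m0_sweep`).

One seed sequence per experiment spawns per-replication substreams, so all
methods see identical data within a replication (common random numbers) and
results are bit-reproducible given a seed.

Note that the first interval (−0.75, 0.75) produces *weak but nonzero*
effects: under it every individual null is false almost surely, with signs
mixed within the gene. These genes drive the directional-error count `S` —
and keep the mdFDR strictly positive even when every gene is false null —
while the two outer intervals give strong, sign-consistent effects that are
essentially always detected.

What the generator does not emulate: replicate-level noise within a time
point (one draw per gene per time point), heavy-tailed or heteroskedastic
expression noise, correlation across time points, and realistic effect-size
distributions. Passing tests therefore demonstrate the procedures' operating
characteristics under the stated Gaussian equicorrelated design, not
performance on any particular real platform.

## Ordered-category front-end

`ofdr.apply` forms per-gene hypothesis sets from an expression matrix with
ordered sample categories, in either successive (`j+1` vs `j`) or baseline
(each vs first) contrast designs. Per contrast it runs a two-sample t-test —
Welch by default, since expression variance rarely matches across conditions;
pooled-variance by flag — taking the sign of (later − earlier/baseline) mean
difference, so +1 means induced. A contrast with fewer than two non-missing
replicates on a side is reported as `p = 1`, sign 0, with a warning
(conservative); two zero-variance groups with equal means likewise. Genes
whose significant contrasts all point up are called `induced`, all down
`suppressed`, otherwise `mixed`; the per-gene count of significant contrasts
is tabulated as a dose-sensitivity distribution. Normalization, probe-gene
mapping, fold-change filters and variance-moderated statistics are out of
scope; values are assumed log-scale and normalized.

## Problem sizes used in the checks

The statistical acceptance checks run the full design (m = 1000, q = 5) at
200 replications per grid point over false-null-gene counts
{0, 250, 500, 750, 1000} and ρ ∈ {0, 0.2, 0.5, 0.8} — enough for the
three-sigma error-rate margins they assert. `scripts/acceptance.py` uses the
full 1000 replications. FWER and uniformity spot-checks use 10⁵ draws.

## Known limitations

- OFDR/mdFDR control is proved under independence across sets; positive
  equicorrelation is covered empirically (the Monte-Carlo sweep shows the
  mdFDR falling, not rising, with ρ) but no guarantee is offered for
  arbitrary dependence, and no Benjamini–Yekutieli-style correction is
  implemented.
- The Simes-based second stage is deliberately absent: it does not control
  the FWER, hence breaks the mdFDR guarantee.
- Power (II) inherits Monte-Carlo noise from being a per-set all-or-nothing
  statistic; at small effect sizes its estimates are low and comparatively
  variable.
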