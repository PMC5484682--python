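# Methods

## Model and procedure

The pipeline targets cohorts stratified on an ordinal severity axis
(healthy control → uncomplicated → complicated disease, coded 0/1/2).
Severity association of each expression feature is measured by Spearman's
rank correlation against the severity code. Because the severity axis has
only three distinct values, ties dominate one side of every correlation;
the statistic is therefore computed as the Pearson correlation of mid-ranks
(average ranks for ties), never via the tie-free Σd² shortcut, which is
invalid under ties. The equal 0/1/2 spacing carries no assumption: Spearman
uses only rank order. Two-sided p-values use the asymptotic
t = ρ√((n−2)/(1−ρ²)) approximation on n−2 degrees of freedom, which is
standard at the cohort sizes the screen targets (n ≈ 60–80); no exact
permutation option is provided. Multiplicity is controlled by
Benjamini–Hochberg step-up adjustment; the adjustment family is the set of
non-constant features surviving the presence filter on that platform
(post-filter, not the raw platform), a choice that is documented rather
than derivable. All threshold comparisons are strict (`adj_p < alpha`),
with `alpha >= 1` treated as "keep all tested features" since adjusted
p-values can equal 1 exactly.

Regulatory-pair integration keeps predicted bindings with mirSVR score
≤ −1.2 (inclusive: a pair printed as −1.201 at coarser precision must not
fall out under an exclusive rule), intersects them with the
screen-significant miRNAs and genes, and retains pairs whose miRNA and
target expression are negatively correlated with BH-adjusted p < 0.005.
The BH family for pair p-values is the candidate set after the DE
intersection. Pair correlation uses the sample intersection of the two
platforms — the miRNA and mRNA cohorts may differ (by default 13 vs 22
complicated-group samples), and the intersection is the only well-defined
choice. Duplicate target predictions collapse to the most negative score
(conservative for a ≤ cutoff); duplicate expression probes collapse to the
per-feature arithmetic mean (deterministic and order-independent).

The severity score of a signature with per-feature severity correlations
ρᵢ is S = Σᵢ sgn(ρᵢ)·(eᵢ−μᵢ)/τᵢ. Weights are the *sign* of ρ only, never
its magnitude, and ρ is the severity correlation from the screen, not the
pair correlation. τ is the sample standard deviation (n−1 denominator).
Standardization is transductive: μᵢ and τᵢ are recomputed on every cohort
being scored, cases included, rather than frozen from a training cohort.
This makes the score invariant to per-feature affine rescaling — the
property that lets one signature travel across array platforms — at the
price that a sample's score depends on the cohort it is embedded in.
Cross-platform application assumes shared feature symbols; features absent
from a cohort are dropped with a warning under the default missing-feature
policy (a strict `error` policy is available) and the achieved coverage is
recorded.

Evaluation follows the usual conventions: cases are the positive class and
higher scores are more disease-like; AUC is the Mann–Whitney formulation
with ties counted half; the two-group test is Welch's t (configurable to
Student); PCA standardizes the signature features first (they mix scales)
and fixes component signs so the loading of the first signature feature is
non-negative.

The resampling benchmark compares the signature's summed AUC over
validation cohorts with size-matched random signatures drawn without
replacement from either the whole feature universe shared by the cohorts
("genome" pool) or the severity-screened pool ("disease-related"). The
empirical right-tailed p uses the add-one rule (#{draws ≥ observed}+1)/(n+1),
so p > 0 always and draws tying the observed statistic count toward the
tail — both conservative. Random signatures need an orientation to be
scorable, which the procedure that inspired this package leaves unstated;
here each random feature's sign comes from its severity-screen ρ when
screen records are supplied, and otherwise from the sign of its
correlation with the cohort's own labels. The fallback gives random draws
their best-case orientation per cohort, biasing the benchmark *against*
the tested signature; calibration analyses must therefore supply
label-independent screen records, and the test suite's null-calibration
check does exactly that (signs from a screen on an independent surrogate
cohort), confirming a uniform p under no case shift.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes,
at sizes chosen for fast, well-powered tests:

- One discovery cohort of 35/17/22 (HC/US/CS) samples; the miRNA platform
  exposes 35/17/13 and the gene platform all 74, so pair correlation runs
  on the 65-sample intersection exactly as with real two-platform data.
- 300 miRNA features, 8 of them "signal": expression = baseline +
  direction·severity_effect·severity_code + N(0, noise_sd), with
  severity_effect = 1.5 (per severity step, in noise-SD units) and
  noise_sd = 1 by default.
- 1,000 gene features. Each signal miRNA has 2 planted target genes
  generated *conditionally on the miRNA's realized expression* with slope
  −coupling_strength (default 1), which guarantees the negative
  miRNA–target correlation and gives the target a severity association of
  opposite sign. A further 100 genes are severity-associated but coupled
  to no miRNA — the analogue of the large body of disease-related genes
  outside any miRNA-regulated signature; they populate the
  disease-related resampling pool (in the emulated study design that pool
  is ~90× the signature size).
- A prediction table in which planted pairs score uniformly in
  [−2.0, −1.2] and 200 decoy predictions (random non-planted pairs) score
  in (−1.2, −0.1], so the mirSVR filter partitions them exactly.
- Binary validation cohorts: case samples shift by sgn(ρᵢ)·shift on every
  signature feature, on top of 200 pure-noise background features.
- All noise is Gaussian on a log-expression scale; a single seeded
  generator drives every draw in documented order, so outputs are bitwise
  reproducible given the seed.

Not modelled: probe effects, batch structure, count-based sequencing
noise, detection-call computation, covariates (age/sex), or correlated
background genes. Passing tests therefore demonstrate that the *pipeline
logic* recovers planted structure under idealized noise at realistic
sample sizes — not that the thresholds are well calibrated for any real
array's noise. Detection masks default to all-true; an
`undetected_fraction` option plants missing calls to exercise the
presence filter, whose two-thirds boundary is inclusive.

## Numerical choices and degenerate inputs

- Constant features: the screen logs and excludes them (rho undefined)
  rather than failing; the score and standardizer raise a
  degenerate-input error; `spearman_rho` raises rather than returning NaN.
- p-values are clipped to [tiny, 1] before BH so that |ρ| = 1 (p = 0 under
  the t approximation) stays inside BH's domain.
- The presence-fraction comparison tolerates float representation of 2/3
  (detected/n ≥ fraction − 1e−12).
- TSV dialect: tab-separated, UTF-8, "." decimal, no quoting; Unicode
  minus is normalized to ASCII on read; writes use %.17g so round-trips
  are exact.
- Pipeline manifests contain no timestamps and are serialized with sorted
  keys, making rerun-identity checkable byte-for-byte; stage sub-seeds are
  small fixed offsets from the run seed.

## Known limitations

- The transductive μ/τ means single-sample scoring is undefined; a cohort
  of at least two samples with non-constant signature features is
  required.
- The disease-related resampling pool is only as meaningful as the
  severity screen feeding it; on data where the screen returns little more
  than the signature itself, the benchmark degenerates toward p = 1 by
  construction.
- The miRNA/mRNA sample-intersection rule discards severity information
  carried by samples profiled on one platform only.
- Identifier mapping across platforms is by literal symbol equality;
  probe-level annotation beyond a provided symbol column is out of scope.
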