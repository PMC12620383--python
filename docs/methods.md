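# Methods

This note records the statistical model, the synthetic data-generating
process, the numerical conventions, and the design decisions behind
`peermod`, in the spirit of a model-documentation page: enough detail to
re-derive every number the package produces.

## The moderated peer-influence model

The unit of analysis is one (outcome × peer group × peer-measurement wave ×
moderator) combination. For focal pupil *i* with follow-up outcome value
y₁, baseline value y₀, peer exposure x̄ (defined below) and moderator w, the
linear family fits

    y₁ = b0 + b1·x̄c + b2·wc + b3·(x̄c·wc) + γ'c + b4·y0c + ε

where the subscript c denotes mean-centering on the estimation sample
(continuous variables only; dichotomous moderators stay 0/1), the product is
formed *after* centering, and c collects the covariates: gender (0 = boy,
1 = girl or prefer-not-to-say), age band (three levels, two indicators),
intervention (two-level), ethnicity (binary), and individual SES (ordinal,
entered as indicators). The binary susceptibility outcome uses the logistic
analogue with the peer exposure expressed as a percentage. Rows with any
missing entry are deleted listwise per model; centering happens after
deletion. Covariates that are constant over the estimation sample (e.g.
intervention in a single-school subset) are dropped with a log message
rather than producing a rank-deficient design.

Inference is by Huber–White sandwich covariance. For OLS:
cov = (X'X)⁻¹ X' diag(wᵢeᵢ²) X (X'X)⁻¹ with HC1 weights n/(n−k) (HC0 and
HC3 available), and t-based p-values on n−k degrees of freedom. For the
logit, the fit is IRLS (convergence: max coefficient change < 1e-8, cap
100 iterations; coefficients passing |β| > 100 are flagged as perfect
separation and the model recorded as unfit), and the robust covariance is
the sandwich of score outer products around the inverse information with an
n/(n−1) factor; p-values are Wald z. HC1 is the default because it is the
customary default of the commercial package this style of analysis is most
often run in; the variant is configurable and logged.

Per model we also record: VIFs (1/(1−R²ⱼ), intercept excluded, flags at 5
and 10), the standardized interaction coefficient β_std = b3·SD(x̄)/SD(y)
(the difference, in outcome SDs, between conditional peer-effect slopes one
exposure-SD apart — linear family only), and ΔR², the R² gain of the full
model over the same-sample model without the product column.

### Peer exposures

Three peer groups: the pupils *i* nominated as friends (directed
out-neighbours of the nomination graph at the same wave as the peer
measurement), *i*'s school class excluding *i*, and *i*'s school year group
excluding *i*. The exposure is the mean of the peers' non-missing values
(nominated friends with missing values are excluded); for the binary
outcome, the percentage of contributing peers positive. An exposure with
zero contributing peers is missing, and the pupil drops out of the affected
model only. Whether "friendship network" should mean out-neighbours,
in-neighbours or their union is not determined by the data structure; the
out-neighbour convention (the friends *i* chose) is the default and is
recorded in output metadata.

### Network moderators

Per school and wave, the nomination digraph is projected to an undirected
graph (default: union — an edge if either pupil nominated the other;
intersection and directed available, logged). On that projection:

- local clustering: fraction of closed neighbour pairs, degree < 2 ⇒ 0;
- eigenvector centrality: leading eigenvector of the adjacency, unit
  Euclidean norm, non-negative; computed by power iteration on A + I (the
  shift makes the Perron root strictly dominant in magnitude, otherwise the
  iteration oscillates on bipartite components) to a 1e-14 step tolerance.
  On disconnected graphs the global leading eigenvector is reported: nodes
  outside the dominant component get ≈ 0, and when two components tie the
  uniform start vector spreads mass over the tied eigenspace; both
  behaviours are deliberate and tested;
- closeness: Wasserman–Faust component-adjusted form
  ((r−1)/Σd)·((r−1)/(n−1)); isolates 0;
- betweenness: shortest-path betweenness normalized by (n−1)(n−2)/2;
- school-level Gini coefficient of the degree sequence,
  G = Σᵢⱼ|dᵢ−dⱼ|/(2n²·d̄), computed via the sorted-sequence identity; an
  all-zero degree sequence is reported as 0 and logged.

All five are reported ×10 by default. That scaling is an interface
convention chosen to match the magnitudes conventional in the cohort
literature this package serves (clustering "0 to 10", closeness means
around 3.5, Gini around 2); it can be switched off (`scale_metrics: false`)
to obtain the raw definitions. Individual network moderators enter the grid
at the wave matching the peer measurement.

### Moderator recoding

School SES in the setting with a raw deprivation index is quartiled to an
ordinal 1–4 (1 = most deprived/lowest SES) with inclusive
linear-interpolation quantiles; scores tied with a boundary fall to the
lower category (logged). Any monotone deprivation measure is accepted; the
orientation flag handles rank-style indices where larger means less
deprived. Scale scores are means of items with a minimum-answered rule, and
reliability is Cronbach's alpha (complete-case, ddof = 1 variances; zero
total variance ⇒ missing with a warning).

## Aggregation across the grid

The default outcome battery has 46 entries (45 continuous + binary
susceptibility), so each moderator's grid is 46 × 3 peer groups × 2 waves =
276 models; a self-efficacy subscale moderator excludes the three
self-efficacy outcomes (258 models each, 774 over the three subscales), and
single-setting sensitivity grids restricted to friends are 46 × 2 = 92.
Models that fail to fit stay in the denominator as non-significant: the
grid size is fixed by design, and failures are recorded with reasons.

Per moderator we compute: counts of interactions with p ≤ 0.01 (total, by
peer group, and by sign of b3); the exact upper-tail binomial meta-test
P(X ≥ k), X ~ Binomial(n, 0.01), evaluated by log-space summation of the
binomial mass; directional binomial tests that use the full grid size n
(not k) as the denominator; and Holm–Bonferroni step-down flags at family
α = 0.05 (adjusted pᵢ = max over j ≤ i of min(1, (m−j+1)p₍ⱼ₎)). The
multiverse summaries report the p-value distribution, (β_std, −log₁₀ p)
volcano coordinates (logistic models excluded, having no outcome-SD
standardization), a per-(outcome, peer group, wave) grid, and heatmap cells
of percent-significant per moderator × outcome.

## Probing

The conditional peer effect at moderator value w is slope(w) = b1 + b3w
with Var = Var(b1) + w²Var(b3) + 2w·Cov(b1, b3), taken from the same robust
covariance used for fitting (internal consistency; classical covariance
would understate the uncertainty the fit itself reports). Simple slopes
default to levels 0/1 (dichotomous) or mean ± 1 SD (continuous, i.e. ±SD
after centering). Johnson–Neyman boundaries solve slope(w)² =
t²crit·Var(slope(w)), a quadratic in w, with tcrit from the model's
residual df (standard normal for the logit, where the machinery applies on
the log-odds scale). Boundaries are reported only within the observed
(centered) moderator range, as the region outside it is extrapolation;
exterior real roots are kept separately. Degenerate quadratics (b3 ≈ 0)
collapse to the constant-significance case.

## The synthetic cohort generator

The generator emulates the structure of a two-setting school cohort: 12
schools (6 per setting), per-setting class counts and sizes giving 54
classes and a 1,440-pupil roster by default, pupil attributes (gender, age
band, ethnicity, ordinal individual SES) drawn from realistic categorical
distributions, school SES quartiled from a simulated deprivation score in
one setting and assigned ordinally in the other, and dispositional
moderator scores from truncated normals with literature-typical means and
SDs. The 46 default outcome specifications carry the scale bounds and
baseline moments of the instruments they imitate (norms items on −1…1,
token donations 0–10, risk perceptions 0–100, susceptibility prevalence
≈ 34%).

Nominations: out-degree Poisson with configurable mean (default 5) capped
at 10 and at school size − 1, nominees restricted to the school year group,
sampling weights multiplied by a within-class ratio (default 4) and a
same-gender ratio (default 3); whole schools are sampled in one vectorized
Gumbel top-k step. Homophily ratios of 1 give exactly uniform nominee
choice.

Follow-up outcomes follow a linear autoregressive process: y₁ = μ +
a·(y₀−μ) + p·(x̄₀−μ) + m·s·w* + g·w*·(x̄₀−μ) + covariate terms + N(0,
(noise·s)²), truncated to the scale bounds, where μ and s are the outcome's
baseline mean and SD, x̄₀ is the friend out-neighbour mean at baseline
(year-group mean for pupils without contributing friends, so the process is
defined for isolates), and w* is the standardized planted moderator.
Defaults: a = 0.5, p = 0.3, m = 0.05, g = 0.15, noise = 0.8 (all noise and
moderator terms in units of the outcome's baseline SD — one knob across
scales from [−1, 1] to [0, 100]). The binary outcome uses the logistic
analogue on the log-odds scale with the friend fraction as exposure.
Follow-up missingness is completely at random at the whole-instrument level
(default 7%, matching a ~93% participation rate); the analysis assumes
missingness is ignorable, and no informative-missingness machinery is
provided. Truncation (clipping) rather than resampling keeps the linear
interpretation of the process in the interior of the scale. Identical
(config, seed) gives byte-identical tables; all randomness flows from one
seed through named child streams.

The distributional forms (truncated normals, Poisson out-degrees, logistic
binary process) are stand-ins chosen for transparency, not claims about any
particular cohort. What passing tests on synthetic data do show: the
pipeline's estimators are unbiased and calibrated under a data-generating
process with the assumed structure. What they do not show: robustness to
informative missingness, selection homophily co-evolving with influence,
measurement error in nominations, or multilevel error structure (see
limitations).

An item-response helper (`generate_item_responses`) produces item matrices
consistent with given scale scores via a single-factor model (item =
λ·latent + (1−λ)·noise), giving a closed-form expected inter-item
correlation λ²/(λ²+(1−λ)²) for validating reliability computations.

## Verification and problem sizes

The test suite verifies each stage against an independent oracle: OLS/HC
and logit fits against statsmodels and hand matrix algebra (1,000 random
small designs); Johnson–Neyman boundaries against a 100,000-point grid scan
of the conditional t-statistic (100 random fits); network metrics against
dense eigendecomposition, BFS, and exhaustive path enumeration on every
non-isomorphic graph with ≤ 7 nodes plus a seeded sample of 8-node graphs
(when the leading eigenvalue is (near-)degenerate the eigenvector is only
identified up to its eigenspace, so the check switches to the
eigen-residual); Holm and the exact binomial test against
statsmodels/scipy.

Two Monte-Carlo checks exercise the whole chain. Type-I calibration: 220
replicate cohorts (two schools, ~200 pupils, three wide-bounded outcomes)
with the planted interaction set to zero; the fraction of interaction
p-values ≤ 0.01 across the 3,960 tests is checked for consistency with 1%
and the per-replicate meta-test must be non-significant in ≥ 95% of
replicates. Recovery: cohorts of ~2,000 pupils, planted interactions of
0.1/0.3/0.5, 200 seeds each; the mean estimate must sit within twice the
Monte-Carlo standard error of the truth and meta-test power must rise
monotonically in effect size. These checks use wide scale bounds (±8 SD) so
that truncation cannot bias the linear-model comparisons, and a
standard-normal planted moderator so the raw regression coefficient equals
the planted value; both choices are part of the checks' design, and the
stated replicate counts keep the full suite in the minutes range.

## Known limitations

- Single-level inference. Pupils are clustered in classes and schools, but
  the models use pupil-level robust SEs, not cluster-robust or multilevel
  ones. For pupil-level moderators the interaction test is well calibrated
  (the calibration check above); for school-level moderators (setting,
  school SES, Gini) the clustered outcome structure inflates the type-I
  rate of the interaction test above nominal, which is visible in synthetic
  runs with no planted school-level moderation. Meta-test conclusions about
  school-level moderators should therefore be read as descriptive, and the
  per-moderator summaries keep the full p-value distribution available for
  exactly this reason.
- Missingness is assumed ignorable (MCAR in the generator; listwise
  deletion in the models).
- No selection-vs-influence decomposition: friendship formation is taken as
  given within each wave, and no co-evolution model is fitted.
- The exact centrality normalizations behind the 0–10 reporting convention
  are an inference from the magnitudes conventional in this literature, not
  a fixed standard; they are logged in output metadata and can be disabled.
- Directional conclusions label the sign of significant interaction
  coefficients; with mixed signs the summary reports "no indication of
  overall direction" rather than attempting effect pooling, which is out of
  scope.
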