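# Methods

## The model

The analysis treats one bidding experiment as a recursive linear system on
the DAG with nodes {label, sweetness, familiarity, healthiness, tastiness,
bid}. The label is the only exogenous treatment (1 = sugar-free member of a
product pair); the four ratings mediate its effect on the bid. The edge set
is the complete transitive order sweetness → familiarity → healthiness →
tastiness → bid with the label pointing into every node — 15 directed edges,
five regression equations. Sweetness precedes familiarity in the causal
order because familiarity's equation conditions on sweetness (consumers who
favour sweet snacks are more familiar with them), not the other way round.

Each equation is a linear mixed model with two *crossed* random
intercepts: subject (50 levels) and product pair (30 levels; the pair, not
the individual product, is the product-level grouping factor, because the
two members of a pair are near-identical items). Gender and age enter every
equation as exogenous controls; the position of the product in the
subject's bidding sequence (trial index) enters only the bid equation,
capturing drift over the session. There are no random slopes.

## Estimation

Node models are estimated by REML (an `ml` switch exists for comparing
AICs across fixed-effect structures). The solver (`sugarsem.lmm`) is
specialised to the two-crossed-intercepts structure: the likelihood is
profiled over the fixed effects and the residual variance and optimised
over the two variance ratios γ_g = σ_g²/σ² on the log scale, with the
Woodbury identity reducing each evaluation to O((q_s+q_p)³). This makes
the bootstrap and calibration studies (tens of thousands of refits)
tractable; the test suite verifies agreement with a general mixed-model
solver (statsmodels `MixedLM` with variance-component formulas) on a
synthetic fixture — fixed effects to 1e-4 relative (observed ~1e-8), and
our profiled optimum is never worse than the general solver's.

Wald inference uses a standard-normal reference for the coefficient
t-statistics. With 3,000 observations and 80 random-effect levels the
difference from a Satterthwaite-style t reference is negligible;
Satterthwaite degrees of freedom are deliberately out of scope. A variance
ratio that collapses below 1e-6 is reported as a boundary ("singular") fit
warning on the result, never as an exception; a rank-deficient fixed-effect
design raises an error naming the collinear columns.

## Tests of directed separation and Fisher's C

The basis set is built over the structural nodes plus the controls
(controls act as exogenous parents of the equations they enter). For every
non-adjacent pair — excluding pairs of two exogenous variables, whose
association the model does not constrain — the claim is tested by refitting
the downstream member's mixed model with the other member added and reading
off its Wald p-value; the response is the member that is not an ancestor of
the other. For the default graph this yields exactly four claims, pairing
the trial index with each rating. Fisher's C = −2 Σ ln pᵢ is referred to
χ²(2k); an empty basis set returns C = 0, df = 0, p = 1 by convention, and
an exact zero p-value is rejected as evidence of a degenerate test.

## Effect decomposition and bootstrap

Effects are raw (unstandardized) coefficient products by default: on a
linear recursive system the total effect of source on target equals the sum
over all directed paths of the product of edge coefficients, so
total = direct + indirect holds to machine precision by construction. A
standardization switch multiplies each edge coefficient by
sd(predictor)/sd(response) using observed SDs. Per-mediator effects sum the
contributions of all paths whose interior contains the mediator; since a
path may contain several mediators these sums overlap and need not add up
to the indirect effect — they answer "how much flows through this node",
not "how does the indirect effect partition".

Confidence intervals are percentile bounds (2.5%/97.5%) from a cluster
bootstrap with the subject as the resampling unit (the experiment's
sampling unit; product-pair resampling is available behind a flag). Each
resampled cluster keeps its full trial block and duplicates get fresh
identifiers so they are distinct random-effect levels. Replicate refits are
warm-started at the full-data variance ratios and skip the final
derivative-free polish of the optimizer — CI quantiles do not depend on the
last digits of the variance ratios — while point estimates and d-sep tests
always use the fully polished fit. A failed replicate is dropped with a
warning; more than 5% failures aborts the bootstrap. An effect is flagged
significant when its CI excludes zero. Known limitation: percentile CIs
undercover when the number of resampled clusters is small (an exploratory
run with 24 subjects gave ~86% coverage for a nominal 95% interval); at the
design's 50 subjects measured coverage is ~96%.

## The synthetic-data generator

The generator emulates the study conditions: 50 subjects (21 male coded 0,
29 female coded 1; integer ages from a normal(26.2, 6.9) truncated to
[18, 51]), 30 product pairs (60 products), one record per subject × product
(3,000), and a uniform random bidding order per subject. Responses are
drawn equation by equation in topological order, each adding its intercept,
edge and control terms, the subject and pair intercepts for that equation,
and Gaussian residual noise. Edge and control coefficients default to the
study's fitted point estimates, so the generator and the estimator form a
closed loop with known ground truth.

The study does not report variance components, so the defaults are the
package's own choice, fixed once: residual SD 1.0, subject SD 0.4, pair SD
0.25 for the rating equations, and 25 / 12 / 6 MU for the bid equation.
These give rating dispersions of about 1.1–1.2 Likert points and bid SDs
near 30 MU, comparable to the observed summaries, and they are fully
config-exposed.

Two value modes exist. The default is *latent*: responses stay continuous,
which is what the recovery tests need, since rounding and clipping bias
linear fits. The *discretized* mode rounds ratings to integers clipped to
[1, 5] and bids to integers clipped to [0, 150], reproducing the observable
scales for demonstrations and robustness checks. What the generator does
not emulate: ordinal response processes (ratings are linear-Gaussian, as in
the analysis being validated), response times, label-onset timing,
heteroscedasticity, and any subject × product interaction beyond the two
random intercepts. Passing tests therefore show that the inference
machinery is correct under its own assumptions, not that those assumptions
hold for real consumers.

Age enters the equations in raw years (not centered), matching the most
literal reading of the reported intercepts; a centering flag exists.
Gender coding (0 = male, 1 = female) is a package convention — the source
data's coding is unstated, which is what the schema-mapping argument of the
reader is for.

## Numerical and degenerate-input choices

- Optimisation: L-BFGS-B on (log γ_s, log γ_p) with bounds [−16, 12],
  started at γ = 0.1, followed by a Nelder-Mead polish; deterministic, so
  refits on identical data are bit-identical.
- The BDM expected payoff is computed with integer arithmetic before a
  single division by 150, so the truthfulness proof is exact; the bid = value
  and bid = value − 1 strategies tie exactly (buying at a capsule price equal
  to one's value yields zero surplus) and the tie is resolved to the value.
- The capsule support is {1, …, 150}: a bid of b wins for exactly b capsule
  values, so the purchase probability is b/150 and a zero bid never wins.
- Wilcoxon: zero differences excluded (classical treatment, not Pratt);
  exact null distribution for n ≤ 25 without ties, else normal
  approximation with tie correction.
- Cronbach's alpha uses unbiased (n−1) variances; subjects are the cases
  and the products of one label condition the items, computed per rating
  scale and condition and averaged over the two conditions. Zero
  total-score variance is an error; negative alpha (anti-correlated items)
  is returned, not masked.
- Pairing for the condition comparisons: per-subject means over the
  products of each condition (n = 50 pairs).
- The fully noiseless limit (every variance component zero) makes each
  mediator an exact linear function of label, gender and age, so any
  downstream design matrix is rank-deficient and those coefficients are not
  identified; exact-recovery checks therefore zero the noise of one
  response equation at a time (exact interpolation of that equation), which
  is the well-posed form of the limit.

## Validation-study scales

The package's simulation studies use the following problem sizes, chosen
to exercise each property at meaningful precision:

- Parameter recovery: 20 replicates of the full 50 × 30 design (seeds 1–20
  in the test suite; seeds derived from the CLI seed in
  `scripts/acceptance.py`), comparing replicate-mean coefficients to the
  generating values within 3 Monte-Carlo SEs.
- d-separation calibration: 200 replicates of a 20-subject × 10-pair
  design; per-claim KS uniformity tests at α = 0.01 and the size of
  Fisher's C at the 5% level within 3 binomial SEs.
- Bootstrap coverage: 50 replicates of a 50-subject × 6-pair design with
  200 bootstrap draws each, checking 90–98% empirical coverage of the
  generating label → sweetness effect by the nominal 95% interval.
- Paired-t size: 500 replicates of a 20-subject × 8-pair design with all
  label coefficients zeroed.
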