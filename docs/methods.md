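# Methods

`tsdea` implements a three-stage efficiency analysis for panels of
decision-making units (DMUs): input-oriented data envelopment analysis (DEA),
a stochastic-frontier (SFA) regression that strips environmental and random
effects out of the measured input slacks, and a second DEA pass on the
adjusted inputs.  The motivating application is the operational efficiency of
basic medical insurance across 31 Chinese provinces observed 2017–2020, with
three inputs (fund income, health technicians, government health expenditure),
three outputs (fund expenditure, epidemic morbidity rate, resident health
insurance expenditure) and three environmental covariates (GDP per capita,
social security and employment expenditure, fiscal revenue/expenditure ratio).

## Stage 1 — DEA envelopment models

For a target DMU with inputs `x0` and outputs `y0` in a one-period
cross-section `(X, Y)` of n DMUs, the input-oriented envelopment program is

    min  theta
    s.t. X' lam + S- = theta x0
         Y' lam - S+ = y0
         sum(lam) = 1          (VRS / BCC only)
         lam, S-, S+ >= 0.

Technical efficiency (TE) is the CRS (CCR) optimum, pure technical efficiency
(PTE) the VRS (BCC) optimum, and scale efficiency SE = TE/PTE, so
TE = PTE × SE holds by construction.  The convexity constraint defines the
BCC model and is imposed only in VRS mode; a separate CRS solve is required
for the decomposition to be meaningful.

Slacks are maximised in a second LP at the fixed optimal `theta` (two-phase
method).  This is the numerically robust version of the textbook
non-Archimedean objective `min theta − eps(e'S− + e'S+)`; the single-LP
epsilon mode is retained (default `eps = 1e-6`) and agrees with the two-phase
`theta` to LP tolerance, because the epsilon term cannot move `theta` off its
phase-1 optimum at a vertex.  DMUs are classified *valid* (theta = 1, zero
slack), *weakly valid* (theta = 1, some slack) or *invalid* (theta < 1) with
a frontier-membership tolerance of `1e-6`, since LP solvers return scores
like 0.9999999997 for frontier units.  Intensity weights `lam` may have
alternate optima; only `theta`, total slacks and the validity class are
treated as deterministic outputs.

The total slack passed to stage 2 is the full radial-plus-residual input
reduction `x − X'lam = (1 − theta)x + S−`, per input.  DEA is solved per
period as a cross-section, never pooled across years.

LPs are solved with `scipy.optimize.linprog` (HiGHS).  When phase 2 is
declared infeasible at exactly the phase-1 optimum, the input constraint is
relaxed by bumps up to `1e-7` before erroring.

## Stage 2 — slack regression and harmonisation

Each input's total slack is modelled with a cost-frontier composed error

    s_i = z_i' beta + v_i + u_i,  v_i ~ N(0, sigma_v^2),  u_i ~ N+(0, sigma_u^2),

estimated by maximum likelihood in the Battese–Corra parameterization
(`sigma^2 = sigma_u^2 + sigma_v^2`, `gamma = sigma_u^2/sigma^2`).  One
independent regression is fitted per input on the pooled panel observations
(a per-year mode exists behind a config switch), with an intercept, and with
covariates z-scored internally for optimizer stability; coefficients are
reported on the raw scale.  Internally the likelihood is optimized over
`(beta, log sigma^2, logit gamma)` with an analytic gradient and L-BFGS-B,
from several starts: the OLS start, a moment start from the OLS residual
skewness, and a small gamma grid.  If no start beats the OLS log-likelihood,
the boundary MLE at `gamma = 0` — exactly the OLS solution — is returned
with a warning.  The one-sided LR statistic is `2(logL − logL_OLS)`, clipped
at zero, referred to the Kodde–Palm mixed chi-square (5% critical value
2.706).  Significance stars use asymptotic standard errors from a
central-difference Hessian with delta-method transforms; the raw-scale
intercept SE is approximated by the design-scale one (stars only, no
inferential claim).

Residuals are split with the JLMS conditional mean

    E[u | eps] = sigma_* (phi(a)/Phi(a) + a),   a = eps lam / sigma,
    lam = sigma_u/sigma_v,   sigma_* = sigma lam/(1 + lam^2),

with the Mills ratio evaluated through the scaled complementary error
function (`erfcx`), so that deeply negative residuals decay smoothly to the
asymptote `sigma_*^2/|mu_*|` instead of underflowing or cancelling.  The estimated noise is
`v_hat = eps − E[u|eps]`, and inputs are harmonised to the least favourable
environment and worst luck in the estimation sample:

    x*_i = x_i + [max_k z_k'beta − z_i'beta] + [max_k v_hat_k − v_hat_i].

Adjusted inputs never fall below the originals, and the observation attaining
both maxima is unchanged.  Stage 3 re-solves both CRS and VRS DEA on the
adjusted inputs with the original outputs.

A note on identification: slacks measured by DEA have a point mass at zero
(frontier units) and inherit the envelope's one-sided distortion, so `gamma`
fitted on DEA slacks is biased toward 1 even when the generating inefficiency
share is moderate.  This is a property of the three-stage design, not of the
estimator: on slacks drawn from the composed-error model itself the MLE
recovers `gamma` with median absolute error ≤ 0.15 at the panel's n = 124.
Downstream results depend on `z'beta` and `v_hat`, which remain usable.

## Synthetic panels

The generator instantiates the stage-2 model class exactly, so recovery
questions are well-posed: outputs uniform on configured ranges, efficient
inputs from a per-input Cobb-Douglas inverse frontier on the outputs,
environment with one persistent (GDP-like growth path) covariate, and

    x_obs = x_eff + scale·(c0 + beta·z~)_+ + u + v

with `u` half-normal and `v` Gaussian from a single normalised variance
(`sigma_sq_true`, default 0.02, times the squared input scale), `gamma_true`
= 0.7, and environmental coefficients of a few percent to ~10% of the input
scale with the signs of the motivating application.  Default dimensions are
31 units × 4 periods.  Input scales and covariate ranges match the yearbook
magnitudes; the *output* bands cover the central mass around the yearbook
means rather than the extreme provincial tails, because with a homoskedastic
additive slack a frontier spanning two orders of magnitude would make the
slack negligible for large units and overwhelming for small ones.  What the
generator therefore does **not** emulate: extreme size heterogeneity,
heteroskedastic slacks, spatial correlation between units, and any
calibration to the published provincial tables (impossible without the
undeposited yearbook microdata) — passing recovery tests show the pipeline
recovers the assumed model class, not that the published values are
reproduced.

The recorded truth holds every component (efficient input, environmental
contribution, u, v) plus a managerial efficiency defined radially, as the
contraction of `x_eff + u` onto `x_eff` determined by the binding input —
the analogue of what input-oriented DEA measures.  Observations whose drawn
inputs fall below a positivity floor are redrawn (noise only) up to a retry
cap and flagged; the additive identity is exact for all unflagged rows.

Under these conditions the stage-3 ranks beat the stage-1 ranks against the
truth in roughly 60% of seeds with a small mean gain — the environmental
signal is deliberately moderate, and per-period frontiers with 31 units in a
3×3 indicator space leave substantial envelope noise in both stages.

## Numerical and design choices

- The inefficiency distribution in the slack regression is half-normal; the
  conditional-mean estimator is JLMS, not the Battese–Coelli exponential
  form.
- Sample-standard-deviation convention (n−1) in descriptive tables;
  unadjusted two-sided Pearson p-values in the correlation screen, which is
  advisory (a warning below |r| = 0.2), not a gate.
- A unit is counted "on the frontier" when its across-period mean TE equals
  1 at 3 printed decimals.
- The epidemic-morbidity-like output is used as given; because a
  lower-is-better output violates DEA's output monotonicity, the CLI warns
  and offers `--invert-output K` (max − value plus 1% of the range, keeping
  positivity).  The generator's default draws it higher-is-better for
  coherence; a realistic lower-is-better mode exercises the inversion path.
- Slacks fed to stage 2 come from the VRS model by default (config switch
  for CRS).
- All seeds are explicit; the canonical default is 20171231.  Fixed seed and
  config reproduce every score to 1e-10 and every exported CSV byte for
  byte.
- Problem sizes in the test-suite simulations (50-seed end-to-end replicate
  set, 200-replicate null calibration, n = 500 recovery) were chosen to keep
  Monte-Carlo error well below the asserted margins while the full suite
  runs in minutes on one core.

## Known limitations

- Gamma fitted on DEA slacks is boundary-biased (see above); interpret the
  reported `gamma` qualitatively.
- The published provincial tables ship as verbatim fixtures for aggregation
  checks only; nothing in the package attempts to re-derive them from raw
  data.
- No bootstrap confidence intervals for DEA scores, no Malmquist indices, no
  super-efficiency or SBM variants, and no time-varying panel-SFA models.
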