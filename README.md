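# tsdea — three-stage DEA with stochastic-frontier slack adjustment

`tsdea` measures the technical efficiency of decision-making units (DMUs)
observed in a panel — the motivating application is the operational
efficiency of basic medical insurance across China's 31 provinces, 2017–2020,
with provincial fund income, health technicians and government health
expenditure as inputs and fund expenditure, epidemic morbidity rate and
resident health insurance expenditure as outputs — and removes the part of
measured inefficiency that is due to the operating environment or to luck
rather than to management.  It is aimed at health-systems and public-economics
researchers running DEAP/FRONTIER-style efficiency studies who want a single
scriptable, tested pipeline.

## The model

**Stage 1.** Input-oriented envelopment DEA per period: for DMU 0,

```
min θ   s.t.  Σ_j X_j λ_j + S⁻ = θ X₀,   Σ_j Y_j λ_j − S⁺ = Y₀,
              Σ_j λ_j = 1 (VRS only),    λ, S⁻, S⁺ ≥ 0,
```

giving TE (CRS/CCR), PTE (VRS/BCC) and scale efficiency SE = TE/PTE, so
TE = PTE × SE.  A DMU is DEA-valid iff θ = 1 with zero slacks.

**Stage 2.** Each input's total slack (radial plus residual,
`(1−θ)x + S⁻`) is regressed on environmental covariates z with a composed
error — noise v ~ N(0, σ_v²) plus half-normal inefficiency u ~ N⁺(0, σ_u²) —
by maximum likelihood in the Battese–Corra (σ², γ) parameterization.  The
residual is split by the JLMS conditional mean
E[u|ε] = σ\*(φ(a)/Φ(a) + a), a = ελ/σ, λ = σ_u/σ_v, and every input is
raised to the worst observed environment and worst luck:

```
x*ᵢ = xᵢ + [max_k z_k'β − zᵢ'β] + [max_k v̂_k − v̂ᵢ]  ≥  xᵢ.
```

**Stage 3.** DEA is re-run on the adjusted inputs with the original outputs;
the remaining inefficiency is attributable to management.

A synthetic-panel generator reproduces exactly this data-generating process
with recorded ground truth (frontier, u, v, environmental contribution), so
every stage is testable without the yearbook microdata.  See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```
$ tsdea simulate --out demo --seed 42
wrote panel of 124 observations (31 units x 4 periods) to demo

$ tsdea run --panel demo/panel.csv --env demo/env.csv --out demo_run --seed 42
stage1: grand mean TE 0.939, 1 unit(s) on the frontier, minimum at U26 (0.826)
stage3: grand mean TE 0.951, 3 unit(s) on the frontier, minimum at U23 (0.847)
wrote 8 files to demo_run
```

Reading: on the raw data the average CRS efficiency over the 124
province-year observations is 0.939 and one unit keeps a 4-period mean TE of
1.000 at 3 decimals ("on the frontier").  After the slack regression strips
environmental advantage and noise out of the inputs, the average rises to
0.951, the frontier holds 3 units and the weakest unit changes — differences
between the two stages are exactly the environmental/stochastic distortion
the three-stage design is meant to remove.  `demo_run/` contains the per-DMU
scores (`stage1_efficiency.csv`, `stage3_efficiency.csv` with TE/PTE/SE and
validity), the slacks, the per-input SFA table (coefficients, σ², γ,
log-likelihood, one-sided LR), the adjusted inputs and a config echo.

The same analysis on real data needs two CSVs in the same schemas —
`panel.csv` (`unit,period,<inputs...>,<outputs...>`) and `env.csv`
(`unit,period,<covariates...>`), custom column names via `--schema`.  Note
the morbidity-rate caveat: a lower-is-better output violates DEA's output
monotonicity; pass `--invert-output K` to flip it defensibly.

The package also ships the published provincial result tables of the
motivating study as packaged fixtures; `tsdea check-fixtures` aggregates
them (grand mean 0.921, frontier counts 5 → 4, national minimum 0.784 in
Guizhou, ...).

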