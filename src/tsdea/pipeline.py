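"""Three-stage orchestration: DEA -> SFA slack adjustment -> DEA re-run.

Stage 1 scores every DMU per period under both CRS and VRS on the raw data
and extracts each observation's total input slacks.  Stage 2 regresses each
input's pooled slacks on the environmental covariates (half-normal SFA),
splits the residual into inefficiency and noise, and raises all inputs to a
common worst-environment / worst-luck footing.  Stage 3 re-scores the
adjusted inputs against the original outputs, so the remaining inefficiency
is attributable to management alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dea_core, sfa_stage2
from .dea_core import DEAConfig, DecompositionRow, ReturnsToScale
from .panel_io import DMUPanel, printed_fixtures
from .sfa_stage2 import ErrorDecomposition, SFAFit

logger = logging.getLogger("tsdea")

FRONTIER_DECIMALS = 3  # a unit is "on the frontier" when its across-period
                       # mean TE equals 1 at this printed precision


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    dea: DEAConfig = field(default_factory=DEAConfig)
    slack_rts: ReturnsToScale = ReturnsToScale.VRS  # model whose slacks feed stage 2
    pooled_sfa: bool = True       # one slack regression per input over all years
    invert_output: int | None = None  # 0-based output to flip (lower-is-better)
    seed: int = 20171231


@dataclass
class ThreeStageResult:
    panel: DMUPanel                    # panel as analysed (post inversion)
    stage1: pd.DataFrame               # unit, period, TE, PTE, SE, validity
    stage1_slacks: pd.DataFrame        # unit, period, slack_<input>...
    sfa_fits: list[SFAFit]
    decompositions: list[ErrorDecomposition]
    adjusted: DMUPanel
    stage3: pd.DataFrame
    summary: dict
    config: RunConfig = None


def _invert_output(panel: DMUPanel, k: int) -> DMUPanel:
    """Flip a lower-is-better output: y' = max - y + 1% of the range.

    The offset keeps the transformed output strictly positive for the maximal
    observation, as DEA requires.
    """
    col = panel.output_cols[k]
    y = panel.data[col].to_numpy(float)
    span = float(np.max(y) - np.min(y)) or float(np.max(y))
    out = panel.data.copy()
    out[col] = np.max(y) - y + 0.01 * span
    return DMUPanel(out, panel.input_cols, panel.output_cols, panel.env_cols)


def _stage_dea(panel: DMUPanel, config: RunConfig, stage: str,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-period CRS+VRS solve; returns the score table and the total slacks
    of the configured slack model, both in panel row order."""
    rows: list[DecompositionRow] = []
    slack_records = []
    crs_cfg = replace(config.dea, returns_to_scale=ReturnsToScale.CRS)
    vrs_cfg = replace(config.dea, returns_to_scale=ReturnsToScale.VRS)
    for period in panel.periods:
        sl = panel.period_slice(period)
        X, Y = sl.inputs, sl.outputs
        for j in range(sl.n_obs):
            unit = sl.data["unit"].iloc[j]
            try:
                crs = dea_core.solve_efficiency(j, X, Y, crs_cfg)
                vrs = dea_core.solve_efficiency(j, X, Y, vrs_cfg)
            except dea_core.DEASolverError as exc:
                raise PipelineError(stage, f"unit {unit!r} period {period!r}: "
                                    f"{exc}") from exc
            rows.append(DecompositionRow(
                unit=unit, period=period, te=crs.theta, pte=vrs.theta,
                se=crs.theta / vrs.theta, validity=vrs.validity))
            chosen = vrs if config.slack_rts is ReturnsToScale.VRS else crs
            slack = dea_core.total_slack(chosen, X[j])
            slack_records.append({"unit": unit, "period": period,
                                  **{f"slack_{name}": slack[i] for i, name in
                                     enumerate(panel.input_cols)}})
    scores = dea_core.decomposition_frame(rows)
    slacks = pd.DataFrame(slack_records)
    # restore original panel row order
    key = panel.data[["unit", "period"]].astype(str).agg("\x1f".join, axis=1)
    for frame in (scores, slacks):
        frame["_key"] = frame[["unit", "period"]].astype(str).agg(
            "\x1f".join, axis=1)
    scores = scores.set_index("_key").loc[key].reset_index(drop=True)
    slacks = slacks.set_index("_key").loc[key].reset_index(drop=True)
    return scores, slacks


def _stage2(panel: DMUPanel, slacks: pd.DataFrame, config: RunConfig,
            ) -> tuple[list[SFAFit], list[ErrorDecomposition], DMUPanel]:
    Z = panel.env
    fits: list[SFAFit] = []
    decomps: list[ErrorDecomposition] = []
    if config.pooled_sfa:
        for idx, name in enumerate(panel.input_cols):
            s = slacks[f"slack_{name}"].to_numpy(float)
            fit = sfa_stage2.fit_sfa(s, Z, input_index=idx)
            fits.append(fit)
            decomps.append(sfa_stage2.decompose_errors(fit, s, Z))
        adjusted = sfa_stage2.adjust_inputs(panel, fits, decomps)
        return fits, decomps, adjusted
    # per-year variant: independent regressions and maxima within each period
    pieces = []
    for period in panel.periods:
        mask = (panel.data["period"] == period).to_numpy()
        sub = panel.period_slice(period)
        year_fits, year_decs = [], []
        for idx, name in enumerate(panel.input_cols):
            s = slacks.loc[mask, f"slack_{name}"].to_numpy(float)
            fit = sfa_stage2.fit_sfa(s, sub.env, input_index=idx)
            year_fits.append(fit)
            year_decs.append(sfa_stage2.decompose_errors(fit, s, sub.env))
        pieces.append(sfa_stage2.adjust_inputs(sub, year_fits, year_decs).data)
        fits.extend(year_fits)
        decomps.extend(year_decs)
    merged = pd.concat(pieces, ignore_index=True)
    key = panel.data[["unit", "period"]].astype(str).agg("\x1f".join, axis=1)
    merged["_key"] = merged[["unit", "period"]].astype(str).agg(
        "\x1f".join, axis=1)
    merged = merged.set_index("_key").loc[key].reset_index(drop=True)
    adjusted = DMUPanel(merged, panel.input_cols, panel.output_cols,
                        panel.env_cols)
    return fits, decomps, adjusted


def run_three_stage(panel: DMUPanel, config: RunConfig | None = None,
                    ) -> ThreeStageResult:
    """Run the full three-stage analysis on a panel with environment."""
    if config is None:
        config = RunConfig()
    if panel.env.shape[1] == 0:
        raise PipelineError("stage2", "panel has no environmental covariates")
    work = panel
    if config.invert_output is not None:
        work = _invert_output(panel, config.invert_output)
        logger.info("inverted output %d (lower-is-better transformation)",
                    config.invert_output)

    stage1, slacks = _stage_dea(work, config, "stage1")
    try:
        fits, decomps, adjusted = _stage2(work, slacks, config)
    except sfa_stage2.SFAError as exc:
        raise PipelineError("stage2", str(exc)) from exc
    if np.any(adjusted.inputs < work.inputs - 1e-9):
        raise PipelineError("stage2", "adjusted inputs fell below originals")
    stage3, _ = _stage_dea(adjusted, config, "stage3")

    result = ThreeStageResult(
        panel=work, stage1=stage1, stage1_slacks=slacks, sfa_fits=fits,
        decompositions=decomps, adjusted=adjusted, stage3=stage3,
        summary={}, config=config)
    result.summary = summarize(result)
    return result


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_efficiency_table(scores: pd.DataFrame, value_col: str = "TE",
                               decimals: int = FRONTIER_DECIMALS) -> dict:
    """Aggregate a long table (unit, period, score): grand and period means,
    per-unit across-period means, frontier count (per-unit mean = 1 at the
    printed precision) and the minimum-efficiency unit."""
    vals = scores[value_col].to_numpy(float)
    unit_means = scores.groupby("unit", sort=False)[value_col].mean()
    period_means = scores.groupby("period", sort=False)[value_col].mean()
    frontier = unit_means.round(decimals) == 1.0
    return {
        "grand_mean": float(vals.mean()),
        "period_means": {k: float(v) for k, v in period_means.items()},
        "unit_means": {k: float(v) for k, v in unit_means.items()},
        "frontier_count": int(frontier.sum()),
        "frontier_units": list(unit_means.index[frontier]),
        "min_unit": unit_means.idxmin(),
        "min_unit_mean": float(unit_means.min()),
    }


def summarize(result: ThreeStageResult) -> dict:
    return {
        "stage1": summarize_efficiency_table(result.stage1),
        "stage3": summarize_efficiency_table(result.stage3),
    }


def check_fixtures() -> dict:
    """Aggregate the packaged published tables and report headline numbers.

    Everything here is recomputed from the packaged per-province values: the
    grand mean and 2017 mean of the stage-1 scores, frontier counts before
    and after adjustment, the minimum stage-3 TE and its province, and the
    largest violation of TE = PTE x SE across the printed rows (nonzero only
    because the printed rows are 4-year means of per-year identities).
    """
    fx = printed_fixtures()
    by_year = fx.stage1_by_year
    year_cols = [c for c in by_year.columns if c.startswith("y")]
    long = by_year.melt(id_vars="province", value_vars=year_cols,
                        var_name="period", value_name="TE")
    long = long.rename(columns={"province": "unit"})
    s1 = summarize_efficiency_table(long)

    dec = fx.decomposition
    s3_frontier = int((dec["te_s3"].round(FRONTIER_DECIMALS) == 1.0).sum())
    min_idx = dec["te_s3"].idxmin()
    gaps = np.concatenate([
        (dec["te_s1"] - dec["pte_s1"] * dec["se_s1"]).abs().to_numpy(),
        (dec["te_s3"] - dec["pte_s3"] * dec["se_s3"]).abs().to_numpy(),
    ])
    return {
        "stage1_grand_mean": round(s1["grand_mean"], FRONTIER_DECIMALS),
        "stage1_mean_2017": round(s1["period_means"]["y2017"],
                                  FRONTIER_DECIMALS),
        "stage1_frontier_count": s1["frontier_count"],
        "stage1_frontier_units": s1["frontier_units"],
        "stage3_frontier_count": s3_frontier,
        "stage3_min_te": float(dec["te_s3"].min()),
        "stage3_min_unit": str(dec.loc[min_idx, "province"]),
        "te_identity_max_gap": float(gaps.max()),
        "n_units": int(len(dec)),
    }


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def _stars(beta: float, se: float | None) -> str:
    if se is None or not np.isfinite(se) or se <= 0:
        return ""
    from scipy.stats import norm
    p = 2.0 * norm.sf(abs(beta) / se)
    return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""


def sfa_table(result: ThreeStageResult) -> pd.DataFrame:
    """Stage-2 estimates laid out one column per input, one row per
    parameter, with significance stars from asymptotic normal tests."""
    panel = result.panel
    rows = {}
    env_names = list(panel.env_cols)
    params = ["intercept", *env_names, "sigma_squared", "gamma",
              "log_likelihood", "lr_one_sided"]
    if not result.sfa_fits:
        raise PipelineError("report", "no SFA fits to tabulate")
    for fit in result.sfa_fits[:len(panel.input_cols)]:
        col = panel.input_cols[fit.input_index]
        se = fit.beta_se
        cells = []
        for i, name in enumerate(["intercept", *env_names]):
            star = _stars(fit.beta[i], None if se is None else se[i])
            cells.append(f"{fit.beta[i]:.6g}{star}")
        cells += [f"{fit.sigma_sq:.6g}", f"{fit.gamma:.6g}",
                  f"{fit.log_likelihood:.6g}", f"{fit.lr_one_sided:.6g}"]
        rows[col] = cells
    return pd.DataFrame(rows, index=params)


def export_report(result: ThreeStageResult, out_dir: str | Path) -> list[Path]:
    """Write the run's artifacts as CSVs plus a config echo and a log.

    Re-running with the same panel, seed and config reproduces the numeric
    CSVs byte for byte.
    """
    if result is None or result.stage1.empty or result.stage3.empty:
        raise PipelineError("report", "refusing to export an empty result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(name: str, frame: pd.DataFrame):
        path = out / name
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)

    _write("stage1_efficiency.csv", result.stage1)
    _write("stage1_slacks.csv", result.stage1_slacks)
    table = sfa_table(result)
    path = out / "stage2_sfa.csv"
    table.to_csv(path, index_label="parameter")
    written.append(path)
    adj = result.adjusted.data[["unit", "period",
                                *result.adjusted.input_cols]]
    _write("adjusted_inputs.csv", adj)
    _write("stage3_efficiency.csv", result.stage3)

    summary_rows = []
    for stage in ("stage1", "stage3"):
        s = result.summary[stage]
        summary_rows.append({
            "stage": stage,
            "grand_mean_te": s["grand_mean"],
            "frontier_count": s["frontier_count"],
            "min_unit": s["min_unit"],
            "min_unit_mean_te": s["min_unit_mean"],
        })
    _write("summary.csv", pd.DataFrame(summary_rows))

    cfg = result.config or RunConfig()
    echo = {
        "seed": cfg.seed,
        "returns_to_scale_decomposition": ["CRS", "VRS"],
        "slack_rts": cfg.slack_rts.value,
        "pooled_sfa": cfg.pooled_sfa,
        "invert_output": cfg.invert_output,
        "slack_phase": cfg.dea.slack_phase,
        "epsilon": cfg.dea.epsilon,
        "unity_tolerance": cfg.dea.unity_tolerance,
    }
    cfg_path = out / "run_config.yaml"
    cfg_path.write_text(yaml.safe_dump(echo, sort_keys=True))
    written.append(cfg_path)

    log_path = out / "run.log"
    lines = [f"seed={cfg.seed}", f"n_obs={result.panel.n_obs}",
             f"periods={result.panel.periods}"]
    for fit in result.sfa_fits:
        lines.append(
            f"sfa input={fit.input_index} converged={fit.converged} "
            f"gamma={fit.gamma:.6g} ll={fit.log_likelihood:.6g} "
            f"lr={fit.lr_one_sided:.6g}")
    log_path.write_text("\n".join(lines) + "\n")
    written.append(log_path)
    return written
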