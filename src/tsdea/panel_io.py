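"""Panel data model, CSV I/O, descriptive statistics and correlation screening.

The unit of analysis is a decision-making unit (DMU) observed over several
periods — in the motivating application a Chinese province-year of the basic
medical insurance system — with strictly positive input and output quantities
and a small set of environmental covariates (economic conditions the DMU does
not control).  Published per-province efficiency tables are shipped as packaged
CSV resources for aggregation checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tsdea")

UNIT_COL = "unit"
PERIOD_COL = "period"

DEFAULT_INPUT_NAMES = (
    "fund_income",
    "health_technicians",
    "gov_health_expenditure",
)
DEFAULT_OUTPUT_NAMES = (
    "fund_expenditure",
    "epidemic_morbidity_rate",
    "resident_health_expenditure",
)
DEFAULT_ENV_NAMES = (
    "gdp_per_capita",
    "social_security_expenditure",
    "fiscal_revenue_expenditure_ratio",
)


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is malformed."""


class PanelValidationError(ValueError):
    """Panel content violates an invariant (positivity, duplicates, ...)."""


@dataclass(frozen=True)
class PanelSchema:
    """Maps file columns to panel roles.

    ``inputs``/``outputs``/``env`` list the column names, in order, holding the
    N input, M output and P environmental variables.
    """

    unit: str = UNIT_COL
    period: str = PERIOD_COL
    inputs: Sequence[str] = DEFAULT_INPUT_NAMES
    outputs: Sequence[str] = DEFAULT_OUTPUT_NAMES
    env: Sequence[str] = DEFAULT_ENV_NAMES

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PanelSchema":
        return cls(
            unit=mapping.get("unit", UNIT_COL),
            period=mapping.get("period", PERIOD_COL),
            inputs=tuple(mapping["inputs"]),
            outputs=tuple(mapping["outputs"]),
            env=tuple(mapping.get("env", ())),
        )


@dataclass
class DMUPanel:
    """A balanced-or-not panel of DMUs with inputs, outputs and environment.

    ``data`` has one row per (unit, period) with columns
    ``unit, period, <inputs...>, <outputs...>, <env...>``; row order is
    preserved from the source and is the observation order used throughout
    the three-stage pipeline.
    """

    data: pd.DataFrame
    input_cols: tuple[str, ...] = DEFAULT_INPUT_NAMES
    output_cols: tuple[str, ...] = DEFAULT_OUTPUT_NAMES
    env_cols: tuple[str, ...] = DEFAULT_ENV_NAMES

    def __post_init__(self) -> None:
        self.input_cols = tuple(self.input_cols)
        self.output_cols = tuple(self.output_cols)
        self.env_cols = tuple(self.env_cols)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def unit_ids(self) -> list:
        return list(pd.unique(self.data[UNIT_COL]))

    @property
    def periods(self) -> list:
        return list(pd.unique(self.data[PERIOD_COL]))

    @property
    def inputs(self) -> np.ndarray:
        """(n_obs, N) array of input quantities."""
        return self.data[list(self.input_cols)].to_numpy(float)

    @property
    def outputs(self) -> np.ndarray:
        return self.data[list(self.output_cols)].to_numpy(float)

    @property
    def env(self) -> np.ndarray:
        return self.data[list(self.env_cols)].to_numpy(float)

    def period_slice(self, period) -> "DMUPanel":
        """Cross-section of one period, preserving row order."""
        sub = self.data[self.data[PERIOD_COL] == period].reset_index(drop=True)
        if sub.empty:
            raise KeyError(f"period {period!r} not in panel")
        return DMUPanel(sub, self.input_cols, self.output_cols, self.env_cols)

    def with_inputs(self, new_inputs: np.ndarray) -> "DMUPanel":
        """Copy of the panel with replaced input columns (outputs/env intact)."""
        new_inputs = np.asarray(new_inputs, float)
        if new_inputs.shape != (self.n_obs, len(self.input_cols)):
            raise PanelValidationError(
                f"replacement inputs have shape {new_inputs.shape}, "
                f"expected {(self.n_obs, len(self.input_cols))}"
            )
        out = self.data.copy()
        out[list(self.input_cols)] = new_inputs
        return DMUPanel(out, self.input_cols, self.output_cols, self.env_cols)

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        for col in (UNIT_COL, PERIOD_COL, *self.input_cols, *self.output_cols,
                    *self.env_cols):
            if col not in self.data.columns:
                raise SchemaError(f"panel is missing column {col!r}")
        if self.data[list(self.input_cols + self.output_cols + self.env_cols)].isna().any().any():
            raise PanelValidationError("missing values are not supported")
        dup = self.data.duplicated(subset=[UNIT_COL, PERIOD_COL])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise PanelValidationError(
                f"duplicate observation for unit={row[UNIT_COL]!r} "
                f"period={row[PERIOD_COL]!r}"
            )
        for col in self.input_cols + self.output_cols:
            vals = self.data[col].to_numpy(float)
            if not np.all(vals > 0):
                bad = self.data.iloc[int(np.argmin(vals > 0))]
                raise PanelValidationError(
                    f"non-positive value in {col!r} for unit={bad[UNIT_COL]!r} "
                    f"period={bad[PERIOD_COL]!r}"
                )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_panel(
    path: str | Path,
    schema: PanelSchema | Mapping | None = None,
    env_path: str | Path | None = None,
) -> DMUPanel:
    """Read a panel from comma-separated UTF-8 file(s) with a header row.

    ``path`` holds ``unit, period`` plus the input and output columns; the
    environmental covariates may live in the same file or in ``env_path``
    (keyed on unit and period).  Column names are taken from ``schema``.
    """
    if schema is None:
        schema = PanelSchema()
    elif not isinstance(schema, PanelSchema):
        schema = PanelSchema.from_mapping(schema)

    frame = pd.read_csv(path)
    if env_path is not None:
        env_frame = pd.read_csv(env_path)
        for col in (schema.unit, schema.period):
            if col not in env_frame.columns:
                raise SchemaError(f"environment file is missing column {col!r}")
        frame = frame.merge(env_frame, on=[schema.unit, schema.period],
                            how="left", validate="one_to_one")

    for col in (schema.unit, schema.period, *schema.inputs, *schema.outputs,
                *schema.env):
        if col not in frame.columns:
            raise SchemaError(f"input file is missing column {col!r}")

    rename = {schema.unit: UNIT_COL, schema.period: PERIOD_COL}
    frame = frame.rename(columns=rename)
    cols = [UNIT_COL, PERIOD_COL, *schema.inputs, *schema.outputs, *schema.env]
    return DMUPanel(frame[cols].copy(), tuple(schema.inputs),
                    tuple(schema.outputs), tuple(schema.env))


def write_panel(
    panel: DMUPanel,
    panel_path: str | Path,
    env_path: str | Path | None = None,
    float_format: str = "%.10g",
) -> None:
    """Write ``panel.csv`` (unit, period, inputs, outputs) and optionally
    ``env.csv`` (unit, period, env covariates) in the loader's schema."""
    body = panel.data[[UNIT_COL, PERIOD_COL, *panel.input_cols,
                       *panel.output_cols]]
    if env_path is None:
        body = panel.data
        body.to_csv(panel_path, index=False, float_format=float_format)
        return
    body.to_csv(panel_path, index=False, float_format=float_format)
    env = panel.data[[UNIT_COL, PERIOD_COL, *panel.env_cols]]
    env.to_csv(env_path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# descriptive statistics and correlation screen
# ---------------------------------------------------------------------------

def describe(panel: DMUPanel) -> pd.DataFrame:
    """Mean, sample standard deviation (n-1), minimum and maximum per variable.

    One row per input, output and environmental variable, in panel order.
    """
    if panel.n_obs == 0:
        raise PanelValidationError("cannot describe an empty panel")
    rows = []
    roles = (
        [("input", c) for c in panel.input_cols]
        + [("output", c) for c in panel.output_cols]
        + [("env", c) for c in panel.env_cols]
    )
    for role, col in roles:
        x = panel.data[col].to_numpy(float)
        rows.append({
            "variable": col,
            "role": role,
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            "min": float(np.min(x)),
            "max": float(np.max(x)),
        })
    return pd.DataFrame(rows)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations of the input and output indicators."""

    r: pd.DataFrame          # symmetric, unit diagonal; NaN where undefined
    p: pd.DataFrame          # two-sided p-values (NaN on diagonal/undefined)
    significant_1pct: pd.DataFrame
    significant_5pct: pd.DataFrame
    advisory: list[str] = field(default_factory=list)


def pearson_screen(panel: DMUPanel) -> CorrelationReport:
    """Pearson correlation screen of inputs vs outputs (environment excluded).

    Two-sided, unadjusted p-values; a pair involving a zero-variance variable
    is reported as missing (NaN), never as zero.  Emits an advisory warning if
    no input-output pair reaches |r| >= 0.2 — the screen justifies proceeding
    to the efficiency analysis, it is not a hard gate.
    """
    cols = list(panel.input_cols + panel.output_cols)
    if panel.n_obs < 3:
        raise PanelValidationError("correlation screen needs >= 3 observations")
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    data = panel.data[cols].to_numpy(float)
    degenerate = [np.std(data[:, i]) == 0 for i in range(k)]
    for i in range(k):
        if not degenerate[i]:
            r[i, i] = 1.0
        for j in range(i + 1, k):
            if degenerate[i] or degenerate[j]:
                continue
            res = stats.pearsonr(data[:, i], data[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rf = pd.DataFrame(r, index=cols, columns=cols)
    pf = pd.DataFrame(p, index=cols, columns=cols)
    advisory: list[str] = []
    cross = rf.loc[list(panel.input_cols), list(panel.output_cols)].abs()
    if cross.notna().any().any() and float(cross.max().max()) < 0.2:
        msg = ("no input-output pair reaches |r| >= 0.2; the indicator system "
               "may be weakly coupled")
        advisory.append(msg)
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
    return CorrelationReport(
        r=rf, p=pf,
        significant_1pct=pf < 0.01,
        significant_5pct=pf < 0.05,
        advisory=advisory,
    )


# ---------------------------------------------------------------------------
# published result tables (packaged fixtures)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrintedResultsFixture:
    """Published per-province efficiency tables for the 2017-2020 panel.

    ``stage1_by_year``: stage-1 technical efficiency per province per year plus
    the per-province 4-year mean (31 x 5 values).  ``decomposition``: stage-1
    and stage-3 TE/PTE/SE per province (31 x 6 values).  The two occurrences of
    the pinyin "Shanxi" are disambiguated as ``Shanxi`` and ``Shaanxi``.
    """

    stage1_by_year: pd.DataFrame
    decomposition: pd.DataFrame


def printed_fixtures() -> PrintedResultsFixture:
    """Load the packaged published-results tables."""
    pkg = resources.files("tsdea") / "data"
    by_year = pd.read_csv(str(pkg / "stage1_efficiency_by_year.csv"))
    decomp = pd.read_csv(str(pkg / "stage1_stage3_decomposition.csv"))
    for frame, cols in ((by_year, by_year.columns[1:]),
                        (decomp, decomp.columns[1:])):
        vals = frame[cols].to_numpy(float)
        if not ((vals > 0) & (vals <= 1)).all():
            raise PanelValidationError("fixture efficiency outside (0, 1]")
    return PrintedResultsFixture(stage1_by_year=by_year, decomposition=decomp)
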