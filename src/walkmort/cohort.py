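"""Assembly of the modelling table and follow-up truncation.

The modelling table joins, per included participant: 3 demographics, 7
Advanced Disease Condition (ADC) and 10 Modifiable Risk Factor (MRF)
categorical features, the 76 aggregated sensor features (or whatever sensor
columns are supplied), and the survival outcome (time in years, event flag).
A sidecar schema maps each predictor column to its feature group
(demo / ADC / MRF / continuous) so model sets can be selected by name.

Categoricals are encoded 1 = bad health / 0 = good health, ordinals kept
ordinal.  Missing covariates are handled complete-case (dropped rows are
counted, not imputed).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ADC_COLUMNS, DEMO_COLUMNS, MRF_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["FollowupSpec", "assemble_table", "truncate_followup", "feature_groups", "write_schema"]


@dataclass(frozen=True)
class FollowupSpec:
    """Maximum follow-up horizons in years (events beyond a horizon are
    treated as administratively censored at that horizon)."""

    horizons: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)

    def __post_init__(self) -> None:
        if any(y <= 0 for y in self.horizons):
            raise ValueError("all horizons must be positive")


def feature_groups(columns) -> dict[str, str]:
    """Column -> group label (demo / ADC / MRF / continuous) for known columns."""
    schema: dict[str, str] = {}
    for col in columns:
        if col in DEMO_COLUMNS:
            schema[col] = "demo"
        elif col in ADC_COLUMNS:
            schema[col] = "ADC"
        elif col in MRF_COLUMNS:
            schema[col] = "MRF"
        elif col in {"id", "time", "event", "site"}:
            continue
        else:
            schema[col] = "continuous"
    return schema


def assemble_table(
    sensor: pd.DataFrame, covariates: pd.DataFrame, outcomes: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Inner-join sensor aggregates, covariates and outcomes on ``id``.

    Duplicate ids raise; rows with missing covariates are dropped
    (complete-case) with the count logged; disjoint id sets yield an empty
    table with a warning.  Returns (table, column->group schema).
    """
    for name, df in (("sensor", sensor), ("covariates", covariates), ("outcomes", outcomes)):
        if "id" not in df.columns:
            raise ValueError(f"{name} table lacks an 'id' column")
        if df["id"].duplicated().any():
            raise ValueError(f"duplicate ids in {name} table")

    table = covariates.merge(sensor, on="id", how="inner").merge(outcomes, on="id", how="inner")
    if table.empty:
        warnings.warn("assembled table is empty: input id sets do not overlap", stacklevel=2)
        return table, feature_groups(table.columns)

    n_before = len(table)
    table = table.dropna()
    n_dropped = n_before - len(table)
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d participants", n_dropped, n_before)
    table = table.reset_index(drop=True)
    table.attrs["n_dropped_incomplete"] = n_dropped

    if (table["time"] <= 0).any():
        raise ValueError("all follow-up times must be positive")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event must be binary")
    return table, feature_groups(table.columns)


def truncate_followup(table: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Administrative truncation at ``horizon`` years: (time, event) becomes
    (min(time, Y), event * [time <= Y]).  Idempotent; the input is not
    modified."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = table.copy()
    over = out["time"] > horizon
    out.loc[over, "time"] = horizon
    out.loc[over, "event"] = 0
    return out


def write_schema(schema: dict[str, str], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(schema, indent=2, sort_keys=True))
    return path


def select_predictors(schema: dict[str, str], groups) -> list[str]:
    """Predictor columns whose group is in ``groups`` (e.g. ('demo','continuous'))."""
    wanted = set(groups)
    unknown = wanted - {"demo", "ADC", "MRF", "continuous"}
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    return [col for col, grp in schema.items() if grp in wanted]
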