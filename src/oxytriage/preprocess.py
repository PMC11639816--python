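"""Mask-aware preprocessing of irregular ICU observations.

Stages, in fixed order (clamping runs both before and after the synthetic-data
stages, and values are rounded to matrix granularity before scoring):

1. merge duplicate rows / duplicate admission copies,
2. clamp implausible values to missing,
3. chained-equation imputation of observation-level missing cells
   (boosted-tree regressors, single completed dataset),
4. linear interpolation of every admission onto a 1-minute grid,
5. re-clamp and round,
6. derivation of BMI and MAP,
7. TAG scoring and severity labeling.

Every cell that was not directly observed - imputed, interpolated, or derived
from a synthetic source - carries a provenance mask of 1; observed cells carry
0.  The 16 per-variable masks (10 numeric variables + 6 TAGs) are model
features; the per-row interpolation flag is bookkeeping only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .scoring import (
    CLAMP_BOUNDS,
    VITALS,
    SeverityMatrix,
    ThresholdMatrix,
    assign_age_group,
    population_group,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClampSpec",
    "MaskedMinuteSeries",
    "RACE_CATEGORIES",
    "FEATURE_COLUMNS",
    "merge_duplicates",
    "clamp_outliers",
    "impute_chained",
    "interpolate_minutes",
    "validate_interpolation",
    "derive_physiology",
    "assemble_features",
    "run_pipeline",
]

#: One-hot race/ethnicity categories (an unknown category maps to all zeros).
RACE_CATEGORIES = (
    "white",
    "black_african_american",
    "hispanic_latino",
    "asian",
    "american_indian_alaska_native",
    "native_hawaiian_pacific_islander",
    "multiracial",
)

#: The ten numeric variables that carry provenance masks.
MASKED_NUMERIC = (
    "spo2",
    "systolic_bp",
    "diastolic_bp",
    "respiratory_rate",
    "temperature",
    "bmi",
    "heart_rate",
    "map",
    "height",
    "weight",
)

NUMERIC_FEATURES = (
    "gender",
    "age",
    "weight",
    "height",
    "bmi",
    "systolic_bp",
    "diastolic_bp",
    "map",
    "temperature",
    "heart_rate",
    "respiratory_rate",
    "spo2",
)

TAG_COLUMNS = tuple(f"tag_{v}" for v in VITALS)
MASK_COLUMNS = tuple(f"mask_{v}" for v in MASKED_NUMERIC) + tuple(
    f"mask_tag_{v}" for v in VITALS
)
RACE_COLUMNS = tuple(f"race_{c}" for c in RACE_CATEGORIES)

#: The 41 model-input columns, in canonical order.
FEATURE_COLUMNS = NUMERIC_FEATURES + RACE_COLUMNS + TAG_COLUMNS + MASK_COLUMNS

BOOKKEEPING_COLUMNS = ("patient_id", "admission_id", "charttime", "row_interpolated")


@dataclass(frozen=True)
class ClampSpec:
    """Inclusive per-vital plausibility bounds."""

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CLAMP_BOUNDS)
    )

    def is_valid(self, vital: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[vital]
        v = np.asarray(values, dtype=float)
        return (v >= lo) & (v <= hi)


@dataclass
class MaskedMinuteSeries:
    """One admission on a regular 1-minute grid with provenance masks.

    ``frame`` holds value columns, ``mask_*`` columns in {0, 1}, a
    ``charttime`` column of consecutive minutes, and ``row_interpolated``.
    """

    admission_id: object
    patient_id: object
    demographics: dict
    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)


def merge_duplicates(obs: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate observation rows.

    Keeps a single value per (admission, charttime, vital); when several
    distinct non-null values collide, the last by input order wins and a
    warning is logged.  Fully identical rows keep only their most recent copy.
    """
    if obs.empty:
        return obs.copy()
    out = obs.drop_duplicates(keep="last")
    key = ["admission_id", "charttime", "vital"]
    dup = out.duplicated(subset=key, keep=False) & out["value"].notna()
    if dup.any():
        n_conflicts = out.loc[dup].groupby(key).size().gt(1).sum()
        if n_conflicts:
            logger.warning(
                "merge_duplicates: %d (charttime, vital) cells had conflicting "
                "values; keeping last by input order",
                int(n_conflicts),
            )
    # Prefer non-null values within a cell, then last input order.
    out = out.assign(__nonnull=out["value"].notna(), __ord=np.arange(len(out)))
    out = out.sort_values(["__nonnull", "__ord"], kind="stable")
    out = out.drop_duplicates(subset=key, keep="last").drop(columns=["__nonnull", "__ord"])
    return out.sort_values(["admission_id", "charttime", "vital"], kind="stable").reset_index(
        drop=True
    )


def clamp_outliers(obs: pd.DataFrame, spec: ClampSpec | None = None) -> pd.DataFrame:
    """Replace out-of-range values with NaN (to be imputed downstream)."""
    spec = spec or ClampSpec()
    out = obs.copy()
    n_clamped = 0
    for vital, (lo, hi) in spec.bounds.items():
        sel = out["vital"] == vital
        vals = out.loc[sel, "value"]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        n_clamped += int(bad.sum())
        out.loc[bad[bad].index, "value"] = np.nan
    if n_clamped:
        logger.info("clamp_outliers: %d implausible values set to missing", n_clamped)
    return out


def _default_imputer(seed: int) -> IterativeImputer:
    return IterativeImputer(
        estimator=HistGradientBoostingRegressor(random_state=seed),
        max_iter=10,
        tol=1e-3,
        imputation_order="ascending",
        skip_complete=True,
        random_state=seed,
        keep_empty_features=False,
    )


def impute_chained(
    table: pd.DataFrame, seed: int = 0, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing cells by chained equations with boosted-tree regressors.

    Returns the completed table and a same-shaped 0/1 mask marking every
    imputed cell.  Reproducible for a fixed seed.  Columns listed in
    ``columns`` (default: all numeric) participate; a fully missing column is
    an error because the chain cannot be initialized from it.
    """
    cols = columns or [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    sub = table[cols].astype(float)
    mask = sub.isna().astype(np.int8)
    if int(mask.values.sum()) == 0:
        return table.copy(), mask
    all_missing = [c for c in cols if sub[c].isna().all()]
    if all_missing:
        raise ValueError(f"cannot impute fully missing columns: {all_missing}")
    frac = sub.isna().mean()
    heavy = frac[frac >= 0.5]
    if not heavy.empty:
        logger.warning(
            "impute_chained: columns exceed 50%% missing: %s", dict(heavy.round(3))
        )
    imp = _default_imputer(seed)
    filled = imp.fit_transform(sub.values)
    out = table.copy()
    out[cols] = filled
    logger.info("impute_chained: filled %d cells", int(mask.values.sum()))
    return out, mask


def interpolate_minutes(
    wide: pd.DataFrame,
    value_cols: list[str] | None = None,
    imput_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Linearly interpolate one admission onto a 1-minute grid.

    ``wide`` has a ``charttime`` column (integer minutes, sorted) and one
    column per variable, with no missing cells (imputation runs first).  The
    grid spans the first to the last observed charttime; nothing is
    extrapolated beyond either endpoint.  Generated minutes get
    ``row_interpolated`` = 1 and a value mask of 1 for every variable; at
    observed minutes the value mask is the imputation mask (default 0).
    """
    if wide.empty:
        raise ValueError("interpolate_minutes requires at least one observation")
    value_cols = value_cols or [c for c in wide.columns if c != "charttime"]
    times = wide["charttime"].to_numpy(dtype=np.int64)
    if times.size != np.unique(times).size:
        raise ValueError("duplicate charttimes; run merge_duplicates first")
    order = np.argsort(times)
    times = times[order]
    grid = np.arange(times[0], times[-1] + 1, dtype=np.int64)
    observed = np.isin(grid, times)
    out = pd.DataFrame({"charttime": grid})
    out["row_interpolated"] = (~observed).astype(np.int8)
    pos = np.searchsorted(times, grid[observed])
    for col in value_cols:
        vals = wide[col].to_numpy(dtype=float)[order]
        if np.isnan(vals).any():
            raise ValueError(f"column {col!r} still has missing values; impute first")
        out[col] = np.interp(grid, times, vals)
        cell_mask = np.ones(grid.size, dtype=np.int8)
        if imput_mask is not None and col in imput_mask.columns:
            obs_mask = imput_mask[col].to_numpy(dtype=np.int8)[order][pos]
        else:
            obs_mask = np.zeros(pos.size, dtype=np.int8)
        cell_mask[observed] = obs_mask
        out[f"mask_{col}"] = cell_mask
    return out


def validate_interpolation(
    times: np.ndarray,
    values: np.ndarray,
    methods: tuple[str, ...] = ("linear", "cubic_spline", "polynomial_3", "polynomial_5"),
) -> pd.DataFrame:
    """Diagnostic comparison of interpolation families on one series.

    Evaluates each method on the dense minute grid and reports its min/max.
    Higher-order methods can leave the plausible range; linear interpolation
    cannot exceed the observed extremes.
    """
    from scipy.interpolate import CubicSpline

    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 4:
        raise ValueError("need at least 4 observations to compare methods")
    grid = np.arange(times.min(), times.max() + 1.0)
    rows = []
    for method in methods:
        if method == "linear":
            y = np.interp(grid, times, values)
        elif method == "cubic_spline":
            y = CubicSpline(times, values)(grid)
        elif method.startswith("polynomial_"):
            deg = int(method.rsplit("_", 1)[1])
            coef = np.polynomial.Polynomial.fit(times, values, deg)
            y = coef(grid)
        else:
            raise ValueError(f"unknown interpolation method {method!r}")
        rows.append({"method": method, "minimal": float(y.min()), "maximal": float(y.max())})
    return pd.DataFrame(rows).set_index("method")


def derive_physiology(frame: pd.DataFrame) -> pd.DataFrame:
    """Add BMI and MAP (and their masks) to a minute-grid frame.

    BMI = weight_kg / height_m^2, MAP = (SBP + 2 DBP) / 3, both rounded to
    0.1.  A derived cell is synthetic when any source cell is.
    """
    out = frame.copy()
    height_m = out["height"] / 100.0
    out["bmi"] = np.round(out["weight"] / height_m**2, 1)
    out["map"] = np.round((out["systolic_bp"] + 2.0 * out["diastolic_bp"]) / 3.0, 1)
    n_inverted = int((out["diastolic_bp"] > out["systolic_bp"]).sum())
    if n_inverted:
        logger.warning(
            "derive_physiology: %d minutes with DBP > SBP; MAP computed anyway",
            n_inverted,
        )
    out["mask_bmi"] = np.maximum(
        out.get("mask_weight", 0), out.get("mask_height", 0)
    ).astype(np.int8)
    out["mask_map"] = np.maximum(
        out.get("mask_systolic_bp", 0), out.get("mask_diastolic_bp", 0)
    ).astype(np.int8)
    return out


def _round_vitals(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for vital in VITALS:
        if vital == "temperature":
            out[vital] = np.round(out[vital], 1)
        else:
            out[vital] = np.round(out[vital])
    return out


def _clamp_frame(frame: pd.DataFrame, spec: ClampSpec) -> pd.DataFrame:
    out = frame.copy()
    for vital, (lo, hi) in spec.bounds.items():
        if vital in out.columns:
            out[vital] = out[vital].clip(lo, hi)
    return out


def one_hot_race(race: str | None) -> dict[str, float]:
    """Seven-column one-hot encoding; unknown categories map to all zeros."""
    cols = {c: 0.0 for c in RACE_COLUMNS}
    if race is None or (isinstance(race, float) and np.isnan(race)):
        return cols
    key = f"race_{str(race).strip().lower()}"
    if key in cols:
        cols[key] = 1.0
    elif str(race).strip().lower() not in ("undefined", "unknown", ""):
        logger.info("one_hot_race: unknown category %r mapped to all zeros", race)
    return cols


def assemble_features(
    series: MaskedMinuteSeries,
    tmatrix: ThresholdMatrix,
    smatrix: SeverityMatrix,
) -> pd.DataFrame:
    """Build the 41-feature model table for one admission.

    Columns: 12 numeric, 7 one-hot race, 6 TAG, 16 masks - plus the label and
    bookkeeping columns (ids, charttime, row_interpolated), which are not
    model inputs.
    """
    demo = series.demographics
    frame = series.frame
    group = assign_age_group(demo["age"])
    pop = population_group(demo["age"], bool(demo.get("copd", False)))

    out = pd.DataFrame(index=frame.index)
    out["gender"] = float(demo["gender"])
    out["age"] = float(demo["age"])
    out["weight"] = float(np.round(demo["weight"], 1))
    out["height"] = float(np.round(demo["height"], 1))
    height_m = demo["height"] / 100.0
    out["bmi"] = frame["bmi"] if "bmi" in frame else np.round(demo["weight"] / height_m**2, 1)
    for col in ("systolic_bp", "diastolic_bp", "map", "temperature", "heart_rate",
                "respiratory_rate", "spo2"):
        out[col] = frame[col].to_numpy()
    for col, val in one_hot_race(demo.get("race")).items():
        out[col] = val
    for vital in VITALS:
        out[f"tag_{vital}"] = tmatrix.score_array(
            vital, frame[vital].to_numpy(), group
        ).astype(np.int32)
        src = frame.get(f"mask_{vital}")
        out[f"mask_tag_{vital}"] = (
            src.to_numpy(dtype=np.int8) if src is not None else np.int8(0)
        )
    for var in MASKED_NUMERIC:
        col = frame.get(f"mask_{var}")
        if col is not None:
            out[f"mask_{var}"] = col.to_numpy(dtype=np.int8)
        else:
            out[f"mask_{var}"] = np.int8(demo.get(f"{var}_imputed", 0))
    out["label"] = smatrix.label_array(frame["spo2"].to_numpy(), pop).astype(np.int64)
    out["patient_id"] = series.patient_id
    out["admission_id"] = series.admission_id
    out["charttime"] = frame["charttime"].to_numpy()
    out["row_interpolated"] = frame["row_interpolated"].to_numpy(dtype=np.int8)
    return out[list(FEATURE_COLUMNS) + ["label"] + list(BOOKKEEPING_COLUMNS)]


def run_pipeline(
    obs: pd.DataFrame,
    demographics: pd.DataFrame,
    tmatrix: ThresholdMatrix,
    smatrix: SeverityMatrix,
    seed: int = 0,
    clamp: ClampSpec | None = None,
) -> pd.DataFrame:
    """Full preprocessing: long observations -> model-ready minute table.

    ``obs`` columns: patient_id, admission_id, charttime, vital, value.
    ``demographics`` columns: patient_id, admission_id, age, gender, race,
    height, weight, copd (height/weight may be missing; they are imputed).
    """
    clamp = clamp or ClampSpec()
    obs = merge_duplicates(obs)
    obs = clamp_outliers(obs, clamp)

    wide = obs.pivot_table(
        index=["admission_id", "charttime"], columns="vital", values="value", aggfunc="last"
    ).reset_index()
    wide.columns.name = None
    for vital in VITALS:
        if vital not in wide.columns:
            wide[vital] = np.nan
    demo = demographics.set_index("admission_id")
    wide = wide.join(demo[["age", "gender", "height", "weight"]], on="admission_id")

    impute_cols = list(VITALS) + ["height", "weight", "age", "gender"]
    filled, imask = impute_chained(wide[impute_cols], seed=seed)
    for col in impute_cols:
        wide[col] = filled[col]
    # Demographics are admission-constant: one imputed cell flags the whole stay.
    demo_imputed = (
        pd.concat([wide[["admission_id"]], imask[["height", "weight"]]], axis=1)
        .groupby("admission_id")
        .max()
    )

    tables = []
    for adm_id, g in wide.groupby("admission_id", sort=True):
        g = g.sort_values("charttime")
        grid = interpolate_minutes(
            g[["charttime"] + list(VITALS)],
            value_cols=list(VITALS),
            imput_mask=imask.loc[g.index, list(VITALS)],
        )
        grid = _clamp_frame(grid, clamp)
        grid = _round_vitals(grid)
        row = demo.loc[adm_id]
        height = float(np.median(g["height"]))
        weight = float(np.median(g["weight"]))
        grid["height"] = np.round(height, 1)
        grid["weight"] = np.round(weight, 1)
        grid["mask_height"] = np.int8(demo_imputed.loc[adm_id, "height"])
        grid["mask_weight"] = np.int8(demo_imputed.loc[adm_id, "weight"])
        grid = derive_physiology(grid)
        series = MaskedMinuteSeries(
            admission_id=adm_id,
            patient_id=row["patient_id"],
            demographics={
                "age": float(row["age"]) if pd.notna(row["age"]) else float(g["age"].iloc[0]),
                "gender": float(row["gender"]) if pd.notna(row["gender"]) else float(g["gender"].iloc[0]),
                "race": row.get("race"),
                "height": height,
                "weight": weight,
                "copd": bool(row.get("copd", False)),
            },
            frame=grid,
        )
        tables.append(assemble_features(series, tmatrix, smatrix))
    result = pd.concat(tables, ignore_index=True)
    logger.info(
        "run_pipeline: %d admissions -> %d minute rows (%d features)",
        wide["admission_id"].nunique(),
        len(result),
        len(FEATURE_COLUMNS),
    )
    return result
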