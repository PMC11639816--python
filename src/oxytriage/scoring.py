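"""NEWS2+ vital-sign scoring and SpO2-based hypoxemia severity labeling.

Two rule tables drive everything here:

* a *TAG matrix* mapping each of six vitals, per age group, to severity bands
  with levels 0 (baseline) through 3 (severe), and
* a *severity matrix* mapping SpO2 to a 4-class hypoxemia severity label
  (0 normal, 1 mild, 2 moderate, 3 severe), stratified by population
  (adult with/without COPD, pediatric without COPD).

The shipped configuration transcribes the printed band tables verbatim,
including their overlaps and gaps.  Loading *canonicalizes* the tables onto a
discrete value grid (integers for rate/pressure/saturation vitals, 0.1 degC
for temperature): overlapping claims resolve to the more severe band, gaps are
annexed by the more severe neighbour, and SpO2 values above the baseline band
score 0 (no hyperoxemia on ambient air).  Every such edit is recorded in a
machine-readable corrections report so the alarm-favoring behavior is fully
auditable and overridable via a user-supplied config file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "AgeGroup",
    "PopulationGroup",
    "Band",
    "Correction",
    "ThresholdMatrix",
    "SeverityMatrix",
    "VITALS",
    "MatrixLoadError",
    "assign_age_group",
    "load_matrices",
    "severity_label",
    "tag_score",
    "tag_vector",
]

#: Canonical vital order used by TAG vectors and feature assembly.
VITALS = (
    "respiratory_rate",
    "spo2",
    "heart_rate",
    "systolic_bp",
    "diastolic_bp",
    "temperature",
)

#: Inclusive plausibility bounds; doubles as the clamped scoring domain.
CLAMP_BOUNDS: Mapping[str, tuple[float, float]] = {
    "respiratory_rate": (0, 300),
    "heart_rate": (0, 300),
    "systolic_bp": (0, 300),
    "diastolic_bp": (0, 300),
    "spo2": (0, 100),
    "temperature": (0.0, 60.0),
}

#: Grid resolution per vital.  Values are rounded to this step before lookup.
GRANULARITY: Mapping[str, float] = {v: 1.0 for v in VITALS} | {"temperature": 0.1}


class MatrixLoadError(ValueError):
    """Raised when a threshold config cannot be canonicalized."""


class AgeGroup(Enum):
    """Age strata of the TAG matrix; boundaries are left-closed."""

    INF_0_11M = "infant_0_11m"
    TOD_12_23M = "toddler_12_23m"
    CHILD_2_4Y = "child_2_4y"
    CHILD_5_11Y = "child_5_11y"
    ADOL_12_17Y = "adol_12_17y"
    ADULT_18PLUS = "adult"


class PopulationGroup(Enum):
    """Population strata of the SpO2 severity matrix."""

    ADULT_NO_COPD = "adult_no_copd"
    ADULT_COPD = "adult_copd"
    PEDIATRIC_NO_COPD = "pediatric_no_copd"


@dataclass(frozen=True)
class Band:
    """One severity band: an inclusive value range scored at ``level``."""

    level: int
    side: str  # low | baseline | high | na
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 <= self.level <= 3:
            raise MatrixLoadError(f"band level {self.level} outside 0-3")
        if self.lower > self.upper:
            raise MatrixLoadError(f"band lower {self.lower} > upper {self.upper}")
        if (self.level == 0) != (self.side == "baseline"):
            raise MatrixLoadError("level 0 must be (exactly) the baseline band")


@dataclass(frozen=True)
class Correction:
    """A canonicalization edit applied to a printed cell range."""

    table: str  # "tag" or "severity"
    vital: str
    group: str
    kind: str  # overlap | gap | ambient_air
    lower: float
    upper: float
    resolved_level: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def assign_age_group(age_years: float) -> AgeGroup:
    """Map a non-negative age in years to its TAG age group.

    Boundaries are left-closed: 2.0 years is CHILD_2_4Y, 18.0 is adult.
    """
    if age_years < 0 or not np.isfinite(age_years):
        raise ValueError(f"age must be a finite non-negative number, got {age_years}")
    if age_years < 1:
        return AgeGroup.INF_0_11M
    if age_years < 2:
        return AgeGroup.TOD_12_23M
    if age_years < 5:
        return AgeGroup.CHILD_2_4Y
    if age_years < 12:
        return AgeGroup.CHILD_5_11Y
    if age_years < 18:
        return AgeGroup.ADOL_12_17Y
    return AgeGroup.ADULT_18PLUS


def population_group(age_years: float, copd: bool) -> PopulationGroup:
    """Map (age, COPD flag) to a severity-matrix population.

    Pediatric patients with COPD are outside the cohort definition and are
    rejected.
    """
    if age_years < 0 or not np.isfinite(age_years):
        raise ValueError(f"age must be a finite non-negative number, got {age_years}")
    if age_years < 18:
        if copd:
            raise ValueError("pediatric (age < 18) patients with COPD are not supported")
        return PopulationGroup.PEDIATRIC_NO_COPD
    return PopulationGroup.ADULT_COPD if copd else PopulationGroup.ADULT_NO_COPD


def _to_grid(vital: str, value: float) -> int:
    """Round a value to the vital's granularity and return its grid index."""
    step = GRANULARITY[vital]
    lo, hi = CLAMP_BOUNDS[vital]
    idx = int(round(float(value) / step))
    lo_idx, hi_idx = int(round(lo / step)), int(round(hi / step))
    if idx < lo_idx or idx > hi_idx:
        raise ValueError(
            f"{vital} value {value} outside clamped domain [{lo}, {hi}]"
        )
    return idx - lo_idx


def _grid_size(vital: str) -> int:
    step = GRANULARITY[vital]
    lo, hi = CLAMP_BOUNDS[vital]
    return int(round(hi / step)) - int(round(lo / step)) + 1


def _canonicalize(
    bands: Sequence[Band],
    vital: str,
    group: str,
    table: str,
    *,
    ambient_air_fill: bool,
) -> tuple[np.ndarray, list[Correction]]:
    """Resolve a printed band list into a total level lookup over the grid.

    Overlapping claims go to the more severe band; unclaimed runs are annexed
    by the more severe flanking band.  When ``ambient_air_fill`` is set,
    unclaimed runs *above* the highest claimed cell score 0 instead (SpO2 has
    no high side on ambient air).
    """
    step = GRANULARITY[vital]
    n = _grid_size(vital)
    lo = CLAMP_BOUNDS[vital][0]
    claims: list[np.ndarray] = []
    for band in bands:
        mask = np.zeros(n, dtype=bool)
        a = max(0, int(round((band.lower - lo) / step)))
        b = min(n - 1, int(round((band.upper - lo) / step)))
        if a <= b:
            mask[a : b + 1] = True
        claims.append(mask)
    claim_count = np.sum(claims, axis=0)
    levels = np.full(n, -1, dtype=np.int8)
    # Paint in ascending severity so more severe bands win contested cells.
    for band, mask in sorted(zip(bands, claims), key=lambda bm: bm[0].level):
        levels[mask] = band.level
    for band, mask in zip(bands, claims):
        if mask.any() and not np.any(levels[mask] == band.level):
            raise MatrixLoadError(
                f"{table}:{vital}:{group}: band {band} is fully shadowed by more "
                "severe bands after canonicalization"
            )

    corrections: list[Correction] = []

    def record(kind: str, a: int, b: int, level: int) -> None:
        corrections.append(
            Correction(
                table=table,
                vital=vital,
                group=group,
                kind=kind,
                lower=round(lo + a * step, 10),
                upper=round(lo + b * step, 10),
                resolved_level=int(level),
            )
        )

    for a, b in _runs(claim_count > 1):
        record("overlap", a, b, int(levels[a : b + 1].max()))

    for a, b in _runs(claim_count == 0):
        left = levels[a - 1] if a > 0 else -1
        right = levels[b + 1] if b + 1 < n else -1
        if right == -1 and ambient_air_fill:
            # Above the topmost band: ambient air, scores 0.
            levels[a : b + 1] = 0
            record("ambient_air", a, b, 0)
            continue
        if left == -1 and right == -1:
            raise MatrixLoadError(
                f"{table}:{vital}:{group}: no band claims any cell"
            )
        winner = max(left, right)
        levels[a : b + 1] = winner
        record("gap", a, b, winner)

    assert (levels >= 0).all()
    return levels, corrections


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, as inclusive (start, end)."""
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        out.append((int(idx[s]), int(idx[e])))
    return out


@dataclass
class ThresholdMatrix:
    """Canonicalized TAG matrix: per (vital, age group) level lookups."""

    bands: dict[tuple[str, AgeGroup], tuple[Band, ...]]
    levels: dict[tuple[str, AgeGroup], np.ndarray]
    provenance: str
    corrections: list[Correction] = field(default_factory=list)

    def lookup(self, vital: str, group: AgeGroup) -> np.ndarray:
        try:
            return self.levels[(vital, group)]
        except KeyError:
            raise KeyError(f"no bands configured for vital={vital!r}, group={group}")

    def score(self, vital: str, value: float, group: AgeGroup) -> int:
        return int(self.lookup(vital, group)[_to_grid(vital, value)])

    def score_array(self, vital: str, values: np.ndarray, group: AgeGroup) -> np.ndarray:
        """Vectorized `score` over a clamped, rounded value array."""
        step = GRANULARITY[vital]
        lo = CLAMP_BOUNDS[vital][0]
        idx = np.round((np.asarray(values, dtype=float) - lo) / step).astype(np.int64)
        table = self.lookup(vital, group)
        if idx.min(initial=0) < 0 or idx.max(initial=0) >= table.size:
            raise ValueError(f"{vital} values outside clamped domain")
        return table[idx]


@dataclass
class SeverityMatrix:
    """Canonicalized SpO2 severity matrix per population group."""

    bands: dict[PopulationGroup, tuple[Band, ...]]
    levels: dict[PopulationGroup, np.ndarray]
    corrections: list[Correction] = field(default_factory=list)

    def label(self, spo2_pct: float, pop: PopulationGroup) -> int:
        return int(self.levels[pop][_to_grid("spo2", spo2_pct)])

    def label_array(self, spo2_pct: np.ndarray, pop: PopulationGroup) -> np.ndarray:
        idx = np.round(np.asarray(spo2_pct, dtype=float)).astype(np.int64)
        table = self.levels[pop]
        if idx.min(initial=0) < 0 or idx.max(initial=0) >= table.size:
            raise ValueError("spo2 values outside [0, 100]")
        return table[idx]

    def band_for(self, pop: PopulationGroup, level: int) -> tuple[float, float]:
        """Inclusive canonical SpO2 range labeled ``level`` for ``pop``."""
        lev = self.levels[pop]
        cells = np.flatnonzero(lev == level)
        if cells.size == 0:
            raise KeyError(f"no SpO2 cell labeled {level} for {pop}")
        return float(cells.min()), float(cells.max())


def _parse_band(raw: Mapping, vital: str) -> Band:
    lo, hi = CLAMP_BOUNDS[vital]
    lower = raw.get("lower")
    upper = raw.get("upper")
    return Band(
        level=int(raw["level"]),
        side=str(raw.get("side", "na")),
        lower=lo if lower is None else float(lower),
        upper=hi if upper is None else float(upper),
    )


def default_config_path() -> Path:
    """Path of the shipped NEWS2+ threshold configuration."""
    return Path(str(resources.files("oxytriage").joinpath("data/news2plus.yaml")))


def load_matrices(path: str | Path | None = None) -> tuple[ThresholdMatrix, SeverityMatrix]:
    """Load and canonicalize (ThresholdMatrix, SeverityMatrix) from YAML.

    Parameters
    ----------
    path
        Config file; defaults to the shipped NEWS2+ tables.

    Raises
    ------
    MatrixLoadError
        If the schema is invalid or a table cannot be made total (for
        example a band entirely shadowed by more severe bands).
    """
    cfg_path = Path(path) if path is not None else default_config_path()
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("tag_matrix", "severity_matrix"):
        if key not in cfg:
            raise MatrixLoadError(f"config missing required section {key!r}")

    tag_bands: dict[tuple[str, AgeGroup], tuple[Band, ...]] = {}
    tag_levels: dict[tuple[str, AgeGroup], np.ndarray] = {}
    corrections: list[Correction] = []
    for group_key, vitals_cfg in cfg["tag_matrix"].items():
        group = AgeGroup(group_key)
        missing = set(VITALS) - set(vitals_cfg)
        if missing:
            raise MatrixLoadError(f"tag_matrix[{group_key}] missing vitals: {sorted(missing)}")
        for vital, raw_bands in vitals_cfg.items():
            if vital not in VITALS:
                raise MatrixLoadError(f"unknown vital {vital!r} in tag_matrix[{group_key}]")
            bands = tuple(_parse_band(rb, vital) for rb in raw_bands)
            if vital == "spo2" and any(b.side == "high" for b in bands):
                raise MatrixLoadError("SpO2 must not define high-side bands (ambient air)")
            levels, corr = _canonicalize(
                bands, vital, group_key, "tag", ambient_air_fill=(vital == "spo2")
            )
            tag_bands[(vital, group)] = bands
            tag_levels[(vital, group)] = levels
            corrections.extend(corr)
    tmatrix = ThresholdMatrix(
        bands=tag_bands,
        levels=tag_levels,
        provenance=str(cfg.get("provenance", cfg_path.name)),
        corrections=corrections,
    )

    sev_bands: dict[PopulationGroup, tuple[Band, ...]] = {}
    sev_levels: dict[PopulationGroup, np.ndarray] = {}
    sev_corr: list[Correction] = []
    for pop_key, raw_bands in cfg["severity_matrix"].items():
        pop = PopulationGroup(pop_key)
        bands = tuple(
            _parse_band({**rb, "side": "baseline" if int(rb["level"]) == 0 else "low"}, "spo2")
            for rb in raw_bands
        )
        if len({b.level for b in bands}) != 4:
            raise MatrixLoadError(f"severity_matrix[{pop_key}] must define all 4 classes")
        levels, corr = _canonicalize(
            bands, "spo2", pop_key, "severity", ambient_air_fill=True
        )
        if np.any(np.diff(levels) > 0):
            raise MatrixLoadError(
                f"severity_matrix[{pop_key}] is not monotone non-increasing in SpO2"
            )
        sev_bands[pop] = bands
        sev_levels[pop] = levels
        sev_corr.extend(corr)
    smatrix = SeverityMatrix(bands=sev_bands, levels=sev_levels, corrections=sev_corr)
    return tmatrix, smatrix


def corrections_report(*matrices: ThresholdMatrix | SeverityMatrix) -> list[dict]:
    """All canonicalization edits of the given matrices as JSON-ready dicts."""
    return [c.to_dict() for m in matrices for c in m.corrections]


def write_corrections_report(path: str | Path, *matrices) -> None:
    Path(path).write_text(json.dumps(corrections_report(*matrices), indent=2))


def tag_score(vital: str, value: float, group: AgeGroup, matrix: ThresholdMatrix) -> int:
    """TAG level (0-3) of one vital measurement for one age group."""
    return matrix.score(vital, value, group)


def tag_vector(
    record: Mapping[str, float], group: AgeGroup, matrix: ThresholdMatrix
) -> tuple[int, ...]:
    """TAG levels for all six vitals, in canonical vital order.

    ``record`` must contain every vital (the pipeline guarantees completeness
    post-imputation); a missing vital is a contract violation.
    """
    missing = [v for v in VITALS if v not in record or record[v] is None]
    if missing:
        raise ValueError(f"tag_vector requires all six vitals; missing {missing}")
    return tuple(matrix.score(v, record[v], group) for v in VITALS)


def severity_label(
    spo2_pct: float, age_years: float, copd: bool, matrix: SeverityMatrix
) -> int:
    """Hypoxemia severity class (0 normal .. 3 severe) from SpO2."""
    if not 0 <= spo2_pct <= 100:
        raise ValueError(f"spo2 must be in [0, 100], got {spo2_pct}")
    return matrix.label(spo2_pct, population_group(age_years, copd))


def baseline_band(matrix: ThresholdMatrix, vital: str, group: AgeGroup) -> tuple[float, float]:
    """Inclusive canonical level-0 range for (vital, group); used by the simulator."""
    step = GRANULARITY[vital]
    lo = CLAMP_BOUNDS[vital][0]
    lev = matrix.lookup(vital, group)
    cells = np.flatnonzero(lev == 0)
    if cells.size == 0:  # pragma: no cover - all shipped tables have a baseline
        raise KeyError(f"no baseline band for {vital}/{group}")
    return lo + step * float(cells.min()), lo + step * float(cells.max())
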