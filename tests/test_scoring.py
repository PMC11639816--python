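"""Scoring: age groups, TAG scores, severity labels, canonicalization."""

import numpy as np
import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from oxytriage.scoring import (
    CLAMP_BOUNDS,
    GRANULARITY,
    VITALS,
    AgeGroup,
    MatrixLoadError,
    PopulationGroup,
    assign_age_group,
    corrections_report,
    default_config_path,
    load_matrices,
    population_group,
    severity_label,
    tag_score,
    tag_vector,
)


class TestAgeGroup:
    @pytest.mark.parametrize(
        "age, expected",
        [
            (0.5, AgeGroup.INF_0_11M),
            (0.0, AgeGroup.INF_0_11M),
            (1.0, AgeGroup.TOD_12_23M),
            (2.0, AgeGroup.CHILD_2_4Y),
            (4.99, AgeGroup.CHILD_2_4Y),
            (5.0, AgeGroup.CHILD_5_11Y),
            (12.0, AgeGroup.ADOL_12_17Y),
            (17.9, AgeGroup.ADOL_12_17Y),
            (18.0, AgeGroup.ADULT_18PLUS),
            (95.0, AgeGroup.ADULT_18PLUS),
        ],
    )
    def test_examples(self, age, expected):
        assert assign_age_group(age) is expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            assign_age_group(-0.1)

    @given(st.floats(min_value=0, max_value=120, allow_nan=False))
    def test_total_and_deterministic(self, age):
        assert assign_age_group(age) is assign_age_group(age)


class TestPopulationGroup:
    def test_pediatric_copd_rejected(self):
        with pytest.raises(ValueError, match="COPD"):
            population_group(10.0, copd=True)

    @pytest.mark.parametrize(
        "age, copd, expected",
        [
            (40.0, False, PopulationGroup.ADULT_NO_COPD),
            (70.0, True, PopulationGroup.ADULT_COPD),
            (8.0, False, PopulationGroup.PEDIATRIC_NO_COPD),
            (18.0, True, PopulationGroup.ADULT_COPD),
        ],
    )
    def test_examples(self, age, copd, expected):
        assert population_group(age, copd) is expected


class TestTagScore:
    @pytest.mark.parametrize(
        "vital, value, group, expected",
        [
            ("heart_rate", 150, AgeGroup.ADULT_18PLUS, 3),
            ("respiratory_rate", 15, AgeGroup.ADULT_18PLUS, 0),
            ("spo2", 93, AgeGroup.CHILD_5_11Y, 1),
            ("temperature", 37.0, AgeGroup.ADULT_18PLUS, 0),
            ("spo2", 84, AgeGroup.ADULT_18PLUS, 3),
            ("heart_rate", 41, AgeGroup.ADULT_18PLUS, 2),
            ("temperature", 39.9, AgeGroup.ADULT_18PLUS, 3),
        ],
    )
    def test_printed_examples(self, matrices, vital, value, group, expected):
        tmatrix, _ = matrices
        assert tag_score(vital, value, group, tmatrix) == expected

    def test_unknown_vital_is_config_error(self, matrices):
        tmatrix, _ = matrices
        with pytest.raises(KeyError):
            tmatrix.score("lactate", 2.0, AgeGroup.ADULT_18PLUS)

    def test_out_of_domain_value_rejected(self, matrices):
        tmatrix, _ = matrices
        with pytest.raises(ValueError):
            tag_score("heart_rate", 301, AgeGroup.ADULT_18PLUS, tmatrix)

    def test_spo2_above_baseline_scores_zero(self, matrices):
        tmatrix, _ = matrices
        for group in AgeGroup:
            assert tag_score("spo2", 100, group, tmatrix) == 0


class TestTagVector:
    ADULT_BASELINE = {
        "respiratory_rate": 15,
        "spo2": 98,
        "heart_rate": 75,
        "systolic_bp": 117,
        "diastolic_bp": 70,
        "temperature": 37.0,
    }

    def test_all_baseline(self, matrices):
        tmatrix, _ = matrices
        assert tag_vector(self.ADULT_BASELINE, AgeGroup.ADULT_18PLUS, tmatrix) == (
            0, 0, 0, 0, 0, 0,
        )

    def test_single_abnormal_spo2(self, matrices):
        tmatrix, _ = matrices
        record = dict(self.ADULT_BASELINE, spo2=84)
        vec = tag_vector(record, AgeGroup.ADULT_18PLUS, tmatrix)
        assert vec[VITALS.index("spo2")] == 3
        assert sum(vec) == 3

    def test_two_abnormal(self, matrices):
        tmatrix, _ = matrices
        record = dict(self.ADULT_BASELINE, heart_rate=41, temperature=39.9)
        vec = tag_vector(record, AgeGroup.ADULT_18PLUS, tmatrix)
        assert vec[VITALS.index("heart_rate")] == 2
        assert vec[VITALS.index("temperature")] == 3

    def test_missing_vital_is_contract_violation(self, matrices):
        tmatrix, _ = matrices
        record = dict(self.ADULT_BASELINE)
        del record["heart_rate"]
        with pytest.raises(ValueError, match="heart_rate"):
            tag_vector(record, AgeGroup.ADULT_18PLUS, tmatrix)


class TestSeverityLabel:
    @pytest.mark.parametrize(
        "spo2, age, copd, expected",
        [
            (96, 40, False, 0),
            (98, 30, False, 0),
            (80, 70, True, 3),
            (86, 8, False, 2),
            (92, 40, False, 2),
            (94, 40, False, 1),
            (91, 40, False, 3),
            (88, 70, True, 0),
            (100, 70, True, 0),  # ambient-air fill above the COPD normal band
        ],
    )
    def test_printed_examples(self, matrices, spo2, age, copd, expected):
        _, smatrix = matrices
        assert severity_label(spo2, age, copd, smatrix) == expected

    def test_pediatric_copd_rejected(self, matrices):
        _, smatrix = matrices
        with pytest.raises(ValueError):
            severity_label(95, 10, True, smatrix)

    def test_out_of_range_spo2_rejected(self, matrices):
        _, smatrix = matrices
        with pytest.raises(ValueError):
            severity_label(101, 40, False, smatrix)

    def test_monotone_in_spo2(self, matrices):
        _, smatrix = matrices
        for pop in PopulationGroup:
            labels = smatrix.levels[pop]
            assert (np.diff(labels) <= 0).all()

    def test_partition_of_domain(self, matrices):
        _, smatrix = matrices
        for pop in PopulationGroup:
            assert smatrix.levels[pop].size == 101
            assert set(np.unique(smatrix.levels[pop])) == {0, 1, 2, 3}


def _printed_band_oracle(raw_bands, vital, value):
    """First matching printed band after a severity-ordered scan, or None."""
    lo, hi = CLAMP_BOUNDS[vital]
    for band in sorted(raw_bands, key=lambda b: -b["level"]):
        lower = lo if band.get("lower") is None else band["lower"]
        upper = hi if band.get("upper") is None else band["upper"]
        if lower <= value <= upper:
            return band["level"]
    return None


def _grid(vital):
    lo, hi = CLAMP_BOUNDS[vital]
    step = GRANULARITY[vital]
    return np.round(np.arange(lo, hi + step / 2, step), 10)


class TestOracleEquivalence:
    def test_tag_matrix_matches_printed_band_scan(self, matrices):
        """Dense-grid equivalence against an independent band-scan oracle,
        excluding cells touched by a recorded correction."""
        tmatrix, _ = matrices
        raw = yaml.safe_load(default_config_path().read_text())["tag_matrix"]
        corrected = {
            (c.vital, c.group): [] for c in tmatrix.corrections
        }
        for c in tmatrix.corrections:
            corrected[(c.vital, c.group)].append((c.lower, c.upper))
        n_checked = 0
        for group_key, vitals_cfg in raw.items():
            group = AgeGroup(group_key)
            for vital, raw_bands in vitals_cfg.items():
                skip = corrected.get((vital, group_key), [])
                for value in _grid(vital):
                    if any(lo <= value <= hi for lo, hi in skip):
                        continue
                    expected = _printed_band_oracle(raw_bands, vital, value)
                    if expected is None:  # ambient-air region above SpO2 baseline
                        assert vital == "spo2"
                        expected = 0
                    assert tag_score(vital, value, group, tmatrix) == expected
                    n_checked += 1
        assert n_checked > 5000

    def test_severity_matrix_matches_printed_band_scan(self, matrices):
        _, smatrix = matrices
        raw = yaml.safe_load(default_config_path().read_text())["severity_matrix"]
        skip = {
            (c.group): [(c.lower, c.upper)] for c in smatrix.corrections
        }
        for pop_key, raw_bands in raw.items():
            pop = PopulationGroup(pop_key)
            for value in range(101):
                if any(lo <= value <= hi for lo, hi in skip.get(pop_key, [])):
                    continue
                expected = _printed_band_oracle(raw_bands, "spo2", value)
                assert smatrix.label(value, pop) == expected


class TestLoadMatrices:
    def test_default_config_has_corrections(self, matrices):
        report = corrections_report(*matrices)
        assert len(report) > 0
        kinds = {c["kind"] for c in report}
        assert {"overlap", "gap"} <= kinds
        # the known infant diastolic overlap is recorded
        assert any(
            c["vital"] == "diastolic_bp"
            and c["group"] == "infant_0_11m"
            and c["kind"] == "overlap"
            for c in report
        )

    def test_disjoint_toy_matrix_has_no_corrections(self, tmp_path):
        cfg = {
            "provenance": "toy",
            "tag_matrix": {
                "adult": {
                    # band edges at each vital's own granularity, no gaps
                    v: [
                        {
                            "level": 3,
                            "side": "low",
                            "lower": None,
                            "upper": 49.9 if v == "temperature" else 49,
                        },
                        {"level": 0, "side": "baseline", "lower": 50, "upper": None},
                    ]
                    for v in VITALS
                }
            },
            "severity_matrix": {
                "adult_no_copd": [
                    {"level": 3, "lower": None, "upper": 25},
                    {"level": 2, "lower": 26, "upper": 50},
                    {"level": 1, "lower": 51, "upper": 75},
                    {"level": 0, "lower": 76, "upper": 100},
                ]
            },
        }
        path = tmp_path / "toy.yaml"
        path.write_text(yaml.safe_dump(cfg))
        tmatrix, smatrix = load_matrices(path)
        assert corrections_report(tmatrix, smatrix) == []

    def test_missing_spo2_row_is_load_error(self, tmp_path):
        cfg = yaml.safe_load(default_config_path().read_text())
        del cfg["tag_matrix"]["adult"]["spo2"]
        path = tmp_path / "broken.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(MatrixLoadError, match="spo2"):
            load_matrices(path)

    def test_fully_shadowed_band_is_load_error(self, tmp_path):
        cfg = yaml.safe_load(default_config_path().read_text())
        # mild-low band entirely inside the severe band
        cfg["tag_matrix"]["adult"]["heart_rate"] = [
            {"level": 3, "side": "low", "lower": 0, "upper": 60},
            {"level": 1, "side": "low", "lower": 50, "upper": 59},
            {"level": 0, "side": "baseline", "lower": 61, "upper": 300},
        ]
        path = tmp_path / "shadow.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(MatrixLoadError, match="shadowed"):
            load_matrices(path)

    def test_totality_over_all_grids(self, matrices):
        tmatrix, _ = matrices
        for (vital, group), levels in tmatrix.levels.items():
            assert levels.size == _grid(vital).size
            assert ((levels >= 0) & (levels <= 3)).all()
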