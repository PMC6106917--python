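"""Rule-based screening against the published healthy ranges and tables."""

import numpy as np
import pytest

from voicescreen import (
    AcousticProfile,
    HealthyRanges,
    SubjectMeta,
    classify_parameter,
    classify_rsi,
    classify_vhi,
    screen,
)
from voicescreen.clinical_reference import (
    KNOWN_VERDICT_ANOMALIES,
    iter_verdict_cells,
)


class TestClassifyParameter:
    @pytest.mark.parametrize(
        "value,parameter,gender,expected",
        [
            (217, "f0", "female", "healthy"),
            (188, "f0", "male", "pathological"),
            (1.046, "jitter", "female", "pathological"),
            (0.016, "shimmer", "female", "healthy"),
            (24.36, "hnr", "female", "healthy"),
            (24.36, "hnr", "male", "healthy"),
            (1.04, "jitter", "male", "pathological"),  # strict "< 1.04"
            (0.35, "shimmer", "female", "pathological"),  # strict "< 0.35"
            (20.0, "hnr", "male", "pathological"),  # strict "> 20"
            (189, "f0", "female", "healthy"),  # inclusive endpoints
            (280, "f0", "female", "healthy"),
            (104, "f0", "male", "healthy"),
            (158, "f0", "male", "healthy"),
        ],
    )
    def test_rule_boundaries(self, value, parameter, gender, expected):
        assert classify_parameter(value, parameter, gender) == expected

    def test_unknown_parameter(self):
        with pytest.raises(ValueError):
            classify_parameter(1.0, "cpp", "female")

    def test_oracle_equivalence_on_random_values(self):
        """Agreement with direct interval membership on random triples."""
        bounds = {
            ("f0", "female"): lambda v: 189 <= v <= 280,
            ("f0", "male"): lambda v: 104 <= v <= 158,
            ("jitter", "female"): lambda v: v < 1.04,
            ("jitter", "male"): lambda v: v < 1.04,
            ("shimmer", "female"): lambda v: v < 0.35,
            ("shimmer", "male"): lambda v: v < 0.35,
            ("hnr", "female"): lambda v: v > 20,
            ("hnr", "male"): lambda v: v > 20,
        }
        scales = {"f0": 600.0, "jitter": 3.0, "shimmer": 3.0, "hnr": 40.0}
        rng = np.random.default_rng(99)
        params = list(bounds)
        for _ in range(10_000):
            parameter, gender = params[rng.integers(len(params))]
            value = float(rng.random() * scales[parameter])
            expected = "healthy" if bounds[(parameter, gender)](value) else "pathological"
            assert classify_parameter(value, parameter, gender) == expected


class TestPublishedVerdicts:
    def test_reproduces_all_printed_verdicts_except_known_anomalies(self):
        """Every printed per-parameter verdict of the reliability and
        portability tables follows from the healthy ranges, except the
        three documented female-F0 anomalies."""
        mismatches = set()
        for cell_id, value, parameter, gender, printed in iter_verdict_cells():
            if classify_parameter(value, parameter, gender) != printed:
                mismatches.add(cell_id)
        assert mismatches == KNOWN_VERDICT_ANOMALIES


class TestScreen:
    def test_all_in_range_overall_healthy(self):
        profile = AcousticProfile(f0=220, jitter=0.5, shimmer=0.1, hnr=25)
        report = screen(profile, SubjectMeta(gender="female"))
        assert report.overall == "healthy"
        assert all(v == "healthy" for v in report.verdicts.values())

    def test_published_reliability_row(self):
        """A printed subject row: F0/HNR in range, jitter/shimmer out."""
        profile = AcousticProfile(f0=217, jitter=1.323, shimmer=1.520, hnr=24.36)
        report = screen(profile, SubjectMeta(gender="female"))
        assert report.verdicts == {
            "f0": "healthy",
            "jitter": "pathological",
            "shimmer": "pathological",
            "hnr": "healthy",
        }
        assert report.overall == "pathological"

    def test_rule_contrast_single_abnormal(self):
        profile = AcousticProfile(f0=220, jitter=0.5, shimmer=0.1, hnr=19.9)
        meta = SubjectMeta(gender="female")
        assert screen(profile, meta, overall_rule="any_abnormal").overall == "pathological"
        assert screen(profile, meta, overall_rule="majority").overall == "healthy"

    def test_unknown_rule(self):
        profile = AcousticProfile(f0=220, jitter=0.5, shimmer=0.1, hnr=25)
        with pytest.raises(ValueError):
            screen(profile, SubjectMeta(gender="female"), overall_rule="unanimous")


class TestQuestionnaireBands:
    @pytest.mark.parametrize(
        "score,band",
        [(0, "none"), (32, "none"), (33, "mild"), (43, "mild"), (44, "moderate"),
         (60, "moderate"), (61, "severe"), (180, "severe")],
    )
    def test_vhi_bands(self, score, band):
        assert classify_vhi(score) == band

    @pytest.mark.parametrize("score,band", [(0, "none"), (12, "none"), (13, "perceived"), (45, "perceived")])
    def test_rsi_bands(self, score, band):
        assert classify_rsi(score) == band

    def test_bands_partition_domains(self):
        for score in range(0, 181):
            classify_vhi(score)  # exactly one band, no gaps
        for score in range(0, 46):
            classify_rsi(score)

    @pytest.mark.parametrize("func,bad", [(classify_vhi, -1), (classify_vhi, 181),
                                          (classify_rsi, -1), (classify_rsi, 46)])
    def test_out_of_range_scores(self, func, bad):
        with pytest.raises(ValueError):
            func(bad)


def test_ranges_override_from_yaml(tmp_path):
    path = tmp_path / "ranges.yaml"
    path.write_text("hnr:\n  female: {low: 15.0, low_inclusive: false}\n")
    ranges = HealthyRanges.from_yaml(path)
    assert classify_parameter(16.0, "hnr", "female", ranges) == "healthy"
    assert classify_parameter(16.0, "hnr", "male", ranges) == "pathological"
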