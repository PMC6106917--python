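"""Classification metrics, reliability and cross-device dispersion."""

import numpy as np
import pytest

from voicescreen import (
    ConfusionCounts,
    UndefinedMetricError,
    confusion,
    confusion_from_rates,
    device_dispersion,
    metrics_from_confusion,
    repeatability_rate,
)
from voicescreen.clinical_reference import PORTABILITY_VOICES


class TestConfusion:
    def test_perfect_classifier(self):
        truth = ["pathological"] * 10 + ["healthy"] * 5
        c = confusion(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 5, 0, 0)

    def test_all_pathological_predictions(self):
        truth = ["pathological"] * 3 + ["healthy"] * 2
        c = confusion(["pathological"] * 5, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 0, 2, 0)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(7)
        labels = ["healthy", "pathological"]
        pred = [labels[i] for i in rng.integers(0, 2, 20)]
        truth = [labels[i] for i in rng.integers(0, 2, 20)]
        c = confusion(pred, truth)
        tp = sum(p == t == "pathological" for p, t in zip(pred, truth))
        tn = sum(p == t == "healthy" for p, t in zip(pred, truth))
        fp = sum(p == "pathological" and t == "healthy" for p, t in zip(pred, truth))
        fn = sum(p == "healthy" and t == "pathological" for p, t in zip(pred, truth))
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(["healthy"], ["healthy", "pathological"])

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            confusion(["sick"], ["healthy"])


class TestMetrics:
    def test_symmetric_case(self):
        m = metrics_from_confusion(ConfusionCounts(tp=50, tn=50, fp=50, fn=50))
        assert (m.accuracy, m.sensitivity, m.specificity) == (50.0, 50.0, 50.0)

    def test_degenerate_extremes(self):
        m = metrics_from_confusion(ConfusionCounts(tp=10, fn=0, tn=0, fp=10))
        assert m.sensitivity == 100.0 and m.specificity == 0.0

    def test_published_jitter_row(self):
        m = metrics_from_confusion(ConfusionCounts(tp=144, tn=7, fp=51, fn=6)).rounded(1)
        assert (m.accuracy, m.sensitivity, m.specificity) == (72.6, 96.0, 12.1)

    def test_zero_denominator_identifies_metric(self):
        with pytest.raises(UndefinedMetricError) as err:
            metrics_from_confusion(ConfusionCounts(tp=5, fn=5, tn=0, fp=0))
        assert err.value.metric == "specificity"

    def test_accuracy_identity(self):
        """accuracy = (sens*P + spec*N) / (P+N) for any counts."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 200, 4))
            m = metrics_from_confusion(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            p, n = tp + fn, tn + fp
            assert m.accuracy == pytest.approx((m.sensitivity * p + m.specificity * n) / (p + n))


class TestReconstruction:
    @pytest.mark.parametrize(
        "rates,expected",
        [
            ((150, 58, 0.960, 0.121), (144, 6, 7, 51)),
            ((150, 58, 0.533, 0.569), (80, 70, 33, 25)),
            ((100, 100, 1.0, 1.0), (100, 0, 100, 0)),
        ],
    )
    def test_counts_from_rates(self, rates, expected):
        c = confusion_from_rates(*rates)
        assert (c.tp, c.fn, c.tn, c.fp) == expected

    def test_roundtrip_reproduces_rates_within_rounding(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n_p, n_h = int(rng.integers(10, 300)), int(rng.integers(10, 300))
            sens, spec = rng.random(), rng.random()
            c = confusion_from_rates(n_p, n_h, sens, spec)
            m = metrics_from_confusion(c)
            assert abs(m.sensitivity / 100 - sens) <= 0.5 / n_p + 1e-12
            assert abs(m.specificity / 100 - spec) <= 0.5 / n_h + 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            confusion_from_rates(0, 10, 0.5, 0.5)
        with pytest.raises(ValueError):
            confusion_from_rates(10, 10, 1.5, 0.5)


class TestReliability:
    def test_published_fraction(self):
        pairs = [("healthy", "pathological")] * 29 + [("healthy", "healthy")] * 179
        assert round(repeatability_rate(pairs), 3) == 0.139

    def test_concordant_and_half(self):
        assert repeatability_rate([("healthy", "healthy")] * 4) == 0.0
        pairs = [("healthy", "pathological")] * 5 + [("pathological", "pathological")] * 5
        assert repeatability_rate(pairs) == 0.5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            repeatability_rate([])


def _two_pass_std(values):
    """Brute-force two-pass sample standard deviation."""
    mean = sum(values) / len(values)
    return (sum((v - mean) ** 2 for v in values) / (len(values) - 1)) ** 0.5


class TestDispersion:
    def test_published_f0_cells(self):
        assert device_dispersion([244, 203, 189, 210]) == pytest.approx(23.36, abs=0.005)
        assert device_dispersion([233, 237, 254, 209]) == pytest.approx(18.55, abs=0.005)

    def test_constant_values(self):
        assert device_dispersion([5, 5, 5, 5]) == 0.0

    def test_agrees_with_two_pass_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            values = rng.random(int(rng.integers(2, 12))) * 100
            assert device_dispersion(values) == pytest.approx(_two_pass_std(values), rel=1e-10)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            device_dispersion([5.0])


def test_all_published_dispersion_cells_reproduce():
    """Every printed cross-device standard deviation follows from its four
    printed measurements with the sample (n-1) divisor, apart from the two
    documented misprints."""
    from voicescreen.clinical_reference import KNOWN_DEVST_ANOMALIES, matches_printed

    for voice in PORTABILITY_VOICES:
        for parameter, values in voice["values"].items():
            if (voice["voice"], parameter) in KNOWN_DEVST_ANOMALIES:
                continue
            computed = device_dispersion(values)
            printed = voice["devst"][parameter]
            assert matches_printed(computed, printed), (
                voice["voice"], parameter, computed, printed
            )
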