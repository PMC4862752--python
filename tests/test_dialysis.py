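import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import szquant as sz
from szquant.dialysis import ESTRADIOL_MW_G_PER_MOL


def _curve_samples(curve, concs, reps=2):
    x = np.repeat(concs, reps)
    return x, np.asarray(curve.predict(x), dtype=float)


class TestProbeRecovery:
    def test_measured_recovery_values(self):
        # overall ~30.1% and 31.3% at the 0.25 ng/ml bath
        assert sz.probe_recovery(0.301, 1.0).percent == pytest.approx(30.1)
        assert sz.probe_recovery(0.07825, 0.25).percent == pytest.approx(31.3)

    def test_identity_bath(self):
        assert sz.probe_recovery(0.8, 0.8).percent == pytest.approx(100.0)

    def test_zero_bath_rejected(self):
        with pytest.raises(ValueError, match="bath"):
            sz.probe_recovery(0.1, 0.0)


class TestFourPL:
    STANDARDS = sz.dilution_series()

    def test_dilution_series_endpoints(self):
        s = self.STANDARDS
        assert s.size == 6
        assert s[0] == pytest.approx(200.0)
        assert s[-1] == pytest.approx(2.048)

    def test_noiseless_parameter_recovery(self):
        truth = sz.StandardCurve(a=2.1, b=1.3, c=18.0, d=0.15)
        x, y = _curve_samples(truth, self.STANDARDS)
        fit = sz.fit_4pl(x, y)
        for name in "abcd":
            assert getattr(fit, name) == pytest.approx(getattr(truth, name), rel=1e-6)

    def test_inversion_roundtrip(self):
        truth = sz.StandardCurve(a=2.0, b=1.1, c=20.0, d=0.1)
        x, y = _curve_samples(truth, self.STANDARDS)
        fit = sz.fit_4pl(x, y)
        conc = sz.invert_4pl(fit, float(truth.predict(12.8)))
        assert conc == pytest.approx(12.8, rel=0.01)

    def test_response_beyond_asymptotes_flagged(self):
        curve = sz.StandardCurve(a=2.0, b=1.0, c=10.0, d=0.1)
        with pytest.raises(ValueError, match="asymptote"):
            sz.invert_4pl(curve, 2.5)

    def test_non_monotone_standards_rejected(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        y = np.array([1.0, 0.8, 0.9, 0.5, 0.3])
        with pytest.raises(ValueError, match="monotone"):
            sz.fit_4pl(x, y)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="5 distinct"):
            sz.fit_4pl([1, 2, 4, 8], [1.0, 0.8, 0.5, 0.2])

    def test_random_parameter_recovery(self):
        """Noiseless curves across random parameter draws recover to high
        relative accuracy (scaled-down version of the full sweep)."""
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(20):
            truth = sz.StandardCurve(
                a=rng.uniform(1.5, 3.0), b=rng.uniform(0.6, 2.5),
                c=rng.uniform(5.0, 80.0), d=rng.uniform(0.02, 0.5),
            )
            x, y = _curve_samples(truth, self.STANDARDS)
            fit = sz.fit_4pl(x, y)
            for name in "abcd":
                rel = abs(getattr(fit, name) - getattr(truth, name)) / abs(getattr(truth, name))
                worst = max(worst, rel)
        assert worst < 1e-4


class TestUnits:
    @pytest.mark.parametrize(
        "pgml, pm",
        [(16.7, 61.3), (30.0, 110.1), (0.0, 0.0)],
    )
    def test_printed_conversion_pairs(self, pgml, pm):
        assert sz.pgml_to_pm(pgml) == pytest.approx(pm, abs=0.05)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(x=st.floats(0, 1e4), alpha=st.floats(0.01, 100))
    def test_linearity(self, x, alpha):
        assert sz.pgml_to_pm(alpha * x) == pytest.approx(alpha * sz.pgml_to_pm(x), rel=1e-12)

    def test_mw_constant(self):
        assert ESTRADIOL_MW_G_PER_MOL == pytest.approx(272.38)


class TestTissueEstimate:
    def test_peak_tissue_estimate(self):
        tissue = sz.tissue_estimate(30.0, 0.30)
        assert tissue == pytest.approx(100.0)
        assert sz.pgml_to_pm(tissue) == pytest.approx(367.1, abs=0.5)

    def test_full_recovery_is_identity(self):
        assert sz.tissue_estimate(6.3, 1.0) == 6.3

    def test_basal_estimate(self):
        assert sz.tissue_estimate(6.3, 0.301) == pytest.approx(20.93, abs=0.01)

    def test_roundtrip_with_probe_recovery(self):
        rec = sz.probe_recovery(0.32, 1.0)
        assert sz.tissue_estimate(0.32, rec.recovery_fraction) == pytest.approx(1.0)

    def test_zero_recovery_rejected(self):
        with pytest.raises(ValueError, match="recovery"):
            sz.tissue_estimate(10.0, 0.0)


class TestPercentBaseline:
    def _samples(self, concs, n_base):
        out = []
        t = -30.0 * n_base
        for i, c in enumerate(concs):
            out.append(
                sz.DialysisSample(t, t + 30.0, c, "baseline" if i < n_base else "post_KA")
            )
            t += 30.0
        return out

    def test_constant_series(self):
        pct = sz.percent_baseline(self._samples([5, 5, 5, 5], 2))
        assert np.allclose(pct, 100.0)

    def test_triple_rise(self):
        pct = sz.percent_baseline(self._samples([5, 5, 15], 2))
        assert pct[-1] == pytest.approx(300.0)

    def test_per_subject_ratio_before_averaging(self):
        """A retrodialysis delta of +8.9 pg/ml on each subject's own baseline
        gives a cohort mean equal to the mean of within-subject ratios."""
        rng = np.random.default_rng(1)
        bases = rng.uniform(3.0, 8.0, size=10)
        ratios = []
        for base in bases:
            pct = sz.percent_baseline(self._samples([base, base, base + 8.9], 2))
            assert pct[-1] == pytest.approx((base + 8.9) / base * 100.0)
            ratios.append(pct[-1])
        expected = np.mean([(b + 8.9) / b * 100.0 for b in bases])
        assert np.mean(ratios) == pytest.approx(expected)

    def test_no_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            sz.percent_baseline(
                [sz.DialysisSample(0.0, 30.0, 5.0, "post_KA")]
            )


class TestClassifySeverity:
    def _trace(self, minutes_in_seizure):
        codes = np.full(7200, "none", dtype="U4")
        codes[: int(minutes_in_seizure * 60)] = "1_2"
        return sz.BehaviorTrace(codes=codes)

    @pytest.mark.parametrize(
        "minutes, expected",
        [(20, "mild"), (30, "moderate"), (90, "moderate"), (100, "severe")],
    )
    def test_boundaries(self, minutes, expected):
        assert sz.classify_severity(self._trace(minutes)) == expected

    def test_staring_does_not_count(self):
        codes = np.full(7200, "0", dtype="U4")  # staring is Racine 0, not 1-5
        assert sz.classify_severity(sz.BehaviorTrace(codes=codes)) == "mild"

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            sz.classify_severity(sz.BehaviorTrace(codes=np.full(100, "none")))


class TestAssayCV:
    def test_identical_replicates(self):
        out = sz.assay_cv({10.0: [4.0, 4.0, 4.0]})
        assert out["intra_cv_percent"] == 0.0

    def test_two_replicates_closed_form(self):
        out = sz.assay_cv({10.0: [8.0, 12.0]})
        assert out["intra_cv_percent"] == pytest.approx(28.28, abs=0.01)

    def test_known_noise_level_recovered(self):
        rng = np.random.default_rng(2)
        reps = {
            c: list(c * (1 + 0.26 * rng.standard_normal(200)))
            for c in sz.dilution_series()[:-1]  # 5.12-200 pg/ml range
        }
        out = sz.assay_cv(reps)
        assert out["intra_cv_percent"] == pytest.approx(26.0, rel=0.10)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            sz.assay_cv({10.0: [4.0]})
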