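"""Median-effect fitting and combination-index scoring."""

import numpy as np
import pytest

from intestsig.synergy import (
    DoseResponsePoint,
    MedianEffectFit,
    combination_index,
    dose_for_effect,
    effect_at_dose,
    isobologram,
    median_effect_fit,
    read_dose_response,
    viability_to_fa,
    write_ci_table,
)
from intestsig.synthetic_data import (
    DoseResponseConfig,
    generate_dose_response,
    single_agent_points,
)


def exact_points(m, dm, doses):
    return [DoseResponsePoint(d, 1.0 / (1.0 + (dm / d) ** m)) for d in doses]


class TestViabilityToFa:
    def test_no_effect_clipped_and_flagged(self):
        fa = viability_to_fa(100.0, 100.0)
        assert fa.fa == pytest.approx(1e-4)
        assert fa.clipped

    def test_plain_arithmetic(self):
        fa = viability_to_fa(25.0, 100.0)
        assert fa.fa == pytest.approx(0.75)
        assert not fa.clipped

    def test_stimulation_clipped(self):
        fa = viability_to_fa(130.0, 100.0)
        assert fa.fa == pytest.approx(1e-4)
        assert fa.clipped

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            viability_to_fa(10.0, 0.0)


class TestMedianEffectFit:
    def test_noiseless_recovery(self):
        fit = median_effect_fit(exact_points(2.0, 10.0, [1, 3, 10, 30, 100]))
        assert fit.m == pytest.approx(2.0, abs=1e-9)
        assert fit.Dm == pytest.approx(10.0, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_two_points_determine_the_line(self):
        fit = median_effect_fit(exact_points(1.5, 5.0, [2, 20]))
        assert fit.m == pytest.approx(1.5, abs=1e-12)
        assert fit.Dm == pytest.approx(5.0, rel=1e-12)

    def test_noisy_slope_recovery_within_five_percent(self):
        """sigma=0.05 on the log-effect, 6 doses: median |m_hat - m|/m < 5%."""
        errors = []
        for seed in range(100):
            res = generate_dose_response(
                DoseResponseConfig(sigma=0.05), seed=seed
            )
            fit = median_effect_fit(single_agent_points(res, "A"))
            errors.append(abs(fit.m - res.truth.fit_a.m) / res.truth.fit_a.m)
        assert np.median(errors) < 0.05

    def test_identical_doses_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_effect_fit([(5.0, 0.2), (5.0, 0.6)])

    def test_non_monotone_data_flagged(self):
        fit = median_effect_fit([(1.0, 0.8), (10.0, 0.5), (100.0, 0.2)])
        assert fit.m < 0
        assert fit.flagged
        with pytest.raises(ValueError, match="flagged"):
            dose_for_effect(fit, 0.5)

    def test_fa_outside_open_interval_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            median_effect_fit([(1.0, 0.0), (2.0, 0.5)])


class TestDoseForEffect:
    def test_half_effect_is_dm(self):
        for m in (0.5, 1.0, 3.3):
            fit = MedianEffectFit(m=m, Dm=7.0, r=1.0)
            assert dose_for_effect(fit, 0.5) == pytest.approx(7.0)

    def test_hand_inverted_hyperbola(self):
        # m=1, Dm=1: fa = D/(1+D), so fa=0.75 needs D=3
        fit = MedianEffectFit(m=1.0, Dm=1.0, r=1.0)
        assert dose_for_effect(fit, 0.75) == pytest.approx(3.0, abs=1e-12)

    def test_round_trip_with_effect_at_dose(self):
        fit = MedianEffectFit(m=1.8, Dm=12.0, r=1.0)
        for fa in (0.05, 0.5, 0.93):
            assert effect_at_dose(fit, dose_for_effect(fit, fa)) == pytest.approx(fa, abs=1e-9)

    def test_invalid_fa_rejected(self):
        fit = MedianEffectFit(m=1.0, Dm=1.0, r=1.0)
        for fa in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ValueError):
                dose_for_effect(fit, fa)


class TestCombinationIndex:
    def test_self_combination_is_exactly_additive(self):
        """An agent combined with itself at the observed single-agent effect: CI = 1."""
        fit = MedianEffectFit(m=1.7, Dm=9.0, r=1.0)
        d1, d2 = 4.0, 6.0
        fa = effect_at_dose(fit, d1 + d2)
        entry = combination_index(fit, fit, d1, d2, fa)
        assert entry.CI == pytest.approx(1.0, abs=1e-12)
        assert entry.classification == "additive"

    def test_hand_computed_example(self):
        fit = MedianEffectFit(m=1.0, Dm=1.0, r=1.0)
        entry = combination_index(fit, fit, 1.0, 1.0, 0.5)
        assert entry.Dx1 == pytest.approx(1.0)
        assert entry.CI == pytest.approx(2.0)
        assert entry.classification == "antagonism"

    def test_single_agent_degenerate(self):
        fit_a = MedianEffectFit(m=2.0, Dm=5.0, r=1.0)
        fit_b = MedianEffectFit(m=1.0, Dm=50.0, r=1.0)
        fa = effect_at_dose(fit_a, 8.0)
        entry = combination_index(fit_a, fit_b, 8.0, 0.0, fa)
        assert entry.CI == pytest.approx(8.0 / dose_for_effect(fit_a, fa))

    def test_both_doses_zero_rejected(self):
        fit = MedianEffectFit(m=1.0, Dm=1.0, r=1.0)
        with pytest.raises(ValueError, match="not both zero"):
            combination_index(fit, fit, 0.0, 0.0, 0.5)

    def test_dose_unit_rescaling_invariance(self):
        """Expressing one agent's doses in different units leaves CI unchanged."""
        fit_a = MedianEffectFit(m=1.4, Dm=20.0, r=1.0)
        fit_b = MedianEffectFit(m=2.2, Dm=3.0, r=1.0)
        ci = combination_index(fit_a, fit_b, 10.0, 2.0, 0.4).CI
        scale = 1000.0  # uM -> nM
        fit_a_nm = MedianEffectFit(m=1.4, Dm=20.0 * scale, r=1.0)
        ci_nm = combination_index(fit_a_nm, fit_b, 10.0 * scale, 2.0, 0.4).CI
        assert ci_nm == pytest.approx(ci, rel=1e-12)


class TestGeneratorInteraction:
    def test_additive_construction_scores_unity(self):
        """s=1, sigma=0: every combination point has CI = 1 to 1e-9."""
        res = generate_dose_response(DoseResponseConfig(sigma=0.0, interaction=1.0), seed=0)
        fit_a = median_effect_fit(single_agent_points(res, "A"))
        fit_b = median_effect_fit(single_agent_points(res, "B"))
        for row in res.combinations.itertuples():
            ci = combination_index(fit_a, fit_b, row.d1, row.d2, row.fa).CI
            assert ci == pytest.approx(1.0, abs=1e-9)

    def test_synergy_factor_recovered(self):
        """s=0.5, sigma=0: CI = 0.5 at every combination point."""
        res = generate_dose_response(DoseResponseConfig(sigma=0.0, interaction=0.5), seed=0)
        fit_a = median_effect_fit(single_agent_points(res, "A"))
        fit_b = median_effect_fit(single_agent_points(res, "B"))
        for row in res.combinations.itertuples():
            ci = combination_index(fit_a, fit_b, row.d1, row.d2, row.fa).CI
            assert ci == pytest.approx(0.5, abs=1e-9)
            assert combination_index(fit_a, fit_b, row.d1, row.d2, row.fa).classification == "synergy"


class TestIsobologram:
    def test_half_effect_intercepts_are_dm(self):
        fit_a = MedianEffectFit(m=1.0, Dm=4.0, r=1.0)
        fit_b = MedianEffectFit(m=2.0, Dm=9.0, r=1.0)
        iso = isobologram(fit_a, fit_b, fa_levels=[0.5])
        line = iso[iso["kind"] == "additivity_line"]
        assert set(line["x"]).issuperset({4.0, 0.0})
        assert set(line["y"]).issuperset({9.0, 0.0})

    def test_symmetric_fits_symmetric_intercepts(self):
        fit = MedianEffectFit(m=1.5, Dm=6.0, r=1.0)
        iso = isobologram(fit, fit, fa_levels=[0.3, 0.7])
        line = iso[iso["kind"] == "additivity_line"]
        for fa in (0.3, 0.7):
            level = line[line["fa"] == fa]
            assert set(level["x"]) == set(level["y"])

    def test_synergistic_points_below_unit_line(self):
        res = generate_dose_response(DoseResponseConfig(sigma=0.0, interaction=0.4), seed=2)
        fit_a = median_effect_fit(single_agent_points(res, "A"))
        fit_b = median_effect_fit(single_agent_points(res, "B"))
        entries = [
            combination_index(fit_a, fit_b, r.d1, r.d2, r.fa)
            for r in res.combinations.itertuples()
        ]
        iso = isobologram(fit_a, fit_b, fa_levels=[0.5], combination_points=entries)
        pts = iso[iso["kind"] == "combination"]
        assert ((pts["x_norm"] + pts["y_norm"]) < 1.0).all()


class TestTableIO:
    def test_dose_response_and_ci_round_trip(self, tmp_path):
        res = generate_dose_response(DoseResponseConfig(sigma=0.0), seed=1)
        path = tmp_path / "dr.tsv"
        res.single_agent.to_csv(path, sep="\t", index=False)
        per_agent = read_dose_response(path)
        assert set(per_agent) == {"A", "B"}
        fit_a = median_effect_fit(per_agent["A"])
        fit_b = median_effect_fit(per_agent["B"])
        entries = [
            combination_index(fit_a, fit_b, r.d1, r.d2, r.fa)
            for r in res.combinations.itertuples()
        ]
        out = tmp_path / "ci.tsv"
        write_ci_table(entries, out)
        header = out.read_text().splitlines()[0]
        assert header == "d1\td2\tfa\tDx1\tDx2\tCI\tclassification"
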