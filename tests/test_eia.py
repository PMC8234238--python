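"""Cross-reactivity prediction, fraction deconvolution and assay ranking."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fcmid.eia import (
    CrossReactivityMatrix,
    FractionSeries,
    attribute_fraction_activity,
    deconvolve_fractions,
    default_crossreactivity,
    predict_response,
    rank_assays,
)
from fcmid.simulate import SimulationConfig, simulate_fraction_study, simulate_fractionation


class TestMatrix:
    def test_bound_cells_contribute_zero(self):
        m = default_crossreactivity()
        assert m.response_pct("cortisol", "THF") == 0.0
        assert m.bounds.loc["cortisol", "THF"]
        assert m.bound_values.loc["cortisol", "THF"] == pytest.approx(0.001)

    def test_negative_crossreactivity_rejected(self):
        values = pd.DataFrame({"THF": [-1.0]}, index=["a"])
        with pytest.raises(ValueError):
            CrossReactivityMatrix(values)

    def test_csv_roundtrip_preserves_bounds(self, tmp_path):
        m = default_crossreactivity()
        path = tmp_path / "cr.csv"
        m.to_csv(path)
        loaded = CrossReactivityMatrix.from_csv(path)
        pd.testing.assert_frame_equal(
            loaded.values[m.compounds], m.values, check_like=True
        )
        pd.testing.assert_frame_equal(
            loaded.bounds[m.compounds], m.bounds, check_like=True
        )


class TestPredictResponse:
    def test_standard_responds_at_unity(self):
        m = default_crossreactivity()
        assert predict_response({"cortisol": 1.0}, m, "cortisol") == pytest.approx(1.00, abs=5e-3)

    def test_partial_crossreactant_attenuated(self):
        m = default_crossreactivity()
        assert predict_response({"3b-allo-THF": 1.0}, m, "cortisol") == pytest.approx(0.250, abs=5e-4)

    def test_thf_on_its_matched_assay(self):
        m = default_crossreactivity()
        assert predict_response({"THF": 1.0}, m, "50c") == pytest.approx(0.207, abs=5e-4)

    def test_bound_only_compound_contributes_nothing(self):
        m = default_crossreactivity()
        assert predict_response({"THF": 1e6}, m, "cortisol") == 0.0

    def test_unknown_assay_and_compound_rejected(self):
        m = default_crossreactivity()
        with pytest.raises(ValueError, match="assay"):
            predict_response({"THF": 1.0}, m, "nope")
        with pytest.raises(ValueError, match="compound"):
            predict_response({"nope": 1.0}, m, "50c")
        with pytest.raises(ValueError, match="negative"):
            predict_response({"THF": -1.0}, m, "50c")

    @given(
        st.floats(min_value=0.0, max_value=1e6),
        st.floats(min_value=0.0, max_value=1e6),
        st.floats(min_value=0.0, max_value=100.0),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_linear_and_additive(self, a, b, scale):
        m = default_crossreactivity()
        r_a = predict_response({"THF": a}, m, "50c")
        r_b = predict_response({"allo-THF": b}, m, "50c")
        r_both = predict_response({"THF": a, "allo-THF": b}, m, "50c")
        assert r_both == pytest.approx(r_a + r_b, rel=1e-9, abs=1e-9)
        assert predict_response({"THF": scale * a}, m, "50c") == pytest.approx(
            scale * r_a, rel=1e-9, abs=1e-6
        )


def toy_series(areas: dict, responses: dict, widths=None) -> FractionSeries:
    n = len(next(iter(areas.values())))
    if widths is None:
        bounds = [(float(i), float(i + 1)) for i in range(n)]
    else:
        edges = np.concatenate([[0.0], np.cumsum(widths)])
        bounds = [(edges[i], edges[i + 1]) for i in range(n)]
    return FractionSeries(
        animal="A",
        boundaries=bounds,
        eia={k: np.asarray(v, float) for k, v in responses.items()},
        areas=pd.DataFrame(areas, index=range(1, n + 1), dtype=float),
    )


class TestFractionSeries:
    def test_non_contiguous_boundaries_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            FractionSeries(
                "A", [(0.0, 1.0), (2.0, 3.0)],
                {"cortisol": np.zeros(2)},
                pd.DataFrame({"THF": [0.0, 0.0]}, index=[1, 2]),
            )

    def test_response_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            FractionSeries(
                "A", [(0.0, 1.0), (1.0, 2.0)],
                {"cortisol": np.zeros(3)},
                pd.DataFrame({"THF": [0.0, 0.0]}, index=[1, 2]),
            )


class TestDeconvolution:
    def test_noise_free_forward_inverse_recovery(self):
        m = default_crossreactivity()
        cfg = SimulationConfig()
        amounts = {"THF": 2000.0, "cortisol": 1500.0, "3b-allo-THF": 800.0}
        rts = {"THF": 36.0, "cortisol": 30.2, "3b-allo-THF": 26.3}
        series = simulate_fractionation(cfg, amounts, rts)
        for assay, name in [("50c", "THF"), ("cortisol", "cortisol"), ("37e", "3b-allo-THF")]:
            result = deconvolve_fractions(series, m, assay)
            total = float(result.compound_totals[name])
            assert total == pytest.approx(amounts[name], rel=0.01)

    def test_coeluting_inert_isomer_not_credited(self):
        # the high-cross-reactivity stereoisomer explains the signal; its
        # co-eluting near-inert isomer must not absorb any of it
        m = default_crossreactivity()
        areas = {"3b-allo-THF": [0.0, 800.0, 0.0], "3b-THF": [0.0, 300.0, 0.0]}
        responses = {"cortisol": [0.0, 200.0, 0.0]}
        result = attribute_fraction_activity(toy_series(areas, responses), m, "cortisol")
        assert "3b-allo-THF" in result.responsible
        assert "3b-THF" not in result.responsible
        assert "3b-THF" in result.excluded

    def test_bound_only_candidate_leaves_activity_unexplained(self):
        m = default_crossreactivity()
        areas = {"THF": [0.0, 2000.0, 0.0]}
        responses = {"cortisol": [0.0, 150.0, 0.0]}
        result = attribute_fraction_activity(toy_series(areas, responses), m, "cortisol")
        assert result.responsible == {}
        assert result.table["unexplained"].iloc[1]
        assert result.unexplained_share == pytest.approx(1.0)

    def test_elution_tail_area_is_not_evidence(self):
        # a 1e-4 relative tail from a neighbouring peak must not make the
        # compound a candidate in that fraction
        m = default_crossreactivity()
        areas = {"cortisol": [1000.0, 0.1], "3b-allo-THF": [0.0, 500.0]}
        responses = {"cortisol": [1000.0, 125.0]}
        result = deconvolve_fractions(toy_series(areas, responses), m, "cortisol")
        assert result.amounts.loc[2, "cortisol"] == 0.0
        assert result.amounts.loc[2, "3b-allo-THF"] == pytest.approx(500.0, rel=1e-6)

    def test_identical_crossreactivities_reported_unresolved(self):
        m = CrossReactivityMatrix.from_strings(
            {"a": {"x": 50.0, "y": 50.0}}
        )
        areas = {"x": [100.0], "y": [100.0]}
        responses = {"a": [100.0]}
        result = deconvolve_fractions(toy_series(areas, responses), m, "a")
        assert result.unresolved_groups == [frozenset({"x", "y"})]

    def test_unknown_assay_rejected(self):
        m = default_crossreactivity()
        with pytest.raises(ValueError):
            deconvolve_fractions(toy_series({"THF": [0.0]}, {"cortisol": [0.0]}), m, "nope")

    def test_noisy_recovery_within_ten_percent_median(self):
        m = default_crossreactivity()
        cfg = SimulationConfig()
        amounts = {"THF": 2000.0, "cortisol": 1500.0}
        rts = {"THF": 36.0, "cortisol": 30.2}
        clean = simulate_fractionation(cfg, amounts, rts)
        # 5% of the assay's own maximum response
        noise_sd = 0.05 * float(clean.eia["50c"].max())
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            series = simulate_fractionation(cfg, amounts, rts, rng=rng, noise_sd=noise_sd)
            result = deconvolve_fractions(series, m, "50c")
            fitted = float(result.compound_totals["THF"])
            errors.append(abs(fitted - amounts["THF"]) / amounts["THF"])
        assert float(np.median(errors)) <= 0.10


class TestRanking:
    def _attributions(self, cfg=None):
        cfg = cfg or SimulationConfig()
        m = default_crossreactivity()
        study = simulate_fraction_study(cfg)
        return {
            animal: {
                assay: attribute_fraction_activity(series, m, assay)
                for assay in m.assays
            }
            for animal, series in study.items()
        }

    def test_both_animal_assay_ranks_first(self):
        ranking = rank_assays(self._attributions())
        top = ranking.iloc[0]
        assert top["assay"] == "50c"
        assert top["primary_compound"] == "THF"
        assert top["animal_coverage"] == 1.0
        assert not top["single_animal_caveat"]

    def test_single_animal_input_carries_caveat(self):
        atts = self._attributions()
        one = {"Harvey": atts["Harvey"]}
        ranking = rank_assays(one)
        assert ranking["single_animal_caveat"].all()

    def test_ranking_invariant_to_animal_order(self):
        atts = self._attributions()
        fwd = rank_assays(atts)
        rev = rank_assays(dict(reversed(list(atts.items()))))
        pd.testing.assert_frame_equal(fwd, rev)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_assays({})
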