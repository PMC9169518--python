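import numpy as np
import pytest

from citrusauth import (
    BlendSpec,
    DECISION_RULES,
    ProfileMatrix,
    SampleMeta,
    classify_label,
    default_blend_spec,
    evaluate_model,
    generate_blends,
    predict_purity,
    train_purity_model,
)
from citrusauth.authenticity import (
    AuthenticityError,
    BlendSet,
    classify_grapefruit_conservative,
)


def _profiles(n, species, values, prefix):
    metas = tuple(
        SampleMeta(sample_id=f"{prefix}{i}", species=species,
                   cultivar=f"{prefix}cv{i}", region="r", harvest_year=2020)
        for i in range(n)
    )
    return ProfileMatrix(metas=metas, columns=("15", "17", "26"),
                         values=np.asarray(values, dtype=float))


def _random_profiles(n, species, prefix, seed, base):
    rng = np.random.default_rng(seed)
    values = np.asarray(base) * rng.uniform(0.7, 1.3, size=(n, 3))
    return _profiles(n, species, values, prefix)


ORANGE_BASE = [0.02, 1.2, 0.02]
MANDARIN_BASE = [1.0, 0.08, 1.2]


class TestGenerateBlends:
    def test_external_test_set_count_is_475(self):
        main = _random_profiles(10, "orange", "o", 1, ORANGE_BASE)
        adu = _random_profiles(15, "mandarin", "m", 2, MANDARIN_BASE)
        spec = BlendSpec(main_species="orange", adulterant="mandarin",
                         purity_levels=(95.0, 90.0, 80.0),
                         include_pure_main=True, include_pure_adulterant=True)
        blends = generate_blends(main, adu, spec)
        # 10*15*3 blended rows + all 25 pure juices
        assert blends.matrix.n_samples == 475
        assert (blends.y == 100.0).sum() == 10
        assert (blends.y == 0.0).sum() == 15

    def test_per_level_counts_match_table(self):
        main = _random_profiles(17, "grapefruit", "g", 3, ORANGE_BASE)
        sg = _random_profiles(12, "pomelo", "p", 4, MANDARIN_BASE)
        wg = _random_profiles(25, "pomelo", "q", 5, MANDARIN_BASE)
        one_level = BlendSpec(main_species="grapefruit", adulterant="pomelo",
                              purity_levels=(90.0,), include_pure_main=False)
        assert generate_blends(main, sg, one_level).matrix.n_samples == 204
        assert generate_blends(main, wg, one_level).matrix.n_samples == 425

    def test_blend_row_is_exact_convex_combination(self):
        main = _profiles(1, "orange", [[1.0, 2.0, 3.0]], "o")
        adu = _profiles(1, "mandarin", [[5.0, 0.0, 1.0]], "m")
        spec = BlendSpec(main_species="orange", adulterant="mandarin",
                         purity_levels=(90.0,), include_pure_main=True,
                         include_pure_adulterant=True)
        blends = generate_blends(main, adu, spec)
        assert blends.matrix.n_samples == 3
        expected = 0.9 * np.array([1.0, 2.0, 3.0]) + 0.1 * np.array([5.0, 0.0, 1.0])
        assert np.allclose(blends.matrix.values[0], expected, atol=1e-15)

    def test_conservation_from_provenance(self):
        main = _random_profiles(4, "orange", "o", 6, ORANGE_BASE)
        adu = _random_profiles(3, "mandarin", "m", 7, MANDARIN_BASE)
        spec = default_blend_spec("orange_vs_mandarin")
        blends = generate_blends(main, adu, spec)
        main_rows = {m.sample_id: v for m, v in zip(main.metas, main.values)}
        adu_rows = {m.sample_id: v for m, v in zip(adu.metas, adu.values)}
        for row, (mid, aid, purity) in zip(blends.matrix.values,
                                           blends.provenance):
            frac = purity / 100.0
            expected = np.zeros(3)
            if mid is not None:
                expected += frac * main_rows[mid]
            if aid is not None:
                expected += (1 - frac) * adu_rows[aid]
            assert np.allclose(row, expected, atol=1e-12)

    def test_empty_profiles_error(self):
        main = _random_profiles(2, "orange", "o", 8, ORANGE_BASE)
        empty = _profiles(0, "mandarin", np.zeros((0, 3)), "m")
        with pytest.raises(AuthenticityError):
            generate_blends(main, empty, default_blend_spec("orange_vs_mandarin"))


class TestPurityModel:
    def test_noiseless_blends_are_recovered_exactly(self):
        # one profile per species, exact mixing: purity is exactly linear in
        # the marker block
        main = _profiles(1, "orange", [ORANGE_BASE], "o")
        adu = _profiles(1, "mandarin", [MANDARIN_BASE], "m")
        spec = BlendSpec(main_species="orange", adulterant="mandarin",
                         purity_levels=(95.0, 90.0, 80.0),
                         include_pure_main=True, include_pure_adulterant=True)
        blends = generate_blends(main, adu, spec)
        model = train_purity_model(blends, "orange_vs_mandarin")
        assert model.rmsecv_ < 1e-6
        assert model.r2_train_ == pytest.approx(1.0)
        predictions = model.predict(blends.matrix.values)
        assert np.allclose(predictions, blends.y, atol=1e-6)

    def test_pure_main_sample_predicts_100(self):
        main = _profiles(1, "orange", [ORANGE_BASE], "o")
        adu = _profiles(1, "mandarin", [MANDARIN_BASE], "m")
        blends = generate_blends(main, adu,
                                 default_blend_spec("orange_vs_mandarin"))
        model = train_purity_model(blends, "orange_vs_mandarin")
        pp = predict_purity(model, ORANGE_BASE)
        assert pp == pytest.approx(100.0, abs=1e-6)

    def test_predictions_are_not_clipped(self):
        main = _profiles(1, "orange", [ORANGE_BASE], "o")
        adu = _profiles(1, "mandarin", [MANDARIN_BASE], "m")
        blends = generate_blends(main, adu,
                                 default_blend_spec("orange_vs_mandarin"))
        model = train_purity_model(blends, "orange_vs_mandarin")
        # extrapolate far beyond the pure-adulterant end
        beyond = np.array(MANDARIN_BASE) * 2 - np.array(ORANGE_BASE)
        pp = predict_purity(model, beyond)
        assert pp < 0.0  # unclipped, negative purity is reportable

    def test_missing_variable_named_in_error(self):
        metas = tuple(
            SampleMeta(sample_id=f"x{i}", species="orange", cultivar=f"c{i}")
            for i in range(4)
        )
        matrix = ProfileMatrix(metas=metas, columns=("15", "17"),
                               values=np.ones((4, 2)))
        blends = BlendSet(matrix=matrix, y=np.array([100.0, 95, 90, 80]),
                          provenance=((None, None, 0.0),) * 4)
        with pytest.raises(AuthenticityError, match="26"):
            train_purity_model(blends, "orange_vs_mandarin")

    def test_foreign_variables_rejected(self):
        main = _profiles(1, "orange", [ORANGE_BASE], "o")
        adu = _profiles(1, "mandarin", [MANDARIN_BASE], "m")
        blends = generate_blends(main, adu,
                                 default_blend_spec("orange_vs_mandarin"))
        with pytest.raises(AuthenticityError):
            train_purity_model(blends, "orange_vs_mandarin",
                               variables=("15", "17", "36"))


class TestEvaluateModel:
    @pytest.fixture()
    def noiseless_model_and_blends(self):
        main = _profiles(1, "orange", [ORANGE_BASE], "o")
        adu = _profiles(1, "mandarin", [MANDARIN_BASE], "m")
        blends = generate_blends(main, adu,
                                 default_blend_spec("orange_vs_mandarin"))
        return train_purity_model(blends, "orange_vs_mandarin"), blends

    def test_perfect_predictions(self, noiseless_model_and_blends):
        model, blends = noiseless_model_and_blends
        result = evaluate_model(model, blends)
        assert result.rmsep == pytest.approx(0.0, abs=1e-6)
        assert result.r_squared == pytest.approx(1.0)
        assert set(result.pp_ranges) == {0.0, 80.0, 90.0, 95.0, 100.0}

    def test_constant_offset_shows_in_rmsep_not_r2(self,
                                                   noiseless_model_and_blends):
        model, blends = noiseless_model_and_blends
        shifted = BlendSet(matrix=blends.matrix, y=blends.y - 2.0,
                           provenance=blends.provenance)
        result = evaluate_model(model, shifted)
        assert result.rmsep == pytest.approx(2.0, abs=1e-6)
        assert result.r_squared == pytest.approx(1.0)

    def test_single_row_returns_rmsep_without_r2(self,
                                                 noiseless_model_and_blends):
        model, blends = noiseless_model_and_blends
        single = BlendSet(matrix=blends.matrix.subset(
            [i == 0 for i in range(blends.matrix.n_samples)]),
            y=blends.y[:1], provenance=blends.provenance[:1])
        result = evaluate_model(model, single)
        assert result.r_squared is None
        assert result.rmsep == pytest.approx(0.0, abs=1e-6)


class TestDecisionRules:
    @pytest.mark.parametrize(
        "scenario, pp, expected",
        [
            ("orange_vs_mandarin", 95.0, "authentic"),
            ("orange_vs_mandarin", 94.0, "authentic"),
            ("orange_vs_mandarin", 93.99, "indeterminate"),
            ("orange_vs_mandarin", 82.0, "indeterminate"),
            ("orange_vs_mandarin", 81.99, "fraudulent"),
            ("grapefruit_vs_SG", 94.0, "authentic"),
            ("grapefruit_vs_SG", 86.0, "indeterminate"),
            ("grapefruit_vs_SG", 84.0, "fraudulent"),
            ("grapefruit_vs_WG", 95.0, "authentic"),
            ("grapefruit_vs_WG", 94.99, "indeterminate"),
            ("grapefruit_vs_WG", 86.99, "fraudulent"),
        ],
    )
    def test_published_thresholds(self, scenario, pp, expected):
        assert classify_label(pp, DECISION_RULES[scenario]) == expected

    def test_monotone_in_pp(self):
        order = {"fraudulent": 0, "indeterminate": 1, "authentic": 2}
        rule = DECISION_RULES["orange_vs_mandarin"]
        grid = np.linspace(-40.0, 110.0, 301)
        labels = [order[classify_label(pp, rule)] for pp in grid]
        assert all(b >= a for a, b in zip(labels, labels[1:]))

    def test_conservative_grapefruit_verdict(self):
        assert classify_grapefruit_conservative(96.0, 96.0) == "authentic"
        assert classify_grapefruit_conservative(96.0, 94.0) == "indeterminate"
        assert classify_grapefruit_conservative(90.0, 86.0) == "fraudulent"
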