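"""Demographic model construction, rescaling and size lookup."""

import math

import pytest

from lethalpop.demography import (
    DEFAULT_RESCALE,
    DemographicModel,
    Epoch,
    MigrationPhase,
    base_tennessen_params,
    constant_size_model,
    load_model,
    rescaled_tennessen,
    save_model,
    size_at,
    variant_model,
)


@pytest.fixture(scope="module")
def default_model():
    return rescaled_tennessen()


@pytest.fixture(scope="module")
def base_model():
    return rescaled_tennessen(1.0)


class TestRescaledTennessen:
    def test_african_size_change_at_11643(self, default_model):
        assert default_model.history_length == 11_643

    def test_burnin_size_pinned_to_published_value(self, default_model):
        assert default_model.burnin_ne == 14_328
        assert default_model.burnin_generations == 10 * 14_328
        assert size_at(default_model, "ANC", 50_000) == 14_328

    def test_c1_reproduces_base_parameters(self, base_model):
        p = base_tennessen_params()
        assert base_model.history_length == p["T_african_growth"] == 5_920
        assert base_model.split_gen == p["T_split"] == 2_040
        assert base_model.burnin_ne == p["N_ancestral"] == 7_310
        assert size_at(base_model, "ANC", 3_000) == p["N_african"] == 14_474
        assert size_at(base_model, "EUR", 1_500) == p["N_bottleneck"] == 1_861
        assert base_model.migration_at(1_000) == p["m_ancestral_european"]
        assert base_model.migration_at(100) == p["m_african_european"]

    def test_sizes_and_times_scale_with_c(self, default_model, base_model):
        c = DEFAULT_RESCALE
        assert default_model.split_gen == round(base_model.split_gen * c)
        assert size_at(default_model, "AFR", 3_000) == round(14_474 * c)
        assert size_at(default_model, "EUR", 3_000) == round(1_861 * c)

    def test_rates_divided_by_c(self, default_model, base_model):
        c = DEFAULT_RESCALE
        assert default_model.migration_at(2_000) == pytest.approx(1.5e-4 / c)
        assert default_model.migration_at(10) == pytest.approx(2.5e-5 / c)

    def test_present_european_size_near_rescaled_512k(self, default_model):
        assert size_at(default_model, "EUR", 0) == pytest.approx(
            DEFAULT_RESCALE * 512_000, rel=0.05
        )

    def test_total_generations_is_burnin_plus_history(self, default_model):
        assert default_model.total_generations == 11_643 + 10 * 14_328

    def test_rescale_round_trip(self, default_model, base_model):
        back = default_model.rescaled(1.0 / DEFAULT_RESCALE)
        for e_back, e_base in zip(
            sorted(back.epochs, key=lambda e: (e.population, -e.start_gen)),
            sorted(base_model.epochs, key=lambda e: (e.population, -e.start_gen)),
        ):
            assert e_back.population == e_base.population
            assert e_back.start_gen == pytest.approx(e_base.start_gen, abs=1.0)
            # epoch times are rounded to whole generations at build, which
            # shifts re-solved boundary sizes of growing epochs by O(r)
            assert e_back.n_start == pytest.approx(e_base.n_start, rel=5e-3, abs=1.0)
            assert e_back.growth == pytest.approx(e_base.growth, rel=1e-9)

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            rescaled_tennessen(0.0)
        with pytest.raises(ValueError):
            rescaled_tennessen(-2.0)


class TestSizeAt:
    def test_constant_epoch_rounds_nominal_size(self):
        e = Epoch("EUR", 100.0, 0.0, 1032.4)
        assert all(e.size_at(t) == 1032 for t in (0, 50, 99))

    def test_exponential_epoch_start_size(self):
        e = Epoch("EUR", 100.0, 0.0, 1000.0, growth=0.01)
        assert e.size_at(100 - 1e-12) == 1000
        assert e.size_at(0) == round(1000 * math.exp(0.01 * 100))

    def test_out_of_span_raises(self, default_model):
        with pytest.raises(ValueError):
            size_at(default_model, "EUR", 11_643 + 10 * 14_328 + 5)

    def test_pre_split_daughters_fall_back_to_ancestral(self, default_model):
        assert size_at(default_model, "EUR", 5_000) == size_at(default_model, "ANC", 5_000)


class TestVariantModels:
    def test_multiplier_one_staged_is_identity(self, default_model):
        v = variant_model(default_model, 1.0, "staged")
        assert size_at(v, "EUR", 0) == pytest.approx(size_at(default_model, "EUR", 0), rel=1e-6)
        assert len(v.epochs) == len(default_model.epochs)

    def test_tenfold_staged_present_size(self, default_model):
        v = variant_model(default_model, 10.0, "staged")
        assert size_at(v, "EUR", 0) == pytest.approx(10 * size_at(default_model, "EUR", 0), rel=1e-6)
        # epoch boundaries preserved
        assert {e.start_gen for e in v.epochs} == {e.start_gen for e in default_model.epochs}

    def test_immediate_growth_single_epoch_from_bottleneck_exit(self, default_model):
        v = variant_model(default_model, 1.0, "immediate")
        eur = v.epochs_for("EUR")
        assert len(eur) == 2  # bottleneck + one exponential to the present
        assert eur[1].end_gen == 0
        assert eur[1].growth > 0
        assert size_at(v, "EUR", 0) == pytest.approx(size_at(default_model, "EUR", 0), rel=1e-6)

    def test_rejects_multiplier_below_one(self, default_model):
        with pytest.raises(ValueError):
            variant_model(default_model, 0.5)


class TestModelValidation:
    def test_epoch_gap_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            DemographicModel(
                epochs=(Epoch("ANC", 100.0, 50.0, 1000.0), Epoch("ANC", 40.0, 0.0, 1000.0)),
                split_gen=None,
                burnin_ne=1000,
            )

    def test_migration_rate_bounds(self):
        with pytest.raises(ValueError):
            MigrationPhase(100.0, 0.0, 0.7)

    def test_reversed_epoch_rejected(self):
        with pytest.raises(ValueError):
            Epoch("ANC", 0.0, 100.0, 1000.0)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, default_model):
        path = tmp_path / "model.json"
        save_model(default_model, path)
        loaded = load_model(path)
        assert loaded == default_model

    def test_constant_model_round_trip(self, tmp_path):
        m = constant_size_model(500, 25)
        path = tmp_path / "const.json"
        save_model(m, path)
        assert load_model(path) == m
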