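import numpy as np
import pandas as pd
import pytest

from beechroma.choice import (
    ChoiceDataset, CategoryLogitFit, filter_primary, fit_model,
    log_odds_table, lrt_species, predicted_proportions, read_choices,
    write_choices,
)
from beechroma.simulate import SimulationDesign, simulate_choices


def dataset_from_counts(counts_by_species, parameter="purity",
                        trained_level="high", n_bees=20):
    """Build a long-form dataset whose per-species level counts are given,
    spreading choices over ``n_bees`` bees (5 choices each where possible)."""
    rows = []
    for sp, counts in counts_by_species.items():
        total = int(sum(counts))
        seq = np.repeat(np.arange(1, 5), counts)
        for i, lev in enumerate(seq):
            rows.append(dict(
                bee_id=f"{sp}_{i % n_bees:03d}", species=sp,
                parameter=parameter, trained_level=trained_level,
                training_round=1, choice_rank=i // n_bees + 1,
                chosen_level=int(lev)))
        assert total == len(seq)
    return ChoiceDataset(pd.DataFrame(rows))


class TestFilterPrimary:
    def test_keeps_first_round_and_first_five(self):
        rows = []
        for rnd in (1, 2):
            for rank in range(1, 8):
                rows.append(dict(bee_id="b1", species="apis",
                                 parameter="purity", trained_level="high",
                                 training_round=rnd, choice_rank=rank,
                                 chosen_level=1))
        out = filter_primary(ChoiceDataset(pd.DataFrame(rows)))
        assert len(out) == 5
        assert set(out.records["training_round"]) == {1}
        assert out.records["choice_rank"].max() == 5

    def test_study_design_yields_100_records_per_species(self):
        design = SimulationDesign(
            species_probs={"apis": [0.25] * 4, "tetragonula": [0.25] * 4},
            sigma_individual=0.5, seed=1)
        data = filter_primary(simulate_choices(design))
        per_species = data.records.groupby("species").size()
        assert (per_species == 100).all()  # 20 bees x 5 choices


class TestClosedFormOracle:
    """With sigma fixed at 0 the model is a plain multinomial logit whose
    MLE has the closed form log(n_k / n_1) per species."""

    def test_uniform_counts_give_zero_coefficients(self):
        data = dataset_from_counts({"apis": [25, 25, 25, 25]})
        fit = fit_model(data, species_effect=False, sigma=0.0)
        np.testing.assert_allclose(fit.beta0, 0.0, atol=1e-6)

    def test_double_count_gives_log_two(self):
        data = dataset_from_counts({"apis": [20, 20, 20, 40]})
        fit = fit_model(data, species_effect=False, sigma=0.0)
        assert fit.beta0[2] == pytest.approx(np.log(2.0), abs=1e-6)

    def test_twenty_random_count_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            counts = {sp: rng.integers(5, 60, size=4)
                      for sp in ("apis", "tetragonula")}
            data = dataset_from_counts(counts)
            fit = fit_model(data, species_effect=True, sigma=0.0)
            lo_a = np.log(counts["apis"][1:] / counts["apis"][0])
            lo_t = np.log(counts["tetragonula"][1:] / counts["tetragonula"][0])
            np.testing.assert_allclose(fit.beta0, lo_a, atol=1e-6)
            np.testing.assert_allclose(fit.beta0 + fit.beta1, lo_t, atol=1e-6)

    def test_predicted_proportions_equal_empirical_frequencies(self):
        rng = np.random.default_rng(12)
        counts = {sp: rng.integers(5, 60, size=4)
                  for sp in ("apis", "tetragonula")}
        data = dataset_from_counts(counts)
        fit = fit_model(data, species_effect=True, sigma=0.0)
        props = predicted_proportions(fit)
        for sp in counts:
            emp = counts[sp] / counts[sp].sum()
            np.testing.assert_allclose(props.loc[sp].to_numpy(), emp, atol=1e-6)
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)


class TestFitBehaviour:
    def test_deterministic_and_invariant_to_bee_relabelling(self):
        design = SimulationDesign(
            species_probs={"apis": [0.1, 0.2, 0.3, 0.4],
                           "tetragonula": [0.25] * 4},
            sigma_individual=0.4, seed=5)
        data = simulate_choices(design)
        fit1 = fit_model(data, species_effect=True)
        fit2 = fit_model(data, species_effect=True)
        np.testing.assert_array_equal(fit1.beta0, fit2.beta0)
        assert fit1.loglik == fit2.loglik
        relabel = data.records.copy()
        relabel["bee_id"] = relabel["bee_id"].map(
            lambda s: "zz_" + s[::-1])
        fit3 = fit_model(ChoiceDataset(relabel), species_effect=True)
        assert fit3.loglik == pytest.approx(fit1.loglik, abs=1e-8)
        np.testing.assert_allclose(fit3.beta0, fit1.beta0, atol=1e-6)

    def test_separation_warning_attached(self):
        data = dataset_from_counts({"apis": [20, 20, 20, 40],
                                    "tetragonula": [10, 0, 20, 30]})
        fit = fit_model(data, species_effect=True, sigma=0.0)
        assert any("separation" in w for w in fit.warnings)

    def test_species_effect_requires_both_species(self):
        data = dataset_from_counts({"apis": [20, 20, 20, 40]})
        with pytest.raises(ValueError, match="both species"):
            fit_model(data, species_effect=True)

    def test_sigma_recovers_large_n_log_odds(self):
        # sigma=0 generator and fit: closed-form recovery ln2, ln3, ln4
        design = SimulationDesign(
            species_probs={"apis": [0.1, 0.2, 0.3, 0.4]},
            n_bees_per_group=400, choices_per_bee=5,
            sigma_individual=0.0, seed=21)
        data = simulate_choices(design)
        fit = fit_model(data, species_effect=False, sigma=0.0)
        np.testing.assert_allclose(fit.beta0, np.log([2.0, 3.0, 4.0]), atol=0.1)


class TestWaldTable:
    def _fit_with(self, beta0, beta1, cov):
        k = 3
        names = [f"beta0_{j}" for j in (2, 3, 4)] + \
            [f"beta1_{j}" for j in (2, 3, 4)]
        return CategoryLogitFit(
            beta0=np.asarray(beta0, float), beta1=np.asarray(beta1, float),
            sigma=0.0, sigma_fixed=True, covariance=np.asarray(cov, float),
            param_names=names, loglik=-1.0, n_individuals=40, n_choices=200,
            n_nodes=1, converged=True, species_levels=["apis", "tetragonula"])

    def test_unit_se_gives_plus_minus_196(self):
        cov = np.eye(6)
        fit = self._fit_with([0.0, 0.0, 0.0], [0.0, 0.0, 0.0], cov)
        row = log_odds_table(fit, pair_prefix="SP")[0]
        assert row.pair == "SP2/SP1"
        assert row.ci95 == pytest.approx((-1.96, 1.96))
        assert row.stars == ""

    def test_star_thresholds(self):
        # SEs chosen so the two-sided Wald p lands in each band
        z_for = {"": 1.0, "*": 2.2, "**": 2.9, "***": 4.0}
        for stars, z in z_for.items():
            cov = np.eye(6) / z ** 2
            fit = self._fit_with([1.0, 1.0, 1.0], [0.0, 0.0, 0.0], cov)
            assert log_odds_table(fit)[0].stars == stars

    def test_second_species_variance_combines_covariance(self):
        cov = np.eye(6) * 0.25
        cov[0, 3] = cov[3, 0] = -0.1
        fit = self._fit_with([1.0, 0.0, 0.0], [0.5, 0.0, 0.0], cov)
        rows = log_odds_table(fit)
        tet = [r for r in rows if r.species == "tetragonula"][0]
        assert tet.estimate == pytest.approx(1.5)
        assert tet.se == pytest.approx(np.sqrt(0.25 + 0.25 - 0.2))

    def test_nonconverged_fit_rejected(self):
        from dataclasses import replace
        fit = self._fit_with([0.0] * 3, [0.0] * 3, np.eye(6))
        bad = replace(fit, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            log_odds_table(bad)


class TestLRT:
    def test_identical_logliks_give_chi2_zero(self):
        data = dataset_from_counts({"apis": [25, 25, 25, 25],
                                    "tetragonula": [25, 25, 25, 25]})
        full = fit_model(data, species_effect=True, sigma=0.0)
        reduced = fit_model(data, species_effect=False, sigma=0.0)
        res = lrt_species(full, reduced)
        assert res.df == 3
        assert res.chi2 == pytest.approx(0.0, abs=1e-4)
        assert res.p == pytest.approx(1.0, abs=1e-4)

    def test_full_must_contain_species_terms(self):
        data = dataset_from_counts({"apis": [25, 25, 25, 25],
                                    "tetragonula": [25, 25, 25, 25]})
        reduced = fit_model(data, species_effect=False, sigma=0.0)
        with pytest.raises(ValueError, match="species"):
            lrt_species(reduced, reduced)


class TestIO:
    def test_round_trip(self, tmp_path):
        design = SimulationDesign(
            species_probs={"apis": [0.25] * 4, "tetragonula": [0.25] * 4},
            n_bees_per_group=3, seed=2)
        data = simulate_choices(design)
        path = tmp_path / "choices.csv"
        write_choices(data, path)
        back = read_choices(path)
        pd.testing.assert_frame_equal(back.records, data.records)

    def test_bad_level_rejected(self):
        df = pd.DataFrame([dict(bee_id="b", species="apis", parameter="purity",
                                trained_level="high", training_round=1,
                                choice_rank=1, chosen_level=5)])
        with pytest.raises(ValueError, match="chosen_level"):
            ChoiceDataset(df)
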