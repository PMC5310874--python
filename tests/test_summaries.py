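import numpy as np
import pandas as pd
import pytest

from gapc.data_model import MortalityDataset, StudyDimensions
from gapc.errors import StructureError
from gapc.inference import PosteriorResult
from gapc.structure import ModelSpec, cohort_index_grid
from gapc.summaries import (
    age_profiles_by,
    average_rate_profile,
    cohort_ratio_map,
    median_rate_grid,
    region_effect_map,
    spacetime_surface,
    summary_bundle,
)


def _toy_result(dims, rng, spread=0.0, phi=None, delta=None, beta=-9.0):
    """Hand-assembled posterior with controllable draws."""
    # odd pooled draw count so the sample median is order-statistic exact
    C, S = 3, 41
    def draws(*shape, center=0.0):
        return center + spread * rng.standard_normal((C, S) + shape)

    samples = {
        "beta": draws(dims.G, center=beta),
        "alpha": draws(dims.G, dims.T),
        "gamma": draws(dims.G, dims.I),
        "kappa": draws(dims.G, dims.K),
        "phi": draws(dims.A) if phi is None else np.broadcast_to(
            phi, (C, S, dims.A)).copy(),
        "delta": draws(dims.A, dims.T) if delta is None else np.broadcast_to(
            delta, (C, S, dims.A, dims.T)).copy(),
    }
    spec = ModelSpec(dims=dims, interaction_type="I")
    return PosteriorResult(samples=samples, spec=spec, seed=0, chains=C,
                           iterations=2 * S, warmup=S)


@pytest.fixture
def toy(rng):
    dims = StudyDimensions(G=2, A=3, I=3, T=4)
    ds = MortalityDataset(
        dims=dims,
        deaths=np.ones(dims.shape, int),
        population=rng.uniform(1e4, 5e4, size=dims.shape),
    )
    return dims, ds


class TestRegionEffects:
    def test_zero_field_gives_unit_effect_and_zero_probability(self, toy, rng):
        dims, _ = toy
        res = _toy_result(dims, rng, phi=np.zeros(dims.A))
        tab = region_effect_map(res)
        np.testing.assert_allclose(tab["effect"], 1.0)
        np.testing.assert_allclose(tab["prob_above_1"], 0.0)

    def test_median_commutes_with_exp(self, toy, rng):
        dims, _ = toy
        res = _toy_result(dims, rng, spread=0.3)
        tab = region_effect_map(res)
        phi = res.pooled("phi")
        np.testing.assert_allclose(tab["effect"], np.exp(np.median(phi, axis=0)))

    def test_symmetric_draws_give_half_probability(self, toy, rng):
        dims, _ = toy
        res = _toy_result(dims, rng, spread=0.5)
        phi = res.pooled("phi")
        phi -= phi.mean(axis=0, keepdims=True)
        sym = np.concatenate([phi, -phi], axis=0)
        res.samples["phi"] = sym.reshape(2, -1, dims.A)
        tab = region_effect_map(res)
        assert np.abs(tab["prob_above_1"] - 0.5).max() < 1e-12


class TestSpacetimeSurface:
    def test_zero_interaction_reduces_to_region_effects(self, toy, rng):
        dims, _ = toy
        res = _toy_result(dims, rng, spread=0.2, delta=np.zeros((dims.A, dims.T)))
        surf = spacetime_surface(res).pivot(index="area", columns="year", values="effect")
        reg = region_effect_map(res).set_index("area")["effect"]
        for year in surf.columns:
            np.testing.assert_allclose(surf[year], reg.loc[surf.index], atol=1e-12)

    def test_constant_shift_multiplies_surface(self, toy, rng):
        dims, _ = toy
        res = _toy_result(dims, rng, spread=0.2)
        s0 = spacetime_surface(res)["effect"].to_numpy()
        res.samples["delta"] = res.samples["delta"] + 0.7
        s1 = spacetime_surface(res)["effect"].to_numpy()
        np.testing.assert_allclose(s1, s0 * np.exp(0.7), rtol=1e-12)

    def test_matches_per_cell_median_oracle(self, toy, rng):
        dims, _ = toy
        res = _toy_result(dims, rng, spread=0.4)
        surf = spacetime_surface(res)
        phi, delta = res.pooled("phi"), res.pooled("delta")
        for _, row in surf.iloc[:5].iterrows():
            a = int(row["area"]) - 1
            t = int(row["year"]) - 1
            oracle = np.median(np.exp(phi[:, a] + delta[:, a, t]))
            assert row["effect"] == pytest.approx(oracle)


class TestRateProfiles:
    def test_weighted_mean_matches_hand_computation(self, rng):
        dims = StudyDimensions(G=1, A=2, I=2, T=1)
        pop = np.array([[[[1e4], [3e4]], [[2e4], [4e4]]]])
        ds = MortalityDataset(dims=dims, deaths=np.ones(dims.shape, int), population=pop)
        res = _toy_result(dims, rng, spread=0.1)
        rates = median_rate_grid(res, ds)
        prof = average_rate_profile(res, ds, "age", 0)
        for i in range(2):
            w = pop[0, :, i, 0]
            hand = np.average(rates[0, :, i, 0], weights=w) * 1e5
            assert prof["rate"].iloc[i] == pytest.approx(hand)

    def test_single_area_single_period_profile_is_cell_rates(self, rng):
        dims = StudyDimensions(G=1, A=1, I=4, T=1)
        ds = MortalityDataset(dims=dims, deaths=np.ones(dims.shape, int),
                              population=np.full(dims.shape, 1e4))
        res = _toy_result(dims, rng, spread=0.2)
        rates = median_rate_grid(res, ds)
        prof = average_rate_profile(res, ds, "age", 0)
        np.testing.assert_allclose(prof["rate"], rates[0, 0, :, 0] * 1e5)

    def test_cohort_axis_groups_via_index_map(self, toy, rng):
        dims, ds = toy
        res = _toy_result(dims, rng, spread=0.1)
        prof = average_rate_profile(res, ds, "cohort", 1)
        kgrid = cohort_index_grid(dims)
        assert set(prof["cohort"]) == {int(k) + 1 for k in np.unique(kgrid)}


class TestCohortRatios:
    def test_single_area_ratios_are_one(self, rng):
        dims = StudyDimensions(G=1, A=1, I=3, T=4)
        ds = MortalityDataset(dims=dims, deaths=np.ones(dims.shape, int),
                              population=np.full(dims.shape, 1e4))
        res = _toy_result(dims, rng, spread=0.2)
        tab = cohort_ratio_map(res, ds, 0)
        np.testing.assert_allclose(tab["ratio"], 1.0, atol=1e-12)

    def test_area_with_doubled_rates_has_ratio_near_two(self, toy, rng):
        dims, _ = toy
        # equal populations so the national profile is a plain mean over areas
        ds = MortalityDataset(
            dims=dims, deaths=np.ones(dims.shape, int),
            population=np.full(dims.shape, 1e4),
        )
        phi = np.array([np.log(2.0), 0.0, 0.0])
        res = _toy_result(dims, rng, phi=phi, delta=np.zeros((dims.A, dims.T)))
        tab = cohort_ratio_map(res, ds, 0)
        r0 = tab[tab.area == ds.areas[0]]["ratio"]
        national_mean = (2.0 + 1.0 + 1.0) / 3.0
        np.testing.assert_allclose(r0, 2.0 / national_mean, rtol=1e-10)


class TestAgeProfiles:
    def test_cohort_support_is_T_consecutive_indices(self, toy, rng):
        dims, ds = toy
        res = _toy_result(dims, rng, spread=0.1)
        prof = age_profiles_by(res, ds, "cohort", 0)
        for i, age in enumerate(ds.age_groups):
            ks = sorted(prof[prof.age_group == age]["cohort"])
            assert len(ks) == dims.T
            assert ks == list(range(ks[0], ks[0] + dims.T))
            if i == dims.I - 1:  # oldest group starts at cohort 1
                assert ks == list(range(1, dims.T + 1))

    def test_single_cell_trajectory_is_median_rate(self, rng):
        dims = StudyDimensions(G=1, A=1, I=2, T=1)
        ds = MortalityDataset(dims=dims, deaths=np.ones(dims.shape, int),
                              population=np.full(dims.shape, 1e4))
        res = _toy_result(dims, rng, spread=0.3)
        prof = age_profiles_by(res, ds, "period", 0)
        rates = median_rate_grid(res, ds)
        np.testing.assert_allclose(prof["rate"], rates[0, 0, :, 0] * 1e5)


class TestDeterminismAndErrors:
    def test_summaries_from_saved_bundle_are_bit_identical(self, tmp_path, tiny_fit):
        _, _, dataset, _, result = tiny_fit
        result.save(tmp_path / "bundle")
        reloaded = PosteriorResult.load(tmp_path / "bundle")
        b1 = summary_bundle(result, dataset)
        b2 = summary_bundle(reloaded, dataset)
        assert set(b1) == set(b2)
        for key in b1:
            pd.testing.assert_frame_equal(b1[key], b2[key])

    def test_missing_spatial_effect_is_structural_error(self, toy, rng):
        dims, _ = toy
        res = _toy_result(dims, rng)
        res.spec = ModelSpec(dims=dims, effects=("alpha",), interaction_type="none")
        with pytest.raises(StructureError):
            region_effect_map(res)
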