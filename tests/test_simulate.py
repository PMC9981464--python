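"""Synthetic-cohort generator: maps, mosaics, probabilities, covariates,
traits and mediation triplets against counting/variance oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import domqtl as dq
from domqtl.errors import ConfigError


class TestGeneticMap:
    def test_boundary_two_markers(self):
        gmap = dq.make_genetic_map(1, 2, 100, seed=0)
        pos = gmap.positions("1")
        assert len(pos) == 2
        assert np.all(pos > 0) and np.all(pos <= 100)

    def test_marker_count_and_monotonicity(self):
        gmap = dq.make_genetic_map(20, 100, 100, seed=7)
        assert gmap.n_markers == 2000
        for chrom in gmap.chromosomes:
            assert np.all(np.diff(gmap.positions(chrom)) > 0)

    def test_deterministic_given_seed(self):
        a = dq.make_genetic_map(3, 10, 100, seed=5)
        b = dq.make_genetic_map(3, 10, 100, seed=5)
        for chrom in a.chromosomes:
            np.testing.assert_array_equal(a.positions(chrom), b.positions(chrom))

    @pytest.mark.parametrize("bad", [(0, 5), (2, 1), (-1, 10)])
    def test_invalid_sizes_rejected(self, bad):
        with pytest.raises(ConfigError):
            dq.make_genetic_map(bad[0], bad[1], 100, seed=0)


class TestMosaics:
    def test_zero_generations_single_segment(self, small_map):
        mosaic = dq.simulate_do_mosaics(small_map, 10, 0, seed=1)
        for ind in range(10):
            for chrom in small_map.chromosomes:
                assert len(mosaic.segments[ind][chrom]) == 1

    def test_segments_tile_chromosome(self, small_map):
        mosaic = dq.simulate_do_mosaics(small_map, 20, 20, seed=2)
        for ind in range(20):
            for chrom in small_map.chromosomes:
                segs = mosaic.segments[ind][chrom]
                assert segs[0][0] == 0.0
                assert segs[-1][1] == small_map.lengths[chrom]
                for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
                    assert e0 == s1
                assert len({s[2] for s in segs}) >= 1
                for _, _, f in segs:
                    assert 0 <= f < 8

    def test_breakpoint_count_poisson_oracle(self):
        # 1 Morgan chromosome (200 Mbp at 0.5 cM/Mbp); rate 20 per Morgan
        gmap = dq.make_genetic_map(1, 2, 200, seed=0)
        mosaic = dq.simulate_do_mosaics(gmap, 1000, 20, seed=3)
        counts = [len(mosaic.segments[i]["1"]) - 1 for i in range(1000)]
        se = np.sqrt(20 / 1000)
        assert abs(np.mean(counts) - 20) < 3 * se

    def test_founder_occupancy_uniform(self, small_map):
        """At any single marker, founder ancestry across mice is multinomial
        with uniform 1/8 probabilities (draws independent across mice)."""
        from scipy import stats

        mosaic = dq.simulate_do_mosaics(small_map, 1000, 10, seed=4)
        probs = dq.mosaics_to_probs(mosaic, small_map, softness=0.0)
        counts = probs.arrays["3"][:, :, 25].sum(axis=0)  # (8,) one-hot counts
        n = counts.sum()
        frac = counts / n
        se = np.sqrt((1 / 8) * (7 / 8) / n)
        assert np.all(np.abs(frac - 1 / 8) < 3 * se)
        chi2 = np.sum((counts - n / 8) ** 2 / (n / 8))
        assert chi2 < stats.chi2.ppf(0.99, df=7)


class TestGenoProbs:
    def test_softness_zero_one_hot(self, small_map):
        mosaic = dq.simulate_do_mosaics(small_map, 5, 10, seed=5)
        probs = dq.mosaics_to_probs(mosaic, small_map, softness=0.0)
        for chrom in small_map.chromosomes:
            arr = probs.arrays[chrom]
            assert set(np.unique(arr)) <= {0.0, 1.0}

    def test_softness_arithmetic(self, small_map):
        mosaic = dq.simulate_do_mosaics(small_map, 3, 10, seed=6)
        probs = dq.mosaics_to_probs(mosaic, small_map, softness=0.07)
        arr = probs.arrays["1"]
        assert np.allclose(np.sort(np.unique(np.round(arr, 10))), [0.01, 0.93])

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(softness=st.floats(min_value=0.0, max_value=0.49), seed=st.integers(0, 100))
    def test_rows_sum_to_one(self, softness, seed):
        gmap = dq.make_genetic_map(2, 5, 50, seed=0)
        mosaic = dq.simulate_do_mosaics(gmap, 4, 15, seed=seed)
        probs = dq.mosaics_to_probs(mosaic, gmap, softness=softness)
        for chrom in gmap.chromosomes:
            sums = probs.arrays[chrom].sum(axis=1)
            assert np.abs(sums - 1.0).max() < 1e-12

    def test_invalid_softness(self, small_map):
        mosaic = dq.simulate_do_mosaics(small_map, 2, 5, seed=7)
        with pytest.raises(ConfigError):
            dq.mosaics_to_probs(mosaic, small_map, softness=0.5)


class TestCovariates:
    def test_columns_and_balance(self):
        tab = dq.simulate_covariates(100, 5, seed=0)
        assert list(tab.columns) == ["sex", "days_on_diet", "wave_2", "wave_3", "wave_4", "wave_5"]
        assert abs(tab["sex"].sum() - 50) <= 1

    def test_deterministic(self):
        a = dq.simulate_covariates(50, 3, seed=9)
        b = dq.simulate_covariates(50, 3, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateTraits:
    def test_degenerate_constant_trait_flagged(self, cohort):
        spec = dq.SimTraitSpec(name="flat", qtls=[], h2_polygenic=0.0, noise_sd=0.0, seed=0)
        traits, truth = dq.simulate_traits(cohort["probs"], cohort["map"], None, [spec])
        assert truth[0]["degenerate"]
        assert np.var(traits["flat"].to_numpy()) == 0

    def test_variance_budget_must_stay_below_one(self):
        with pytest.raises(ConfigError):
            dq.SimTraitSpec(
                name="bad",
                qtls=[dq.QTLSpec("1", 10.0, np.arange(8.0), 0.7)],
                h2_polygenic=0.3,
            )

    def test_realized_qtl_variance_fraction(self, cohort):
        """Mean realized QTL variance fraction matches the spec over replicates."""
        fracs = []
        for rep in range(100):
            spec = dq.SimTraitSpec(
                name="t",
                qtls=[dq.QTLSpec("2", 40.0, np.random.default_rng(rep).standard_normal(8), 0.5)],
                h2_polygenic=0.0,
                seed=1000 + rep,
            )
            traits, truth = dq.simulate_traits(cohort["probs"], cohort["map"], None, [spec])
            y = traits["t"].to_numpy()
            idx = truth[0]["qtls"][0]["marker_idx"]
            g = cohort["probs"].dosages_at("2", idx) @ np.array(truth[0]["qtls"][0]["beta"])
            # realized fraction via regression of y on the genetic value
            frac = np.var(g * np.polyfit(g, y, 1)[0]) / np.var(y)
            fracs.append(frac)
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_zero_inflation_fraction(self, cohort):
        spec = dq.SimTraitSpec(
            name="ab", qtls=[], h2_polygenic=0.0, noise_model="lognormal",
            zero_inflation=0.3, seed=77,
        )
        traits, _ = dq.simulate_traits(cohort["probs"], cohort["map"], None, [spec])
        frac = (traits["ab"] == 0).mean()
        se = np.sqrt(0.3 * 0.7 / 200)
        assert abs(frac - 0.3) < 3 * se

    def test_polygenic_heritability_unbiased(self, cohort):
        """Realized h2 across replicates is an unbiased estimate of spec h2."""
        probs, gmap = cohort["probs"], cohort["map"]
        K = cohort["kin"].overall
        h2s = []
        for rep in range(100):
            spec = dq.SimTraitSpec(name="h", qtls=[], h2_polygenic=0.5, seed=2000 + rep)
            traits, _ = dq.simulate_traits(probs, gmap, None, [spec], kinship=K)
            nf = dq.fit_null(traits["h"].to_numpy(), np.ones((200, 1)),
                             cohort["kin"].eigen_for(None, "overall"))
            h2s.append(nf.h2)
        assert abs(np.mean(h2s) - 0.5) < 0.03

    def test_bit_reproducible(self, cohort):
        spec = dq.SimTraitSpec(
            name="t", qtls=[dq.QTLSpec("1", 10.0, np.arange(8.0), 0.2)],
            h2_polygenic=0.2, seed=5,
        )
        a, _ = dq.simulate_traits(cohort["probs"], cohort["map"], None, [spec],
                                  kinship=cohort["kin"].overall)
        b, _ = dq.simulate_traits(cohort["probs"], cohort["map"], None, [spec],
                                  kinship=cohort["kin"].overall)
        pd.testing.assert_frame_equal(a, b)


class TestMediationTriplet:
    def _spec(self, mode, alpha, sd=0.3, seed=50):
        return dq.MediationSpec(
            chrom="2", pos_mbp=40.0,
            microbe=dq.SimTraitSpec(
                name="M",
                qtls=[dq.QTLSpec("2", 40.0, np.random.default_rng(seed).standard_normal(8), 0.35)],
                seed=seed,
            ),
            alpha=alpha, lipid_residual_sd=sd, mode=mode, seed=seed,
        )

    def test_independent_mode_lipid_unrelated_to_m(self, cohort):
        m, l, truth = dq.simulate_mediation_triplet(
            cohort["probs"], cohort["map"], self._spec("independent", 0.0)
        )
        idx = truth["locus"]["marker_idx"]
        Z = cohort["probs"].dosages_at("2", idx)
        resid = l.to_numpy() - Z @ np.linalg.lstsq(Z, l.to_numpy(), rcond=None)[0]
        r = np.corrcoef(m, resid)[0, 1]
        assert abs(r) < 0.2

    def test_mediated_zero_residual_affine(self, cohort):
        m, l, _ = dq.simulate_mediation_triplet(
            cohort["probs"], cohort["map"], self._spec("mediated", 2.0, sd=0.0)
        )
        np.testing.assert_allclose(l.to_numpy(), 2.0 * m.to_numpy(), atol=1e-12)

    def test_mediated_regression_removes_marker_variance(self, cohort):
        """Conditioning on M removes >=90% of L's marker-explained variance."""
        m, l, truth = dq.simulate_mediation_triplet(
            cohort["probs"], cohort["map"], self._spec("mediated", 1.0, sd=0.3)
        )
        idx = truth["locus"]["marker_idx"]
        Z = cohort["probs"].dosages_at("2", idx)

        def marker_r2(y):
            X = np.column_stack([np.ones(len(y)), Z[:, :7]])
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            return 1 - (resid @ resid) / np.sum((y - y.mean()) ** 2)

        lv, mv = l.to_numpy(), m.to_numpy()
        r2_before = marker_r2(lv)
        resid_l = lv - np.polyval(np.polyfit(mv, lv, 1), mv)
        r2_after = marker_r2(resid_l)
        assert r2_after <= 0.1 * r2_before

    def test_mode_alpha_consistency_enforced(self):
        with pytest.raises(ConfigError):
            self._spec("independent", 1.0)
        with pytest.raises(ConfigError):
            self._spec("mediated", 0.0)
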