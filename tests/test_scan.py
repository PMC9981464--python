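"""Genome scans, peak calling, Bayesian support intervals, permutation
order statistics, BLUP effects and SNP association against closed-form
and simulation oracles."""

import numpy as np
import pandas as pd
import pytest

import domqtl as dq
from domqtl.errors import ConfigError
from domqtl.kinship import KinshipSet
from domqtl.scan import (
    ScanResult, SnpDef, bayes_interval, blup_effects, find_peaks,
    permutation_thresholds, scan_genome, scan_snps,
)


def _ols_lod(y, X0, X1):
    r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
    r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
    return len(y) / 2.0 * np.log10((r0 @ r0) / (r1 @ r1))


class TestScanEquivalence:
    def test_matches_per_marker_ols_without_kinship(self, cohort):
        """With no kinship (h2=0) every LOD equals the brute-force OLS
        likelihood-ratio LOD."""
        probs, covars = cohort["probs"], cohort["covars"]
        rng = np.random.default_rng(5)
        y = rng.standard_normal(200)
        res = scan_genome(y, covars, probs, None, kinship_mode="none", trait="t")
        Xc = covars.to_numpy(float)
        X0 = np.column_stack([np.ones(200), Xc])
        i = 0
        for chrom in probs.chromosomes:
            for j in range(probs.arrays[chrom].shape[2]):
                X1 = np.column_stack([Xc, probs.arrays[chrom][:, :, j]])
                expect = max(_ols_lod(y, X0, X1), 0.0)
                assert abs(res.table["lod"].iloc[i] - expect) < 1e-8
                i += 1

    def test_identity_kinship_equals_ols(self, cohort):
        probs, covars = cohort["probs"], cohort["covars"]
        n = 200
        kin = KinshipSet(overall=np.eye(n), loco={c: np.eye(n) for c in probs.chromosomes})
        y = np.random.default_rng(6).standard_normal(n)
        res_i = scan_genome(y, covars, probs, kin, kinship_mode="loco", trait="t")
        res_o = scan_genome(y, covars, probs, None, kinship_mode="none", trait="t")
        np.testing.assert_allclose(res_i.table["lod"], res_o.table["lod"], atol=1e-8)

    def test_duplicated_marker_same_lod(self, cohort):
        """A duplicated marker column yields identical LODs at both copies."""
        probs = cohort["probs"]
        arr = probs.arrays["1"].copy()
        arr[:, :, 10] = arr[:, :, 9]
        probs2 = dq.GenoProbs(
            individuals=probs.individuals,
            arrays={"1": arr, "2": probs.arrays["2"]},
            markers={"1": probs.markers["1"], "2": probs.markers["2"]},
        )
        y = np.random.default_rng(7).standard_normal(200)
        kin = dq.calc_kinship(probs2, mode="loco")
        res = scan_genome(y, cohort["covars"], probs2, kin, trait="t")
        lod = res.table[res.table["chrom"] == "1"]["lod"].to_numpy()
        assert abs(lod[9] - lod[10]) < 1e-10

    def test_null_trait_max_lod_moderate(self, cohort):
        """Pure-noise traits rarely reach large genome-wide maxima."""
        maxima = []
        for rep in range(20):
            y = np.random.default_rng(1000 + rep).standard_normal(200)
            res = scan_genome(y, cohort["covars"], cohort["probs"], cohort["kin"], trait="null")
            maxima.append(res.max_lod)
        assert np.median(maxima) < 6

    def test_orthogonalized_redundant_covariate_harmless(self, cohort):
        """Adding a shuffled copy of a covariate barely moves the LOD curve."""
        y = np.random.default_rng(8).standard_normal(200)
        covars = cohort["covars"]
        res1 = scan_genome(y, covars, cohort["probs"], cohort["kin"], trait="t")
        cov2 = covars.copy()
        cov2["sex_perm"] = np.random.default_rng(9).permutation(covars["sex"].to_numpy())
        res2 = scan_genome(y, cov2, cohort["probs"], cohort["kin"], trait="t")
        assert np.abs(res1.table["lod"] - res2.table["lod"]).max() < 0.5


class TestPeaksAndIntervals:
    def _flat_scan(self, lods, positions=None):
        m = len(lods)
        pos = positions if positions is not None else np.linspace(1, 100, m)
        return ScanResult(
            trait="t",
            table=pd.DataFrame(
                {"chrom": "1", "marker": [f"m{j}" for j in range(m)],
                 "pos_mbp": pos, "lod": lods}
            ),
        )

    def test_flat_zero_scan_no_peaks(self):
        assert find_peaks(self._flat_scan(np.zeros(50)), 6.0) == []

    def test_single_spike_single_peak(self):
        lods = np.zeros(100)
        lods[40] = 10.0
        peaks = find_peaks(self._flat_scan(lods), 6.0)
        assert len(peaks) == 1
        assert peaks[0].marker == "m40"
        # the spike holds ~all posterior mass: interval collapses onto it
        assert peaks[0].ci_lo == peaks[0].ci_hi == peaks[0].pos_mbp

    def test_one_peak_per_chromosome(self):
        tab = pd.DataFrame(
            {
                "chrom": ["1"] * 3 + ["2"] * 3,
                "marker": [f"m{j}" for j in range(6)],
                "pos_mbp": [10.0, 20.0, 30.0] * 2,
                "lod": [7, 1, 1, 1, 8, 1],
            }
        )
        peaks = find_peaks(ScanResult(trait="t", table=tab), 6.0)
        assert [(p.chrom, p.pos_mbp) for p in peaks] == [("1", 10.0), ("2", 20.0)]

    def test_tie_broken_to_lower_position(self):
        lods = np.zeros(10)
        lods[[3, 7]] = 9.0
        peaks = find_peaks(self._flat_scan(lods), 6.0)
        assert peaks[0].marker == "m3"

    def test_flat_posterior_spans_95_markers(self):
        lo, hi = bayes_interval(self._flat_scan(np.zeros(100), np.arange(1.0, 101.0)), "1")
        assert 94 <= hi - lo + 1 <= 97

    def test_full_coverage_spans_chromosome(self):
        scan = self._flat_scan(np.zeros(100), np.arange(1.0, 101.0))
        lo, hi = bayes_interval(scan, "1", coverage=1.0)
        assert (lo, hi) == (1.0, 100.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            find_peaks(self._flat_scan(np.zeros(5)), -1.0)


class TestPermutationThresholds:
    def test_order_statistic_definition(self, cohort, monkeypatch):
        """threshold(alpha) is the floor(alpha*n)+1-th largest max LOD."""
        import domqtl.scan as scan_mod

        fake_maxima = iter(np.arange(1000, dtype=float) / 100.0)

        def fake_scan_arrays(y, Xc, probs, kin, mode, cache, fixed_h2=None):
            v = next(fake_maxima)
            return {"1": np.array([v])}, {"1": 0.0}

        monkeypatch.setattr(scan_mod, "_scan_arrays", fake_scan_arrays)
        y = np.random.default_rng(0).standard_normal(200)
        thr = permutation_thresholds(
            y, cohort["covars"], cohort["probs"], None, n_perm=1000,
            alphas=(0.05, 0.2), kinship_mode="none",
        )
        order = np.sort(thr.max_lods)[::-1]
        assert thr.thresholds[0.05] == order[50]   # 51st largest
        assert thr.thresholds[0.2] == order[200]
        assert thr.thresholds[0.05] >= thr.thresholds[0.2]

    def test_constant_maxima_constant_threshold(self, cohort, monkeypatch):
        import domqtl.scan as scan_mod

        monkeypatch.setattr(
            scan_mod, "_scan_arrays",
            lambda *a, **k: ({"1": np.array([3.14])}, {"1": 0.0}),
        )
        y = np.random.default_rng(0).standard_normal(200)
        thr = permutation_thresholds(y, cohort["covars"], cohort["probs"], None,
                                     n_perm=100, alphas=(0.05, 0.2), kinship_mode="none")
        assert thr.thresholds[0.05] == thr.thresholds[0.2] == 3.14

    def test_insufficient_permutations_rejected(self, cohort):
        y = np.random.default_rng(0).standard_normal(200)
        with pytest.raises(ConfigError):
            permutation_thresholds(y, cohort["covars"], cohort["probs"], None,
                                   n_perm=50, kinship_mode="none")
        with pytest.raises(ConfigError):
            permutation_thresholds(y, cohort["covars"], cohort["probs"], None,
                                   n_perm=100, alphas=(0.005,), kinship_mode="none")


class TestBlup:
    def test_recovers_planted_effects(self, cohort, qtl_trait):
        y, truth = qtl_trait
        idx = truth["qtls"][0]["marker_idx"]
        eff = blup_effects(dq.rankz(y), cohort["covars"], cohort["probs"], "3", idx,
                           cohort["kin"])
        r = np.corrcoef(eff.effects, truth["qtls"][0]["beta"])[0, 1]
        assert r > 0.9
        assert not eff.shrunk_to_null

    def test_shrinks_relative_to_fixed_effects(self, cohort, qtl_trait):
        """BLUPs have no larger norm than the near-unshrunk (lambda -> inf)
        fixed-effect limit of the same system."""
        from domqtl.scan import _blup_solve
        from domqtl.lmm import fit_null

        y, truth = qtl_trait
        idx = truth["qtls"][0]["marker_idx"]
        eff = blup_effects(dq.rankz(y), cohort["covars"], cohort["probs"], "3", idx,
                           cohort["kin"])
        yv = dq.rankz(y)
        Xc = cohort["covars"].to_numpy(float)
        X0 = np.column_stack([np.ones(200), Xc])
        eig = cohort["kin"].eigen_for("3", "loco")
        nf = fit_null(yv, X0, eig)
        sw = 1 / np.sqrt(nf.weights)
        U = nf.eigenvectors
        yw, Xw = (U.T @ yv) * sw, (U.T @ X0) * sw[:, None]
        Zw = (U.T @ cohort["probs"].arrays["3"][:, :, idx]) * sw[:, None]
        u_fixed, _ = _blup_solve(1e8, yw, Xw, Zw)
        assert np.linalg.norm(eff.effects) <= np.linalg.norm(u_fixed) + 1e-6

    def test_null_trait_shrunk_to_zero(self, cohort):
        y = np.random.default_rng(12).standard_normal(200)
        eff = blup_effects(y, cohort["covars"], cohort["probs"], "1", 25, cohort["kin"])
        # with no signal the variance component collapses (or nearly so)
        assert eff.shrunk_to_null or np.linalg.norm(eff.effects) < 0.2


class TestSnpScan:
    def test_complementary_sdps_identical_lod(self, cohort, qtl_trait):
        y, _ = qtl_trait
        sdp = np.array([1, 0, 1, 0, 0, 1, 0, 0])
        snps = [
            SnpDef("s", "3", 50.0, sdp),
            SnpDef("s_comp", "3", 50.0, 1 - sdp),
        ]
        res = scan_snps(dq.rankz(y), cohort["covars"], cohort["probs"], snps, cohort["kin"])
        assert abs(res["lod"].iloc[0] - res["lod"].iloc[1]) < 1e-8

    def test_noninformative_sdp_skipped(self, cohort, qtl_trait):
        y, _ = qtl_trait
        with pytest.warns(UserWarning, match="non-informative"):
            res = scan_snps(dq.rankz(y), cohort["covars"], cohort["probs"],
                            [SnpDef("allzero", "3", 50.0, np.zeros(8))], cohort["kin"])
        assert res.empty

    def test_matches_ols_oracle_without_kinship(self, cohort):
        y = np.random.default_rng(13).standard_normal(200)
        sdp = np.array([1, 1, 0, 0, 1, 0, 0, 0])
        snp = SnpDef("s", "2", 33.0, sdp)
        res = scan_snps(y, cohort["covars"], cohort["probs"], [snp], None, kinship_mode="none")
        pos = cohort["probs"].markers["2"]["pos_mbp"].to_numpy()
        j = int(np.argmin(np.abs(pos - 33.0)))
        d = cohort["probs"].arrays["2"][:, :, j] @ sdp
        Xc = cohort["covars"].to_numpy(float)
        X0 = np.column_stack([np.ones(200), Xc])
        X1 = np.column_stack([X0, d])
        assert abs(res["lod"].iloc[0] - max(_ols_lod(y, X0, X1), 0)) < 1e-8

    def test_causal_founder_sdp_beats_mismatched(self, cohort):
        """The SDP isolating the causal founder out-scores a mismatched SDP
        (median over replicates)."""
        probs, gmap = cohort["probs"], cohort["map"]
        wins = 0
        reps = 20
        for rep in range(reps):
            beta = np.zeros(8)
            beta[3] = 1.0  # single causal founder (NOD)
            spec = dq.SimTraitSpec(
                name="t", qtls=[dq.QTLSpec("4", 60.0, beta, 0.25)], seed=3000 + rep
            )
            traits, truth = dq.simulate_traits(probs, gmap, None, [spec])
            idx = truth[0]["qtls"][0]["marker_idx"]
            pos = probs.markers["4"]["pos_mbp"].iloc[idx]
            match = SnpDef("match", "4", pos, (np.arange(8) == 3).astype(int))
            mismatch = SnpDef("mismatch", "4", pos, np.array([1, 1, 0, 0, 1, 0, 1, 0]))
            res = scan_snps(traits["t"], None, probs, [match, mismatch], cohort["kin"])
            if res.set_index("snp")["lod"]["match"] >= res.set_index("snp")["lod"]["mismatch"]:
                wins += 1
        assert wins >= reps * 0.7
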