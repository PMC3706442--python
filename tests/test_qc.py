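import numpy as np
import pytest
from scipy.stats import chi2

from conftest import make_panel
from triherit.datatypes import GRMatrix
from triherit.qc import (
    SampleQCThresholds,
    SnpQCThresholds,
    hwe_test,
    ld_prune,
    pca,
    sample_filter,
    snp_filter,
    tracy_widom_count,
)
from triherit.simulate import GenoSimConfig, simulate_genotypes


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        p, mono = hwe_test(25, 50, 25)
        assert p == pytest.approx(1.0) and not mono

    def test_hand_computed_pearson_statistic(self):
        # counts (50, 20, 30): p(alt) = 0.4 -> expected (36, 48, 16)
        # chi2 = 196/36 + 784/48 + 196/16 = 34.027...
        stat = 196 / 36 + 784 / 48 + 196 / 16
        expected_p = chi2.sf(stat, 1)
        p, _ = hwe_test(50, 20, 30)
        assert p == pytest.approx(expected_p, rel=1e-12)
        assert p == pytest.approx(5.4e-9, rel=0.02)

    def test_monomorphic_flagged(self):
        p, mono = hwe_test(0, 0, 100)
        assert p == 1.0 and mono

    def test_exact_variant_close_to_asymptotic_in_tail(self):
        p_chi, _ = hwe_test(200, 20, 80)
        p_ex, _ = hwe_test(200, 20, 80, exact=True)
        # deep-tail agreement in order of magnitude
        assert abs(np.log10(p_chi) - np.log10(p_ex)) < 2

    def test_exact_test_matches_enumeration_on_tiny_counts(self):
        """Exact p equals brute-force enumeration of the conditional
        distribution for a small table."""
        from math import comb

        n, n_rare = 10, 6
        def prob(h):
            hom_r = (n_rare - h) // 2
            hom_c = n - h - hom_r
            from math import factorial
            return (
                2**h
                * factorial(n)
                / (factorial(hom_r) * factorial(h) * factorial(hom_c))
                * factorial(n_rare)
                * factorial(2 * n - n_rare)
                / factorial(2 * n)
            )
        hets = range(n_rare % 2, n_rare + 1, 2)
        probs = {h: prob(h) for h in hets}
        obs_h = 2
        brute = sum(p for h, p in probs.items() if p <= probs[obs_h] * (1 + 1e-12))
        hom_rare = (n_rare - obs_h) // 2
        p_ex, _ = hwe_test(n - obs_h - hom_rare, obs_h, hom_rare, exact=True)
        assert p_ex == pytest.approx(brute, rel=1e-9)

    def test_calibration_under_hwe(self, hwe_panel):
        """Chi-square HWE test rejects at ~alpha on HWE genotypes."""
        ps = []
        for row in hwe_panel.dosages:
            x = row[~np.isnan(row)].astype(int)
            counts = [(x == g).sum() for g in (0, 1, 2)]
            ps.append(hwe_test(*counts)[0])
        rate = np.mean(np.array(ps) < 0.05)
        # binomial 99% interval around 0.05 at 2000 SNPs
        assert 0.05 - 2.58 * np.sqrt(0.05 * 0.95 / 2000) < rate < 0.05 + 2.58 * np.sqrt(
            0.05 * 0.95 / 2000
        )


class TestSnpFilter:
    def _engineered_panel(self):
        rng = np.random.default_rng(0)
        n = 200
        good = rng.binomial(2, 0.3, size=(5, n)).astype(float)
        low_maf = rng.binomial(2, 0.005, size=(1, n)).astype(float)
        missing = rng.binomial(2, 0.3, size=(1, n)).astype(float)
        missing[0, : int(0.05 * n)] = np.nan
        hwe_bad = np.concatenate([np.zeros(n // 2), np.full(n - n // 2, 2.0)])[None, :]
        dosages = np.vstack([good, low_maf, missing, hwe_bad])
        return make_panel(dosages)

    def test_engineered_failures_counted_once_each(self):
        report = snp_filter(self._engineered_panel(), plate_test=False)
        assert report.counts == {"maf": 1, "missing": 1, "hwe": 1}
        assert len(report.kept) == 5

    def test_info_boundary_strict(self):
        panel = make_panel(
            np.random.default_rng(1).binomial(2, 0.3, size=(3, 100)).astype(float),
            info=[0.97, 0.975, 1.0],
        )
        report = snp_filter(panel, plate_test=False)
        assert report.items.loc[0, "reason"] == "info"
        assert report.items.loc[1, "passed"]  # info == 0.975 passes (strict <)

    def test_maf_boundary_inclusive(self):
        # MAF exactly 0.01 passes the strict "< 1%" rule
        n = 100
        row = np.zeros(n)
        row[:2] = 1.0  # freq = 2/200 = 0.01
        panel = make_panel(row[None, :])
        report = snp_filter(panel, plate_test=False)
        assert report.items.loc[0, "passed"]

    def test_imputed_tier_rules(self):
        rng = np.random.default_rng(2)
        dosages = rng.binomial(2, 0.3, size=(4, 100)).astype(float)
        panel = make_panel(
            dosages,
            imputed=[True, True, True, False],
            stratum=["imputed-both", "imputed-both", "imputed-one", "genotyped"],
            info=[0.99, 0.95, 0.95, 1.0],
        )
        report = snp_filter(panel, plate_test=False)
        assert report.items.loc[0, "passed"]       # 0.99 >= 0.98
        assert report.items.loc[1, "reason"] == "info"  # 0.95 < 0.98
        assert report.items.loc[2, "passed"]       # 0.95 >= 0.90 second-array tier
        assert report.items.loc[3, "passed"]

    def test_plate_effect_detected(self):
        rng = np.random.default_rng(3)
        n = 200
        plates = np.array(["p1"] * (n // 2) + ["p2"] * (n // 2))
        clean = rng.binomial(2, 0.4, size=n).astype(float)
        batched = clean.copy()
        batched[n // 2 :] = rng.binomial(2, 0.05, size=n // 2)
        panel = make_panel(np.vstack([clean, batched]), plates=plates)
        report = snp_filter(panel)
        assert report.items.loc[0, "passed"]
        assert report.items.loc[1, "reason"] in ("plate", "hwe")

    def test_idempotent(self, hwe_panel):
        report = snp_filter(hwe_panel, plate_test=False)
        survivors = hwe_panel.subset_snps(
            hwe_panel.snps["snp"].isin(report.kept).to_numpy()
        )
        again = snp_filter(survivors, plate_test=False)
        assert len(again.kept) == len(report.kept)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            SnpQCThresholds(maf_min=1.5)


class TestSampleFilter:
    def _grm(self, n, pairs=(), call_rates=None):
        v = np.eye(n)
        for j, k, val in pairs:
            v[j, k] = v[k, j] = val
        return GRMatrix(values=v, nsnp=np.full((n, n), 100), ids=[f"i{j}" for j in range(n)],
                        call_rates=call_rates)

    def test_no_relatedness_no_removals(self):
        rng = np.random.default_rng(4)
        panel = make_panel(rng.binomial(2, 0.3, size=(50, 6)).astype(float))
        report = sample_filter(panel, grm=self._grm(6))
        assert report.counts.get("relatedness", 0) == 0

    def test_duplicate_drops_lower_call_rate_member(self):
        rng = np.random.default_rng(5)
        dosages = rng.binomial(2, 0.3, size=(50, 4)).astype(float)
        dosages[:10, 2] = np.nan  # sample i2 has the lowest call rate
        panel = make_panel(dosages)
        grm = self._grm(4, pairs=[(2, 3, 1.0)])
        report = sample_filter(
            panel, SampleQCThresholds(call_rate_min=0.5), grm=grm
        )
        failed = report.items[~report.items["passed"]]
        assert list(failed["item"]) == ["i2"]
        assert list(failed["reason"]) == ["relatedness"]

    def test_related_triangle_resolved_minimally(self):
        """For a 3-clique of related samples, removal must leave no
        offending pair; brute force shows 2 removals suffice and 1 does
        not, so the greedy loop must remove exactly 2."""
        rng = np.random.default_rng(6)
        panel = make_panel(rng.binomial(2, 0.3, size=(50, 5)).astype(float))
        grm = self._grm(5, pairs=[(0, 1, 0.5), (0, 2, 0.5), (1, 2, 0.5)])
        report = sample_filter(panel, grm=grm)
        removed = set(report.items.loc[~report.items["passed"], "item"])
        assert len(removed) == 2 and removed <= {"i0", "i1", "i2"}

    def test_heterozygosity_outlier_flagged(self):
        rng = np.random.default_rng(7)
        dosages = rng.binomial(2, 0.5, size=(400, 20)).astype(float)
        dosages[:, 0] = 1.0  # everything heterozygous
        panel = make_panel(dosages)
        report = sample_filter(panel)
        assert report.items.loc[0, "reason"] == "heterozygosity"


class TestLdPrune:
    def test_perfect_proxies_collapse_to_one(self):
        rng = np.random.default_rng(8)
        x = rng.binomial(2, 0.4, size=300).astype(float)
        panel = make_panel(np.vstack([x, x]))
        kept = ld_prune(panel)
        assert len(kept) == 1

    def test_independent_snps_mostly_kept(self):
        rng = np.random.default_rng(9)
        panel = make_panel(rng.binomial(2, 0.3, size=(200, 1000)).astype(float))
        kept = ld_prune(panel, r2_max=0.2)
        assert len(kept) > 0.99 * 200

    def test_postcondition_no_kept_pair_exceeds_threshold(self):
        rng = np.random.default_rng(10)
        base = rng.binomial(2, 0.4, size=(30, 400)).astype(float)
        # create correlated neighbours
        noisy = np.clip(base + rng.binomial(1, 0.1, size=base.shape), 0, 2)
        panel = make_panel(np.vstack([base, noisy])[np.argsort(np.tile(np.arange(30), 2))])
        kept = ld_prune(panel, r2_max=0.2, window=10)
        idx = [list(panel.snps["snp"]).index(s) for s in kept]
        for a in range(len(idx)):
            for b in range(a + 1, min(a + 11, len(idx))):
                r = np.corrcoef(panel.dosages[idx[a]], panel.dosages[idx[b]])[0, 1]
                assert r * r <= 0.2 + 1e-9

    def test_zero_variance_skipped_with_warning(self):
        rng = np.random.default_rng(11)
        dosages = np.vstack(
            [np.full(100, 2.0), rng.binomial(2, 0.4, 100).astype(float)]
        )
        with pytest.warns(UserWarning, match="zero variance"):
            kept = ld_prune(make_panel(dosages))
        assert len(kept) == 1


class TestPcaTracyWidom:
    def test_components_orthonormal(self, hwe_panel):
        pcs, _ = pca(hwe_panel, k=5)
        np.testing.assert_allclose(pcs.T @ pcs, np.eye(5), atol=1e-8)

    def test_pc1_separates_subpopulations(self):
        panel = simulate_genotypes(
            GenoSimConfig(n_individuals=300, n_snps=3000, n_subpops=2, fst=0.1, seed=12)
        )
        pcs, ev = pca(panel, k=2)
        side = pcs[:, 0] > 0
        acc = max(
            np.mean(side == (panel.subpop == 0)), np.mean(side == (panel.subpop == 1))
        )
        assert acc >= 0.95
        assert tracy_widom_count(ev, 300, 3000) >= 1

    def test_null_spectrum_rarely_significant(self):
        hits = 0
        reps = 20
        for s in range(reps):
            panel = simulate_genotypes(
                GenoSimConfig(n_individuals=120, n_snps=600, seed=300 + s)
            )
            _, ev = pca(panel, k=3)
            if tracy_widom_count(ev, 120, 600) > 0:
                hits += 1
        assert hits <= 0.1 * reps + 1  # >=90% of replicates give count 0

    def test_k_too_large_rejected(self, tiny_panel):
        with pytest.raises(ValueError):
            pca(tiny_panel, k=tiny_panel.n_samples)

    def test_empty_eigenvalues_give_zero(self):
        assert tracy_widom_count([], 100, 1000) == 0

    def test_unsupported_alpha_rejected(self):
        with pytest.raises(ValueError):
            tracy_widom_count([1.0], 10, 100, alpha=0.2)
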