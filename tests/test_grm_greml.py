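import itertools

import numpy as np
import pytest

from conftest import make_panel
from triherit.datatypes import GRMatrix
from triherit.grm import (
    GrmError,
    compute_grm,
    prune_unrelated,
    reml_h2,
    reml_profile_deviance,
    _project_eigen,
)
from triherit.simulate import (
    GenoSimConfig,
    PhenoSimConfig,
    simulate_genotypes,
    simulate_longitudinal_phenotypes,
)


@pytest.fixture(scope="module")
def recovery_setup():
    """Shared n=2000, m=5000 panel + GRM for the parameter-recovery tests."""
    panel = simulate_genotypes(GenoSimConfig(n_individuals=2000, n_snps=5000, seed=11))
    grm = compute_grm(panel)
    covs_of = lambda ph: np.column_stack(
        [ph["sex"].to_numpy(float), ph["cohort"].to_numpy(float)]
    )
    return panel, grm, covs_of


class TestGrmEstimator:
    def test_heterozygote_pair_contributes_zero(self):
        # one SNP at p = 0.5, both individuals heterozygous
        grm = compute_grm(make_panel([[1.0, 1.0, 0.0, 2.0]]))
        assert grm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_homozygotes_give_minus_two(self):
        grm = compute_grm(make_panel([[0.0, 2.0]]))
        assert grm.values[0, 1] == pytest.approx(-2.0, abs=1e-12)

    def test_adjusted_diagonal_heterozygote_is_zero(self):
        # x = 1 at p = 0.5: 1 + (1 - 2 + 0.5)/0.5 = 0
        grm = compute_grm(make_panel([[1.0, 1.0]]))
        assert grm.values[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_mean_diagonal_near_one_under_hwe(self):
        panel = simulate_genotypes(GenoSimConfig(n_individuals=500, n_snps=10_000, seed=13))
        grm = compute_grm(panel)
        assert 0.99 < np.diag(grm.values).mean() < 1.01

    def test_off_diagonals_center_near_zero_for_unrelateds(self, hwe_panel):
        """Sample-frequency centering makes GRM columns sum to ~0, so the
        off-diagonal mean is exactly about -1/(n-1); beyond that the
        off-diagonals are centered noise of SD ~ 1/sqrt(m)."""
        grm = compute_grm(hwe_panel)
        off = grm.off_diagonals()
        n = grm.n
        assert off.mean() == pytest.approx(-1.0 / (n - 1), abs=3e-4)
        assert off.std() == pytest.approx(1.0 / np.sqrt(hwe_panel.n_snps), rel=0.2)

    def test_pairwise_counts_respect_missingness(self):
        dos = np.array([[1.0, np.nan, 0.0], [2.0, 1.0, 0.0], [0.0, 1.0, np.nan]])
        grm = compute_grm(make_panel(dos))
        assert grm.nsnp[0, 1] == 2  # SNP rows 1,2 observed in both
        assert grm.nsnp[0, 2] == 2
        assert grm.nsnp[0, 0] == 3

    def test_monomorphic_only_panel_rejected(self):
        with pytest.raises(GrmError):
            compute_grm(make_panel([[2.0, 2.0, 2.0]]))


class TestPruneUnrelated:
    def _grm(self, n, pairs, call_rates=None):
        v = np.eye(n)
        for j, k, val in pairs:
            v[j, k] = v[k, j] = val
        return GRMatrix(
            values=v, nsnp=np.full((n, n), 10), ids=[f"i{j}" for j in range(n)],
            call_rates=call_rates,
        )

    def test_all_below_cutoff_kept(self):
        kept = prune_unrelated(self._grm(5, []), cutoff=0.025)
        assert len(kept) == 5

    def test_single_offending_pair_loses_one_member(self):
        kept = prune_unrelated(self._grm(6, [(1, 4, 0.5)]), cutoff=0.025)
        assert len(kept) == 5
        assert ("i1" in kept) != ("i4" in kept)

    def test_matches_minimal_removal_oracle_on_small_instances(self):
        """Greedy removal keeps at least as many samples as the brute-force
        minimum vertex cover on every random instance with <= 8 samples."""
        rng = np.random.default_rng(14)
        for trial in range(25):
            n = int(rng.integers(4, 9))
            pairs = []
            for j, k in itertools.combinations(range(n), 2):
                if rng.random() < 0.3:
                    pairs.append((j, k, 0.3))
            grm = self._grm(n, pairs)
            kept = prune_unrelated(grm, cutoff=0.025)
            # validity: no offending pair among kept
            idx = [grm.ids.index(i) for i in kept]
            for a, b in itertools.combinations(idx, 2):
                assert grm.values[a, b] <= 0.025
            # brute-force minimum removals
            edges = [(j, k) for j, k, _ in pairs]
            best = n
            for r in range(n + 1):
                if any(
                    all(j in rem or k in rem for j, k in edges)
                    for rem in itertools.combinations(range(n), r)
                ):
                    best = r
                    break
            assert n - len(kept) >= best  # oracle lower bound
            assert n - len(kept) <= best + 1  # greedy is near-minimal here


class TestReml:
    def test_recovers_h2_half(self, recovery_setup):
        panel, grm, covs_of = recovery_setup
        pheno = simulate_longitudinal_phenotypes(
            panel, PhenoSimConfig(n_causal=1000, h2_snp=0.5, seed=12)
        )
        fit = reml_h2(pheno["y7"].to_numpy(), covs_of(pheno), grm)
        assert fit.se is not None
        assert fit.h2_snp == pytest.approx(0.5, abs=2 * fit.se)

    def test_null_estimate_near_zero(self, recovery_setup):
        """Under h2 = 0 the bounded estimator piles up at the boundary;
        averaged over replicates the estimate stays within 2 SE of 0."""
        panel, grm, covs_of = recovery_setup
        ests, ses = [], []
        for s in (13, 23, 33):
            pheno = simulate_longitudinal_phenotypes(
                panel, PhenoSimConfig(n_causal=0, h2_snp=0.0, seed=s)
            )
            fit = reml_h2(pheno["y7"].to_numpy(), covs_of(pheno), grm)
            ests.append(fit.h2_snp)
            ses.append(fit.se if fit.se is not None else 0.05)
        assert np.mean(ests) <= 2 * np.mean(ses)

    def test_composite_heritability_matches_closed_form(self, recovery_setup):
        """Averaging 3 ages with residual correlation r rescales the
        heritability to h2 / (h2 + (1-h2)(1+2r)/3) = 0.60 for h2 = 0.5,
        r = 0.5."""
        from triherit.transforms import composite_mean

        panel, grm, covs_of = recovery_setup
        pheno = simulate_longitudinal_phenotypes(
            panel, PhenoSimConfig(n_causal=1000, h2_snp=0.5, seed=12)
        )
        y = np.asarray(
            composite_mean(pheno["y7"], pheno["y9"], pheno["y12"]), dtype=float
        )
        fit = reml_h2(y, covs_of(pheno), grm)
        expected = 0.5 / (0.5 + 0.5 * (1 + 2 * 0.5) / 3)
        assert fit.h2_snp == pytest.approx(expected, abs=2 * fit.se)

    def test_profile_matches_grid_oracle(self):
        """Optimizer's restricted deviance equals a brute-force 0.001-step
        grid scan within 1e-6 on an n=200 instance."""
        panel = simulate_genotypes(GenoSimConfig(n_individuals=200, n_snps=1000, seed=15))
        pheno = simulate_longitudinal_phenotypes(
            panel, PhenoSimConfig(n_causal=200, h2_snp=0.4, seed=16)
        )
        y = pheno["y7"].to_numpy()
        C = np.column_stack([pheno["sex"], pheno["cohort"]]).astype(float)
        grm = compute_grm(panel)
        fit = reml_h2(y, C, grm)

        X = np.column_stack([np.ones(200), C])
        d, z = _project_eigen(y, X, grm.values)
        grid = np.arange(0.0, 1.0001, 0.001)
        devs = np.array([reml_profile_deviance(h, d, z) for h in grid])
        assert reml_profile_deviance(fit.h2_snp, d, z) <= devs.min() + 1e-6

    def test_restricted_likelihood_matches_direct_formula(self):
        """Eigen-based profile deviance equals the textbook REML deviance
        log|V| + log|X'V^-1 X| + y'Py (up to the h2-free constant)."""
        panel = simulate_genotypes(GenoSimConfig(n_individuals=80, n_snps=500, seed=17))
        pheno = simulate_longitudinal_phenotypes(
            panel, PhenoSimConfig(n_causal=50, h2_snp=0.3, seed=18)
        )
        y = pheno["y7"].to_numpy()
        X = np.column_stack([np.ones(80), pheno["sex"].to_numpy(float)])
        A = compute_grm(panel).values
        d, z = _project_eigen(y, X, A)

        def direct(h2, s2):
            V = s2 * (h2 * A + (1 - h2) * np.eye(80))
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
            _, ld_v = np.linalg.slogdet(V)
            _, ld_x = np.linalg.slogdet(XtViX)
            return ld_v + ld_x + float(y @ P @ y)

        diffs = []
        for h2 in (0.2, 0.5, 0.8):
            v = h2 * d + (1 - h2)
            s2 = float(np.mean(z * z / v))
            prof = reml_profile_deviance(h2, d, z)
            # remove the shared s2-profile constant from both forms
            diffs.append(direct(h2, s2) - (prof - (80 - 2) * (1 + np.log(2 * np.pi))))
        # equal up to one h2-independent additive constant (log|X'X| terms)
        assert np.ptp(diffs) < 1e-6

    def test_invariance_to_location_and_scale(self):
        panel = simulate_genotypes(GenoSimConfig(n_individuals=300, n_snps=800, seed=19))
        pheno = simulate_longitudinal_phenotypes(
            panel, PhenoSimConfig(n_causal=100, h2_snp=0.4, seed=20)
        )
        y = pheno["y7"].to_numpy()
        C = np.column_stack([pheno["sex"]]).astype(float)
        grm = compute_grm(panel)
        base = reml_h2(y, C, grm).h2_snp
        shifted = reml_h2(5.0 + y, C, grm).h2_snp
        scaled = reml_h2(3.0 * y, C, grm).h2_snp
        assert shifted == pytest.approx(base, abs=1e-8)
        assert scaled == pytest.approx(base, abs=1e-8)

    def test_identity_grm_unidentifiable(self):
        rng = np.random.default_rng(21)
        grm = GRMatrix(values=np.eye(30), nsnp=np.full((30, 30), 10),
                       ids=[f"i{j}" for j in range(30)])
        with pytest.raises(GrmError, match="confounded"):
            reml_h2(rng.standard_normal(30), None, grm)

    def test_se_shrinks_with_sample_size(self):
        ses = {400: [], 1200: []}
        for n in ses:
            for rep in range(5):
                panel = simulate_genotypes(
                    GenoSimConfig(n_individuals=n, n_snps=2000, seed=700 + rep)
                )
                pheno = simulate_longitudinal_phenotypes(
                    panel, PhenoSimConfig(n_causal=400, h2_snp=0.4, seed=800 + rep)
                )
                fit = reml_h2(
                    pheno["y7"].to_numpy(),
                    np.column_stack([pheno["sex"]]).astype(float),
                    compute_grm(panel),
                )
                assert fit.se is not None
                ses[n].append(fit.se)
        assert np.median(ses[400]) > np.median(ses[1200])
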