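import numpy as np
import pytest

from sireimpute.containers import MISSING, GenotypeMatrix, make_snp_table
from sireimpute.hmm import (
    HaplotypePanel,
    LiStephensImputer,
    emission_table,
    estimated_allelic_r2,
    impute,
    most_likely_genotype,
    phase_reference,
    switch_error_count,
    switch_probabilities,
    _fb_posteriors,
)

from _oracles import dense_hmm_posteriors, enumerate_hmm_posteriors
from conftest import make_geno


def run_kernel(panel, obs, theta, error_rate):
    post, ll = _fb_posteriors(
        np.asarray(panel, dtype=np.uint8),
        np.asarray(obs, dtype=np.int8),
        np.asarray(theta, dtype=float),
        emission_table(error_rate),
    )
    return post, ll


def make_panel(haps, pos_morgan=None, animals=None):
    haps = np.asarray(haps, dtype=np.uint8)
    n2, M = haps.shape
    assert n2 % 2 == 0
    pos = np.arange(M) * 0.001 if pos_morgan is None else np.asarray(pos_morgan)
    animals = animals or [f"r{i}" for i in range(n2 // 2)]
    return HaplotypePanel(animals, haps.reshape(n2 // 2, 2, M), pos,
                          [f"s{j}" for j in range(M)])


class TestEmission:
    def test_rows_are_distributions(self):
        E = emission_table(0.01)
        np.testing.assert_allclose(E.sum(axis=1), 1.0, atol=1e-14)

    @pytest.mark.parametrize("eps", [0.0, 0.5, 0.7])
    def test_invalid_error_rate(self, eps):
        with pytest.raises(ValueError):
            emission_table(eps)


class TestForwardBackwardOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_matrix_oracle(self, seed):
        """Posteriors from the factorised kernel equal an explicit H^2 x H^2
        dense-transition forward-backward on random fixtures (H<=4, M<=6)."""
        rng = np.random.default_rng(seed)
        H = rng.integers(2, 5)
        M = rng.integers(3, 7)
        panel = rng.integers(0, 2, size=(H, M)).astype(np.uint8)
        obs = rng.integers(0, 3, size=M).astype(np.int8)
        obs[rng.integers(0, M)] = MISSING
        obs[rng.integers(0, M)] = MISSING
        theta = rng.uniform(0.0, 0.9, size=M - 1)
        post, _ = run_kernel(panel, obs, theta, 0.01)
        oracle = dense_hmm_posteriors(panel, obs, theta, 0.01)
        miss = obs < 0
        assert np.nanmax(np.abs(post[miss] - oracle[miss])) < 1e-10

    @pytest.mark.parametrize("H,M", [(2, 3), (3, 3)])
    def test_dense_oracle_matches_literal_path_enumeration(self, H, M):
        rng = np.random.default_rng(99)
        panel = rng.integers(0, 2, size=(H, M)).astype(np.uint8)
        obs = np.array([1, MISSING, 0][:M], dtype=np.int8)
        theta = rng.uniform(0.1, 0.5, size=M - 1)
        dense = dense_hmm_posteriors(panel, obs, theta, 0.05)
        enum = enumerate_hmm_posteriors(panel, obs, theta, 0.05)
        miss = obs < 0
        assert np.nanmax(np.abs(dense[miss] - enum[miss])) < 1e-12

    def test_posterior_triples_sum_to_one(self):
        rng = np.random.default_rng(5)
        panel = rng.integers(0, 2, size=(6, 20)).astype(np.uint8)
        obs = rng.integers(0, 3, size=20).astype(np.int8)
        obs[[3, 8, 15]] = MISSING
        theta = rng.uniform(0.0, 0.5, size=19)
        post, _ = run_kernel(panel, obs, theta, 0.001)
        miss = obs < 0
        np.testing.assert_allclose(post[miss].sum(axis=1), 1.0, atol=1e-9)

    def test_zero_morgan_panel_allowed(self):
        panel = np.array([[0, 1, 0], [1, 0, 1]], dtype=np.uint8)
        obs = np.array([0, MISSING, 0], dtype=np.int8)
        post, ll = run_kernel(panel, obs, np.zeros(2), 1e-4)
        assert np.isfinite(ll)
        # locked to copying h0 twice (allele 0 at both observed sites), so the
        # masked site is confidently h0[1] + h0[1] = 2
        assert post[1, 2] > 0.99


class TestCopyingLimits:
    def test_single_source_posterior_concentrates(self):
        # validation animal identical to the one panel animal, tight map
        haps = np.array([[0, 1, 0, 1, 0, 1], [1, 1, 0, 0, 0, 1]], dtype=np.uint8)
        panel = make_panel(haps, pos_morgan=np.arange(6) * 1e-5)
        geno_full = haps.sum(axis=0).astype(np.int8)
        calls = geno_full.copy()
        calls[[2, 4]] = MISSING
        geno = make_geno(calls[None, :], pos_cm=np.arange(6) * 1e-3)
        post = impute(geno, panel, error_rate=1e-6)
        for m in (2, 4):
            assert post.probs[0, m, geno_full[m]] > 0.999

    def test_no_ld_limit_equals_hardy_weinberg(self):
        # masked SNP a huge genetic distance from every observed SNP
        rng = np.random.default_rng(1)
        H, M = 6, 5
        haps = rng.integers(0, 2, size=(H, M)).astype(np.uint8)
        pos = np.array([0.0, 0.001, 0.002, 1000.0, 2000.0])
        panel = make_panel(haps, pos_morgan=pos, animals=["a", "b", "c"])
        calls = np.array([[haps[0, 0] + haps[1, 0],
                           haps[0, 1] + haps[1, 1],
                           haps[0, 2] + haps[1, 2], MISSING, 1]], dtype=np.int8)
        geno = make_geno(calls, pos_cm=pos * 100)
        post = impute(geno, panel, error_rate=1e-6)
        p = haps[:, 3].mean()
        hw = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        np.testing.assert_allclose(post.probs[0, 3], hw, atol=1e-6)

    def test_posterior_concentration_degrades_with_error_rate(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(8, 30)).astype(np.uint8)
        panel = make_panel(haps)
        calls = haps[0] + haps[1]
        calls = calls.astype(np.int8)
        calls[::4] = MISSING
        geno = make_geno(calls[None, :], pos_cm=np.arange(30) * 0.1)
        prev = np.inf
        for eps in (0.001, 0.01, 0.1, 0.3, 0.45):
            post = impute(geno, panel, error_rate=eps)
            conc = post.probs[0][calls == MISSING].max(axis=1).mean()
            assert conc <= prev + 1e-9
            prev = conc

    def test_loglik_finite_and_non_increasing_in_error_rate(self):
        # panel-consistent target: the animal formed by the two panel haplotypes
        haps = np.array([[0, 1, 1, 0, 1], [1, 1, 0, 0, 0]], dtype=np.uint8)
        panel = make_panel(haps)
        geno = make_geno((haps[0] + haps[1])[None, :].astype(np.int8),
                         pos_cm=np.arange(5) * 0.1)
        lls = []
        for eps in (1e-4, 1e-3, 1e-2, 0.1, 0.3):
            post = impute(geno, panel, error_rate=eps)
            assert np.all(np.isfinite(post.loglik))
            lls.append(post.loglik[0])
        assert all(b <= a + 1e-12 for a, b in zip(lls, lls[1:]))


class TestMostLikelyGenotype:
    def _post(self, probs, freq=0.3):
        probs = np.asarray(probs, dtype=float)[None, :, :]
        M = probs.shape[1]
        return type("P", (), {
            "probs": probs,
            "panel_freq": np.full(M, freq),
        })()

    def test_argmax(self):
        post = self._post([[0.1, 0.7, 0.2]])
        assert most_likely_genotype(post)[0, 0] == 1

    def test_tie_prefers_heterozygote(self):
        post = self._post([[0.4, 0.4, 0.2]])
        assert most_likely_genotype(post)[0, 0] == 1

    def test_hom_tie_goes_to_panel_major_allele(self):
        post = self._post([[0.5, 0.0, 0.5]], freq=0.3)  # a1 major -> genotype 0
        assert most_likely_genotype(post)[0, 0] == 0
        post = self._post([[0.5, 0.0, 0.5]], freq=0.8)  # a2 major -> genotype 2
        assert most_likely_genotype(post)[0, 0] == 2


class TestEstimatedAllelicR2:
    def _posterior(self, probs, imputed=None):
        probs = np.asarray(probs, dtype=float)
        n, M, _ = probs.shape
        from sireimpute.hmm import PosteriorGenotypes

        return PosteriorGenotypes(
            animals=[f"a{i}" for i in range(n)],
            snp_ids=[f"s{j}" for j in range(M)],
            probs=probs,
            imputed=np.ones((n, M), bool) if imputed is None else imputed,
            panel_freq=np.full(M, 0.4),
            loglik=np.zeros(n),
        )

    def test_degenerate_correct_posteriors_give_one(self):
        onehot = {0: [1, 0, 0], 1: [0, 1, 0], 2: [0, 0, 1]}
        genos = [0, 1, 2, 1, 0]
        probs = np.array([[onehot[g]] for g in genos], dtype=float)
        post = self._posterior(probs)
        assert estimated_allelic_r2(post, snp=0) == pytest.approx(1.0)

    def test_identical_posteriors_flagged_zero(self):
        probs = np.tile(np.array([0.2, 0.5, 0.3]), (4, 1, 1))
        post = self._posterior(probs)
        assert estimated_allelic_r2(post, snp=0) == 0.0

    def test_single_animal_undefined(self):
        probs = np.array([[[0.2, 0.5, 0.3]]])
        assert np.isnan(estimated_allelic_r2(self._posterior(probs), snp=0))

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(4)
        raw = rng.dirichlet(np.ones(3), size=(5, 1))
        post = self._posterior(raw)
        # independent scalar evaluation
        b = np.argmax(raw[:, 0, :], axis=1).astype(float)
        # apply the same tie rules as the implementation (no exact ties here)
        e = raw[:, 0, 1] + 2 * raw[:, 0, 2]
        s = raw[:, 0, 1] + 4 * raw[:, 0, 2]
        n = 5
        num = (np.sum(b * e) - np.sum(b) * np.sum(e) / n) ** 2
        den = (np.sum(b * b) - np.sum(b) ** 2 / n) * (np.sum(s) - np.sum(e) ** 2 / n)
        expected = min(max(num / den, 0.0), 1.0)
        assert estimated_allelic_r2(post, snp=0) == pytest.approx(expected, abs=1e-12)


class TestPhasing:
    def test_at_most_one_het_site_is_exact(self):
        calls = np.array([[0, 2, 1, 0], [0, 2, 0, 0], [2, 0, 0, 2],
                          [0, 2, 2, 0]], dtype=np.int8)
        geno = make_geno(calls, pos_cm=np.arange(4.0))
        panel = phase_reference(geno, n_iterations=5, random_state=0)
        for i in range(4):
            np.testing.assert_array_equal(
                panel.haplotypes[i].sum(axis=0), calls[i])

    def test_identical_homozygous_animals(self):
        calls = np.array([[0, 2, 0, 2], [0, 2, 0, 2]], dtype=np.int8)
        geno = make_geno(calls, pos_cm=np.arange(4.0))
        panel = phase_reference(geno, n_iterations=3, random_state=0)
        expected = np.array([0, 1, 0, 1], dtype=np.uint8)
        for i in range(2):
            for h in range(2):
                np.testing.assert_array_equal(panel.haplotypes[i, h], expected)

    def test_single_animal_reference_warns(self):
        geno = make_geno([[1, 1, 0]], pos_cm=np.arange(3.0))
        with pytest.warns(UserWarning, match="single-animal"):
            panel = phase_reference(geno, n_iterations=2, random_state=0)
        np.testing.assert_array_equal(panel.haplotypes[0].sum(axis=0), [1, 1, 0])

    def test_iteration_reduces_switch_errors(self):
        from sireimpute.simulate import SimulationConfig, simulate_study

        totals = {1: 0, 50: 0}
        for seed in (1, 2):
            cfg = SimulationConfig(
                n_snps=250, chrom_length_bp=10_000_000, chrom_length_morgan=0.3,
                n_founder_haplotypes=60,
                generation_sizes={"T1": 30, "T2": 30, "T3": 30, "T4": 30,
                                  "G0": 24, "G1": 5, "G2": 5},
                n_sires_per_generation=8, n_dams_per_generation=15,
                prop_missing=0.0, seed=seed,
            )
            truth, obs = simulate_study(cfg, validate=False)
            animals = truth.pedigree.in_generation("G0")[:24]
            geno = obs.subset(animals=animals)
            for n_iter in (1, 50):
                panel = phase_reference(geno, n_iterations=n_iter, random_state=7)
                totals[n_iter] += sum(
                    switch_error_count(panel.haplotypes[i],
                                       truth.haplotypes[a], geno.calls[i])
                    for i, a in enumerate(animals)
                )
        assert totals[50] < totals[1]

    def test_phased_pairs_sum_to_genotype(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.05] = MISSING
        geno = make_geno(calls, pos_cm=np.arange(40) * 0.2)
        panel = phase_reference(geno, n_iterations=3, random_state=1)
        sums = panel.haplotypes.sum(axis=1)
        obs = calls != MISSING
        np.testing.assert_array_equal(sums[obs], calls[obs])


class TestImputerEstimator:
    def test_sklearn_conventions(self):
        from sklearn.base import clone

        imp = LiStephensImputer(error_rate=0.01, ne_scale=30.0)
        params = imp.get_params()
        assert params["error_rate"] == 0.01 and params["ne_scale"] == 30.0
        clone(imp)
        with pytest.raises(ValueError, match="not fitted"):
            imp.predict_proba(make_geno([[0, 1]]))

    def test_fit_predict_round_trip(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        geno = make_geno(calls, pos_cm=np.arange(30) * 0.05)
        imp = LiStephensImputer(n_phasing_iterations=3).fit(geno)
        target = geno.subset(animals=geno.animals[:2])
        masked = target.copy()
        masked.calls[:, ::3] = MISSING
        out = imp.predict(masked)
        assert (out.calls != MISSING).all()
        # observed calls pass through untouched
        keep = masked.calls != MISSING
        np.testing.assert_array_equal(out.calls[keep], masked.calls[keep])

    def test_snp_map_mismatch_rejected(self):
        geno = make_geno([[0, 1], [1, 2]], pos_cm=[0.0, 1.0])
        imp = LiStephensImputer(n_phasing_iterations=1).fit(geno)
        other = make_geno([[0, 1]], snp_ids=["x0", "x1"], pos_cm=[0.0, 1.0])
        with pytest.raises(ValueError, match="SNP map"):
            imp.predict_proba(other)

    def test_switch_probability_formula(self):
        theta = switch_probabilities([0.0, 0.01, 0.01], ne_scale=52.0,
                                     n_haplotypes=10)
        np.testing.assert_allclose(
            theta, [1 - np.exp(-4 * 52 * 0.01 / 10), 0.0])
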