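import warnings

import numpy as np
import pytest

from sireimpute.containers import MISSING
from sireimpute.grm import (
    GRM,
    GreedyDiversitySelector,
    compute_grm,
    diversity_proportion,
    select_reference,
    stratify_by_ancestor,
    top_k_relationship,
)

from conftest import make_geno, make_pedigree


def scalar_loop_grm(calls, p):
    """Element-by-element VanRaden method 1, no vectorisation."""
    n, m = calls.shape
    denom = 2 * sum(pj * (1 - pj) for pj in p)
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            acc = 0.0
            for j in range(m):
                zi = 0.0 if calls[i, j] == MISSING else calls[i, j] - 2 * p[j]
                zk = 0.0 if calls[k, j] == MISSING else calls[k, j] - 2 * p[j]
                acc += zi * zk
            G[i, k] = acc / denom
    return G


class TestComputeGRM:
    def test_all_heterozygous_centers_to_zero(self):
        geno = make_geno([[1, 1], [1, 1], [1, 1]])
        G = compute_grm(geno)
        np.testing.assert_allclose(G.values, 0.0, atol=1e-12)

    def test_matches_scalar_loop_oracle(self):
        calls = np.array([[0, 1, 2, 1], [2, 1, 0, 0], [1, MISSING, 2, 1]],
                         dtype=np.int8)
        geno = make_geno(calls)
        G = compute_grm(geno)
        p = []
        for j in range(4):
            col = calls[:, j]
            obs = col[col != MISSING]
            p.append(obs.sum() / (2 * len(obs)))
        np.testing.assert_allclose(G.values, scalar_loop_grm(calls, p), atol=1e-12)

    def test_duplicated_animal_rows(self):
        calls = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0], [1, 0, 1]],
                         dtype=np.int8)
        G = compute_grm(make_geno(calls))
        np.testing.assert_allclose(G.values[0], G.values[1], atol=1e-12)
        assert G.values[0, 1] == pytest.approx(G.values[0, 0])
        # perfect correlation between duplicate rows
        assert np.corrcoef(G.values[0], G.values[1])[0, 1] == pytest.approx(1.0)

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(make_geno([[0, 2], [0, 2]]))


def toy_grm():
    ids = list("abcdef")
    rng = np.random.default_rng(5)
    A = rng.normal(size=(6, 10))
    G = A @ A.T / 10 + 0.5 * np.eye(6)
    return GRM(ids, G)


class TestDiversityProportion:
    def test_scalar_subset(self):
        G = GRM(["x", "t1", "t2"], np.array([
            [1.0, 0.4, 0.6], [0.4, 1.0, 0.1], [0.6, 0.1, 1.0]]))
        res = diversity_proportion(G, ["x"], ["t1", "t2"])
        assert res.proportions[0] == pytest.approx(0.5)
        assert res.captured == pytest.approx(0.5)

    def test_identity_grm_returns_c_exactly(self):
        n = 5
        rng = np.random.default_rng(2)
        vals = np.eye(n)
        off = rng.normal(scale=0.1, size=(n, 3))
        full = np.block([[vals, off], [off.T, np.eye(3)]])
        full = (full + full.T) / 2
        ids = [f"s{i}" for i in range(n)] + ["t0", "t1", "t2"]
        G = GRM(ids, full)
        res = diversity_proportion(G, ids[:n], ids[n:])
        cn = G.block(ids[:n], ids[n:]).mean(axis=1)
        np.testing.assert_allclose(res.proportions, cn, atol=1e-12)

    def test_matches_explicit_inverse_oracle(self):
        G = toy_grm()
        subset, target = ["a", "b", "c"], ["d", "e", "f"]
        res = diversity_proportion(G, subset, target)
        Gn = G.block(subset)
        cn = G.block(subset, target).mean(axis=1)
        np.testing.assert_allclose(res.proportions, np.linalg.inv(Gn) @ cn,
                                   atol=1e-10)
        assert res.residual < 1e-8

    def test_solve_residual_on_random_spd(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(2, 8)
            A = rng.normal(size=(n, n + 2))
            Gn = A @ A.T / (n + 2) + 0.1 * np.eye(n)
            cn = rng.normal(size=n)
            P = np.linalg.solve(Gn, cn)
            assert np.max(np.abs(Gn @ P - cn)) < 1e-8

    def test_near_singular_raises_with_ridge_advice(self):
        vals = np.ones((3, 3)) + 1e-12 * np.eye(3)
        full = np.block([[vals, 0.1 * np.ones((3, 1))],
                         [0.1 * np.ones((1, 3)), np.ones((1, 1))]])
        G = GRM(["a", "b", "c", "t"], full)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            diversity_proportion(G, ["a", "b", "c"], ["t"])
        res = diversity_proportion(G, ["a", "b", "c"], ["t"], ridge=1e-6)
        assert np.isfinite(res.captured)


class TestSelectReference:
    def test_full_candidate_set_limit(self):
        G = toy_grm()
        cand, target = ["a", "b", "c"], ["d", "e", "f"]
        selected, trace = select_reference(G, cand, target, k=3)
        assert sorted(selected) == cand
        full = diversity_proportion(G, cand, target)
        assert trace["captured"].iloc[-1] == pytest.approx(full.captured)

    def test_k1_matches_singleton_brute_force(self):
        G = toy_grm()
        cand, target = ["a", "b", "c", "d"], ["e", "f"]
        selected, trace = select_reference(G, cand, target, k=1)
        brute = {c: diversity_proportion(G, [c], target).captured for c in cand}
        assert selected[0] == max(brute, key=brute.get)
        assert trace["captured"].iloc[0] == pytest.approx(max(brute.values()))

    def test_duplicate_candidate_adds_nothing(self):
        # an exact duplicate makes the augmented block singular -> skipped
        base = toy_grm().values
        vals = np.zeros((7, 7))
        vals[:6, :6] = base
        vals[6, :6] = base[0, :6]
        vals[:6, 6] = base[:6, 0]
        vals[6, 6] = base[0, 0]
        G = GRM(list("abcdef") + ["a_dup"], vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected, _ = select_reference(
                G, ["a", "a_dup", "b", "c"], ["d", "e", "f"], k=4)
        # the duplicate never precedes a non-duplicate candidate
        non_dup_positions = [selected.index(x) for x in ("a", "b", "c")]
        if "a_dup" in selected:
            assert selected.index("a_dup") > max(non_dup_positions)

    def test_trace_monotone_while_additions_help(self):
        # On a pedigree-structured GRM with k well below the candidate pool,
        # each greedy addition increases the captured proportion.  (Forcing
        # additions past saturation can legitimately reduce it, since P_n
        # entries may be negative.)
        from sireimpute.grm import compute_grm, sires_and_mgs
        from sireimpute.qc import qc_filter
        from sireimpute.simulate import simulate_study, smoke_config

        truth, obs = simulate_study(smoke_config(seed=3))
        geno, _ = qc_filter(obs, truth.pedigree)
        genotyped = set(geno.animals)
        cand = [a for a in sires_and_mgs(truth.pedigree, "G0") if a in genotyped]
        target = [a for a in truth.pedigree.in_generation("G0") if a in genotyped]
        G = compute_grm(geno)
        _, trace = select_reference(G, cand, target, k=22)
        assert (np.diff(trace["captured"].to_numpy()) >= -1e-10).all()

    def test_sklearn_estimator_conventions(self):
        from sklearn.base import clone

        sel = GreedyDiversitySelector(k=2, ridge=1e-6)
        assert sel.get_params() == {"k": 2, "ridge": 1e-6}
        sel2 = clone(sel)
        G = toy_grm()
        sel2.fit(G, list("abcd"), ["e", "f"])
        assert len(sel2.selected_) == 2
        assert not hasattr(sel, "selected_")


class TestTopKRelationship:
    def test_mean_of_top_five(self):
        vals = np.eye(7)
        rel = [0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
        vals[0, 1:] = rel
        vals[1:, 0] = rel
        G = GRM(list("xabcdef"), vals)
        assert top_k_relationship(G, "x", list("abcdef"), k=5) == pytest.approx(0.4)

    def test_small_reference_truncates(self):
        vals = np.eye(4)
        vals[0, 1:] = [0.3, 0.2, 0.1]
        vals[1:, 0] = [0.3, 0.2, 0.1]
        G = GRM(list("xabc"), vals)
        assert top_k_relationship(G, "x", list("abc"), k=5) == pytest.approx(0.2)

    def test_k1_is_max(self):
        vals = np.eye(4)
        vals[0, 1:] = [0.3, 0.9, 0.1]
        vals[1:, 0] = [0.3, 0.9, 0.1]
        G = GRM(list("xabc"), vals)
        assert top_k_relationship(G, "x", list("abc"), k=1) == pytest.approx(0.9)

    def test_self_excluded_with_warning(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.5
        G = GRM(list("xab"), vals)
        with pytest.warns(UserWarning, match="excluded"):
            v = top_k_relationship(G, "x", ["x", "a"], k=1)
        assert v == pytest.approx(0.5)


class TestStratifyByAncestor:
    def _pedigree(self):
        # 4 sires, 4 dams (with their own sires), 12 validation animals
        recs = [(f"mg{i}", None, None, "F") for i in range(4)]
        recs += [(f"s{i}", None, None, "T") for i in range(4)]
        recs += [(f"d{i}", f"mg{i}", None, "T") for i in range(4)]
        layout = [
            ("v0", "s0", "d0"), ("v1", "s0", "d1"), ("v2", "s1", "d0"),
            ("v3", "s1", "d2"), ("v4", "s2", "d2"), ("v5", "s2", "d3"),
            ("v6", "s3", "d3"), ("v7", "s3", "d0"), ("v8", "s0", "d3"),
            ("v9", "s1", "d1"), ("v10", "s2", None), ("v11", "s3", "d1"),
        ]
        recs += [(a, s, d, "G0") for a, s, d in layout]
        return make_pedigree(recs, generations=["F", "T", "G0"])

    def test_basic_definitions(self):
        ped = self._pedigree()
        labels = stratify_by_ancestor(ped, ["v0"], ["s0"])
        assert labels["v0"] == "GR_S"
        labels = stratify_by_ancestor(ped, ["v0"], ["s0", "mg0"])
        assert labels["v0"] == "GR_SMGS"
        labels = stratify_by_ancestor(ped, ["v0"], ["mg0"])
        assert labels["v0"] == "GR_MGS"

    def test_hand_enumerated_counts(self):
        ped = self._pedigree()
        reference = ["s0", "s1", "mg0", "mg1"]
        validation = [f"v{i}" for i in range(12)]
        labels = stratify_by_ancestor(ped, validation, reference)
        # hand enumeration: sire in ref for v0,v1,v2,v3,v8,v9; MGS in ref when
        # dam is d0 (mg0) or d1 (mg1): v0,v2,v7 (d0); v1,v9,v11 (d1)
        expected = {
            "v0": "GR_SMGS", "v1": "GR_SMGS", "v2": "GR_SMGS", "v3": "GR_S",
            "v4": "NONE", "v5": "NONE", "v6": "NONE", "v7": "GR_MGS",
            "v8": "GR_S", "v9": "GR_SMGS", "v10": "NONE", "v11": "GR_MGS",
        }
        assert labels.to_dict() == expected

    def test_missing_dam_link_counts_as_absent(self):
        ped = self._pedigree()
        labels = stratify_by_ancestor(ped, ["v10"], ["s2", "mg0", "mg1"])
        assert labels["v10"] == "GR_S"
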