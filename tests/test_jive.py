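"""JIVE decomposition: structure, orthogonality, rank selection, exports."""

import numpy as np
import pandas as pd
import pytest

from actirhythm.jive import JIVE, FeatureBlock, loading_report, select_ranks


def _unit(v):
    return v / np.linalg.norm(v)


def make_blocks(n=250, p1=20, p2=15, noise=0.05, seed=0):
    """Two blocks sharing one joint direction plus one individual direction
    each; returns (dict of DataFrames, truth dict).

    Score vectors are mean-centered before orthonormalization so the truth
    lives in the same centered subject space the decomposition works in
    (per-feature centering would otherwise tilt the generating directions).
    """
    rng = np.random.default_rng(seed)
    joint = _unit(rng.normal(size=n) - 0.0)
    joint = _unit(joint - joint.mean())
    r1 = rng.normal(size=n)
    r1 -= r1.mean()
    ind1 = _unit(r1 - np.dot(r1, joint) * joint)
    r2 = rng.normal(size=n)
    r2 -= r2.mean()
    ind2 = r2 - np.dot(r2, joint) * joint
    ind2 = _unit(ind2 - np.dot(ind2, ind1) * ind1)
    u1, u2 = rng.normal(size=p1), rng.normal(size=p2)
    w1, w2 = rng.normal(size=p1), rng.normal(size=p2)
    X1 = 8 * np.outer(u1, joint) + 5 * np.outer(w1, ind1) + noise * rng.normal(size=(p1, n))
    X2 = 6 * np.outer(u2, joint) + 4 * np.outer(w2, ind2) + noise * rng.normal(size=(p2, n))
    ids = [f"S{i}" for i in range(n)]
    blocks = {
        "PA": pd.DataFrame(X1.T, index=ids, columns=[f"pa{j}" for j in range(p1)]),
        "CR": pd.DataFrame(X2.T, index=ids, columns=[f"cr{j}" for j in range(p2)]),
    }
    return blocks, {"joint": joint, "ind1": ind1, "ind2": ind2}


def principal_angle_deg(a, b):
    """Largest principal angle between the column spaces of a and b."""
    qa, _ = np.linalg.qr(np.atleast_2d(a).T if a.ndim == 1 else a)
    qb, _ = np.linalg.qr(np.atleast_2d(b).T if b.ndim == 1 else b)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return float(np.degrees(np.arccos(np.clip(s.min(), -1, 1))))


@pytest.fixture(scope="module")
def fitted():
    blocks, truth = make_blocks()
    res = JIVE(blocks).fit(joint_rank=1, individual_ranks=(1, 1))
    return res, truth


class TestStructure:
    def test_zero_blocks_give_empty_model(self):
        ids = [f"S{i}" for i in range(10)]
        blocks = {
            "PA": pd.DataFrame(np.zeros((10, 4)), index=ids),
            "CR": pd.DataFrame(np.zeros((10, 3)), index=ids),
        }
        res = JIVE(blocks).fit(joint_rank=0, individual_ranks=(0, 0))
        assert res.joint_scores.shape == (10, 0)
        assert all(s.shape == (10, 0) for s in res.individual_scores)
        assert res.export_scores().empty

    def test_additive_decomposition_exact(self, fitted):
        res, _ = fitted
        for b, J, A in zip(res.blocks, res.J, res.A):
            E = b.features - J - A
            assert np.allclose(b.features, J + A + E)  # identity by construction
            # energies add: orthogonality of the three terms
            total = np.sum(b.features**2)
            parts = np.sum(J**2) + np.sum(A**2) + np.sum(E**2)
            assert parts == pytest.approx(total, rel=1e-4)

    def test_joint_row_space_shared_across_blocks(self, fitted):
        res, _ = fitted
        row_spaces = []
        for J in res.J:
            _, _, vt = np.linalg.svd(J, full_matrices=False)
            row_spaces.append(vt[: res.joint_rank].T)
        angle = principal_angle_deg(row_spaces[0], row_spaces[1])
        assert angle < 1e-4

    def test_individual_orthogonal_to_joint(self, fitted):
        res, _ = fitted
        V = res.joint_row_space
        for A in res.A:
            assert np.max(np.abs(A @ V)) < 1e-10

    def test_joint_space_recovered_within_five_degrees(self, fitted):
        res, truth = fitted
        angle = principal_angle_deg(res.joint_row_space[:, 0], truth["joint"])
        assert angle < 5.0

    def test_variance_decomposition_recovers_generating_shares(self):
        """With known joint/individual energies and tiny noise, the variance
        shares match the construction."""
        blocks, _ = make_blocks(noise=1e-4, seed=3)
        res = JIVE(blocks).fit(joint_rank=1, individual_ranks=(1, 1))
        for v in res.var_decomposition:
            assert v["joint"] + v["individual"] == pytest.approx(1.0, abs=1e-3)
            assert v["residual"] < 1e-3

    def test_subject_permutation_equivariance(self):
        blocks, _ = make_blocks(n=60, seed=4)
        res = JIVE(blocks).fit(joint_rank=1, individual_ranks=(1, 1))
        perm = np.random.default_rng(5).permutation(60)
        pblocks = {k: v.iloc[perm] for k, v in blocks.items()}
        pres = JIVE(pblocks).fit(joint_rank=1, individual_ranks=(1, 1))
        a = res.export_scores().to_numpy()[perm]
        b = pres.export_scores().to_numpy()
        # scores agree up to per-column sign (SVD sign ambiguity broken by
        # loadings, which are permutation-invariant, so signs match too)
        assert np.allclose(a, b, atol=1e-6)

    def test_infeasible_ranks_rejected(self):
        blocks, _ = make_blocks(n=10, p1=4, p2=3, seed=6)
        with pytest.raises(ValueError):
            JIVE(blocks).fit(joint_rank=5, individual_ranks=(4, 3))

    def test_mismatched_subjects_rejected(self):
        blocks, _ = make_blocks(n=12, seed=7)
        blocks["CR"] = blocks["CR"].iloc[::-1]
        with pytest.raises(ValueError):
            JIVE(blocks)


class TestRankSelection:
    def test_pure_noise_selects_zero_ranks(self):
        rng = np.random.default_rng(8)
        ids = [f"S{i}" for i in range(80)]
        blocks = {
            "PA": pd.DataFrame(rng.normal(size=(80, 12)), index=ids),
            "CR": pd.DataFrame(rng.normal(size=(80, 9)), index=ids),
        }
        rj, rind = select_ranks(blocks, n_perm=60, alpha=0.05, seed=1)
        assert rj == 0
        assert rind == [0, 0]

    def test_constructed_structure_selects_one_one_one(self):
        blocks, _ = make_blocks(n=120, seed=9)
        rj, rind = select_ranks(blocks, n_perm=60, alpha=0.05, seed=2)
        assert rj == 1
        assert rind == [1, 1]

    def test_alpha_one_admits_maximal_ranks(self):
        blocks, _ = make_blocks(n=40, p1=6, p2=5, seed=10)
        rj_strict, _ = select_ranks(blocks, n_perm=30, alpha=0.05, seed=3)
        rj_loose, rind_loose = select_ranks(
            blocks, n_perm=30, alpha=0.9999, seed=3, max_rank=4
        )
        assert rj_loose >= rj_strict
        assert all(r >= 1 for r in rind_loose)

    def test_too_few_permutations_rejected(self):
        blocks, _ = make_blocks(n=20, seed=11)
        with pytest.raises(ValueError):
            select_ranks(blocks, n_perm=10)


class TestExports:
    def test_scores_standardized_and_uncorrelated(self, fitted):
        res, _ = fitted
        scores = res.export_scores()
        assert list(scores.columns) == ["Joint1", "PA_1", "CR_1"]
        sds = scores.std(ddof=1)
        assert np.allclose(sds, 1.0, atol=1e-9)
        corr = scores.corr().to_numpy()
        off = corr[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_loading_report_threshold_zero_lists_all(self, fitted):
        res, _ = fitted
        rep = loading_report(res, threshold=0.0)
        assert len(rep["joint"][0]) == 35  # p1 + p2 features
        assert len(rep["individual"]["PA"][0]) == 20

    def test_loading_report_relative_magnitudes(self):
        """A component loading equally on 4 features reports 0.25 each; a
        single-feature component reports relative magnitude 1.  Constructed
        directly at the results level so the expected shares are exact."""
        from actirhythm.jive import FeatureBlock, JIVEResults

        n = 6
        ids = [f"S{i}" for i in range(n)]

        def block(name, p):
            return FeatureBlock(
                name=name,
                features=np.zeros((p, n)),
                feature_names=[f"{name.lower()}{j}" for j in range(p)],
                subject_ids=ids,
            )

        equal = np.full((4, 1), 0.5)       # unit-norm, equal on 4 features
        single = np.array([[0.0], [1.0], [0.0]])
        res = JIVEResults(
            blocks=[block("PA", 4), block("CR", 3)],
            joint_rank=0,
            individual_ranks=(1, 1),
            J=[np.zeros((4, n)), np.zeros((3, n))],
            A=[np.zeros((4, n)), np.zeros((3, n))],
            joint_row_space=np.zeros((n, 0)),
            joint_loadings=[np.zeros((4, 0)), np.zeros((3, 0))],
            joint_scores=np.zeros((n, 0)),
            individual_loadings=[equal, single],
            individual_scores=[np.zeros((n, 1)), np.zeros((n, 1))],
            var_decomposition=[{}, {}],
            n_iter=1,
        )
        rep = loading_report(res, threshold=0.05)
        pa_mags = [e["relative_magnitude"] for e in rep["individual"]["PA"][0]]
        assert pa_mags == pytest.approx([0.25] * 4, abs=1e-12)
        cr_entries = rep["individual"]["CR"][0]
        assert len(cr_entries) == 1
        assert cr_entries[0]["feature"] == "cr1"
        assert cr_entries[0]["relative_magnitude"] == pytest.approx(1.0)
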