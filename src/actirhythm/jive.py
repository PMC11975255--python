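"""Joint and Individual Variation Explained (JIVE) for two feature blocks.

Each block is a feature x subject matrix over the same subjects.  JIVE
decomposes every (scaled) block X_k into

    X_k = J_k + A_k + E_k

where the joint terms J_k share one row space (subject-space directions
common to both blocks), each individual term A_k has a row space orthogonal
to the joint one (block-specific structure), and E_k is residual.  Estimation
is the classic alternating scheme: the joint structure is the rank-r_J
truncated SVD of the stacked blocks (with current individual structure
removed), each individual structure the rank-r_k truncated SVD of the
block residual projected orthogonally to the joint row space, iterated to
convergence of the total squared residual.

Before decomposition each feature is z-scored and each block divided by its
Frobenius norm, so blocks with unequal feature counts contribute equal total
variation.  Rank selection, when requested, uses sequential permutation
tests.  Scores are exported standardized and sign-oriented for use as
regression predictors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fpca import component_sign

__all__ = ["FeatureBlock", "JIVE", "JIVEResults", "select_ranks", "loading_report"]


@dataclass
class FeatureBlock:
    """One named block: features x subjects, with its scaling record."""

    name: str
    features: np.ndarray           # (n_features, n_subjects), scaled
    feature_names: list[str]
    subject_ids: list[str]
    center: np.ndarray = field(default=None)  # per-feature center (original scale)
    scale: np.ndarray = field(default=None)   # per-feature scale
    block_scale: float = 1.0                  # Frobenius divisor

    @classmethod
    def from_dataframe(cls, name: str, df: pd.DataFrame) -> "FeatureBlock":
        """Build a scaled block from a subject x feature DataFrame.

        Missing entries are mean-imputed (with a warning via NaN count in the
        scaling record being implicit); each feature is z-scored (ddof=1) and
        the block divided by its Frobenius norm.
        """
        X = df.to_numpy(dtype=float).T  # features x subjects
        center = np.nanmean(X, axis=1)
        inds = np.where(np.isnan(X))
        if inds[0].size:
            X[inds] = np.take(center, inds[0])
        sd = np.std(X, axis=1, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - center[:, None]) / sd[:, None]
        bscale = float(np.linalg.norm(X))
        if bscale == 0:
            bscale = 1.0
        X = X / bscale
        return cls(
            name=name,
            features=X,
            feature_names=list(df.columns),
            subject_ids=[str(i) for i in df.index],
            center=center,
            scale=sd,
            block_scale=bscale,
        )

    @property
    def n_subjects(self) -> int:
        return self.features.shape[1]


def _svd_approx(X: np.ndarray, rank: int):
    """Rank-r truncated SVD; returns (approx, U, s, Vt)."""
    if rank == 0:
        z = np.zeros_like(X)
        return z, np.zeros((X.shape[0], 0)), np.zeros(0), np.zeros((0, X.shape[1]))
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    return (u * s) @ vt, u, s, vt


class JIVE:
    """JIVE model of two (or more) feature blocks over common subjects.

    Parameters
    ----------
    blocks : dict[str, pandas.DataFrame] or list[FeatureBlock]
        Subject x feature tables with identical, identically ordered index.
    """

    def __init__(self, blocks):
        if isinstance(blocks, dict):
            blocks = [FeatureBlock.from_dataframe(k, v) for k, v in blocks.items()]
        self.blocks: list[FeatureBlock] = list(blocks)
        n = {b.n_subjects for b in self.blocks}
        if len(n) != 1:
            raise ValueError("blocks must share the same subjects in the same order")
        ids = [tuple(b.subject_ids) for b in self.blocks]
        if len(set(ids)) != 1:
            raise ValueError("blocks must share identical subject ordering")
        self.n_subjects = n.pop()

    def fit(
        self,
        joint_rank: int = 1,
        individual_ranks: tuple[int, ...] | list[int] = (4, 3),
        tol: float = 1e-8,
        max_iter: int = 500,
    ) -> "JIVEResults":
        K = len(self.blocks)
        individual_ranks = tuple(int(r) for r in individual_ranks)
        if len(individual_ranks) != K:
            raise ValueError("one individual rank per block required")
        Xs = [b.features for b in self.blocks]
        n = self.n_subjects
        feasible = min(n, sum(x.shape[0] for x in Xs))
        if joint_rank + max(individual_ranks, default=0) > feasible:
            raise ValueError("requested ranks exceed what the data can support")

        As = [np.zeros_like(x) for x in Xs]
        Js = [np.zeros_like(x) for x in Xs]
        V = np.zeros((n, joint_rank))
        rows = np.cumsum([0] + [x.shape[0] for x in Xs])
        prev = np.inf
        converged = False
        for it in range(max_iter):
            stacked = np.vstack([x - a for x, a in zip(Xs, As)])
            Jfull, _, _, vt = _svd_approx(stacked, joint_rank)
            V = vt.T  # (n, r_J) orthonormal joint row-space basis
            Js = [Jfull[rows[k] : rows[k + 1]] for k in range(K)]
            proj_perp = np.eye(n) - V @ V.T
            As = [
                _svd_approx((x - j) @ proj_perp, r)[0]
                for x, j, r in zip(Xs, Js, individual_ranks)
            ]
            resid = sum(
                float(np.sum((x - j - a) ** 2)) for x, j, a in zip(Xs, Js, As)
            )
            if abs(prev - resid) < tol:
                converged = True
                break
            prev = resid
        if not converged:
            raise RuntimeError(
                f"JIVE did not converge in {max_iter} iterations "
                f"(last residual change {abs(prev - resid):.3e})"
            )
        # enforce exact orthogonality of the individual terms to the joint
        # row space (numerical hygiene after the final update)
        proj_perp = np.eye(n) - V @ V.T
        As = [a @ proj_perp for a in As]

        joint_loadings, joint_scores = _structure(np.vstack(Js), joint_rank)
        ind_loadings, ind_scores = [], []
        for a, r in zip(As, individual_ranks):
            L, S = _structure(a, r)
            ind_loadings.append(L)
            ind_scores.append(S)
        # split the stacked joint loadings per block
        joint_loadings_per_block = [
            joint_loadings[rows[k] : rows[k + 1]] for k in range(K)
        ]
        var = []
        for x, j, a in zip(Xs, Js, As):
            tot = float(np.sum(x**2))
            var.append(
                {
                    "joint": float(np.sum(j**2)) / tot if tot else 0.0,
                    "individual": float(np.sum(a**2)) / tot if tot else 0.0,
                    "residual": float(np.sum((x - j - a) ** 2)) / tot if tot else 0.0,
                }
            )
        return JIVEResults(
            blocks=self.blocks,
            joint_rank=joint_rank,
            individual_ranks=individual_ranks,
            J=Js,
            A=As,
            joint_row_space=V,
            joint_loadings=joint_loadings_per_block,
            joint_scores=joint_scores,
            individual_loadings=ind_loadings,
            individual_scores=ind_scores,
            var_decomposition=var,
            n_iter=it + 1,
        )


def _structure(M: np.ndarray, rank: int):
    """(loadings, scores) of a low-rank matrix: unit-norm feature loadings,
    scores carrying the singular values (n x r)."""
    if rank == 0:
        return np.zeros((M.shape[0], 0)), np.zeros((M.shape[1], 0))
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    return u[:, :rank], (vt[:rank].T * s[:rank])


@dataclass
class JIVEResults:
    blocks: list[FeatureBlock]
    joint_rank: int
    individual_ranks: tuple[int, ...]
    J: list[np.ndarray]
    A: list[np.ndarray]
    joint_row_space: np.ndarray
    joint_loadings: list[np.ndarray]
    joint_scores: np.ndarray
    individual_loadings: list[np.ndarray]
    individual_scores: list[np.ndarray]
    var_decomposition: list[dict]
    n_iter: int

    def export_scores(self) -> pd.DataFrame:
        """Subject score table: Joint1.., <block>_1.. columns.

        Every column is standardized to unit variance (ddof=1) and oriented
        by the same deterministic sign rule as the fPCA components (applied
        to the corresponding loading vector).
        """
        ids = self.blocks[0].subject_ids
        data: dict[str, np.ndarray] = {}
        stacked_joint_loadings = (
            np.vstack(self.joint_loadings) if self.joint_rank else np.zeros((0, 0))
        )
        for r in range(self.joint_rank):
            col = self.joint_scores[:, r]
            sgn = component_sign(stacked_joint_loadings[:, r])
            data[f"Joint{r + 1}"] = _standardize(col * sgn)
        for b, L, S in zip(self.blocks, self.individual_loadings, self.individual_scores):
            for r in range(S.shape[1]):
                sgn = component_sign(L[:, r])
                data[f"{b.name}_{r + 1}"] = _standardize(S[:, r] * sgn)
        return pd.DataFrame(data, index=pd.Index(ids, name="subject_id"))

    def summary(self) -> str:
        lines = [
            "JIVE decomposition (%d blocks, joint rank %d, converged in %d iterations)"
            % (len(self.blocks), self.joint_rank, self.n_iter),
            "block   rank(ind)   joint%%   individual%%   residual%%",
        ]
        for b, r, v in zip(self.blocks, self.individual_ranks, self.var_decomposition):
            lines.append(
                "%-6s  %9d   %6.1f   %11.1f   %9.1f"
                % (
                    b.name,
                    r,
                    100 * v["joint"],
                    100 * v["individual"],
                    100 * v["residual"],
                )
            )
        return "\n".join(lines)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    return x / sd if sd > 0 else x


def select_ranks(
    blocks,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    max_rank: int = 10,
) -> tuple[int, list[int]]:
    """Sequential permutation selection of the joint and individual ranks.

    Joint: singular values of the stacked blocks are compared, index by
    index, with their null distribution under permutation of subject order
    within one block (which destroys cross-block alignment but preserves each
    block's own structure); the rank grows while the observed value exceeds
    the (1-alpha) null quantile.  Individual (per block): the same sequential
    test on the joint-removed residual, with nulls from permuting entries
    within each feature row.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a usable null quantile")
    if isinstance(blocks, dict):
        blocks = [FeatureBlock.from_dataframe(k, v) for k, v in blocks.items()]
    rng = np.random.default_rng(seed)
    Xs = [b.features for b in blocks]
    n = Xs[0].shape[1]

    def seq_rank(observed: np.ndarray, null_s: np.ndarray) -> int:
        q = np.quantile(null_s, 1 - alpha, axis=0)
        r = 0
        for i in range(min(len(observed), max_rank)):
            if observed[i] > q[i]:
                r += 1
            else:
                break
        return r

    m = min(np.vstack(Xs).shape)
    obs = np.linalg.svd(np.vstack(Xs), compute_uv=False)
    null = np.empty((n_perm, m))
    for p in range(n_perm):
        perm = rng.permutation(n)
        null[p] = np.linalg.svd(
            np.vstack([Xs[0]] + [x[:, perm] for x in Xs[1:]]), compute_uv=False
        )[:m]
    r_joint = seq_rank(obs, null)

    # joint-removed residuals
    if r_joint > 0:
        _, _, vt = np.linalg.svd(np.vstack(Xs), full_matrices=False)
        V = vt[:r_joint].T
        proj_perp = np.eye(n) - V @ V.T
        Rs = [x @ proj_perp for x in Xs]
    else:
        Rs = Xs
    r_ind: list[int] = []
    for R in Rs:
        mm = min(R.shape)
        obs_k = np.linalg.svd(R, compute_uv=False)
        null_k = np.empty((n_perm, mm))
        for p in range(n_perm):
            Rp = np.array([rng.permutation(row) for row in R])
            null_k[p] = np.linalg.svd(Rp, compute_uv=False)[:mm]
        r_ind.append(seq_rank(obs_k, null_k))
    return r_joint, r_ind


def loading_report(results: JIVEResults, threshold: float = 0.05) -> dict:
    """Per-component feature lists with sign and relative magnitude.

    For each component the relative magnitude of a feature is its squared
    loading as a share of the component's total squared loading (the loading
    vectors are unit norm, so this is loading^2); features above ``threshold``
    are listed, largest first.
    """
    report: dict = {"joint": [], "individual": {}}
    all_names = [nm for b in results.blocks for nm in b.feature_names]
    stacked = np.vstack(results.joint_loadings) if results.joint_rank else None
    for r in range(results.joint_rank):
        v = stacked[:, r]
        report["joint"].append(_component_entries(v, all_names, threshold))
    for b, L in zip(results.blocks, results.individual_loadings):
        comps = []
        for r in range(L.shape[1]):
            comps.append(_component_entries(L[:, r], b.feature_names, threshold))
        report["individual"][b.name] = comps
    return report


def _component_entries(v: np.ndarray, names: list[str], threshold: float) -> list[dict]:
    total = float(np.sum(v**2))
    if total == 0:
        return []
    rel = v**2 / total
    order = np.argsort(rel)[::-1]
    return [
        {
            "feature": names[i],
            "loading": float(v[i]),
            "relative_magnitude": float(rel[i]),
        }
        for i in order
        if rel[i] > threshold
    ]


def save_loading_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
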