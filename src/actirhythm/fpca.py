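"""Functional PCA of subjects' mean diurnal activity profiles.

Profiles (subject x minute-of-day) are binned to 10-minute resolution,
centered at the sample mean function, and the covariance across subjects is
eigen-decomposed (via SVD of the centered matrix).  The top-K eigenfunctions
are orthonormal in the binned Euclidean inner product; subject scores are the
projections of centered profiles onto them.  Eigenfunction signs are fixed by
a deterministic convention so component directions are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["FPCA", "FPCAResults", "orient_components", "bin_profiles"]


def bin_profiles(profiles: np.ndarray, bin_minutes: int = 10) -> np.ndarray:
    """Average minute-level profiles into ``bin_minutes`` bins."""
    profiles = np.asarray(profiles, dtype=float)
    n, m = profiles.shape
    if m % bin_minutes:
        raise ValueError(f"{m} minutes do not divide into {bin_minutes}-minute bins")
    return profiles.reshape(n, m // bin_minutes, bin_minutes).mean(axis=2)


class FPCA:
    """Functional PCA model of diurnal profiles.

    Parameters
    ----------
    profiles : (n_subjects, n_minutes) array
        Complete mean diurnal profiles (impute upstream).
    n_components : int
        Number of components to retain (default 5).
    bin_minutes : int
        Pre-binning resolution; 1 disables binning.
    """

    def __init__(self, profiles, n_components: int = 5, bin_minutes: int = 10):
        profiles = np.asarray(profiles, dtype=float)
        if profiles.ndim != 2:
            raise ValueError("profiles must be a subject x time matrix")
        if np.isnan(profiles).any():
            raise ValueError("profiles must be complete; impute upstream")
        self.profiles = (
            bin_profiles(profiles, bin_minutes) if bin_minutes > 1 else profiles
        )
        self.bin_minutes = bin_minutes
        self.n_components = int(n_components)
        n, t = self.profiles.shape
        if self.n_components > min(n - 1, t):
            raise ValueError(
                f"K={self.n_components} exceeds the rank bound min(n-1={n - 1}, T={t})"
            )

    def fit(self) -> "FPCAResults":
        mean_fn = self.profiles.mean(axis=0)
        centered = self.profiles - mean_fn
        n = centered.shape[0]
        # SVD of the centered data == eigendecomposition of the covariance
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        eigvals_all = s**2 / (n - 1)
        k = self.n_components
        eigenfunctions = vt[:k]
        eigenvalues = eigvals_all[:k]
        total = float(eigvals_all.sum())
        var_explained = eigenvalues / total if total > 0 else np.zeros(k)
        scores = centered @ eigenfunctions.T
        res = FPCAResults(
            mean_fn=mean_fn,
            eigenfunctions=eigenfunctions,
            eigenvalues=eigenvalues,
            scores=scores,
            var_explained=var_explained,
            bin_minutes=self.bin_minutes,
        )
        return orient_components(res)


@dataclass
class FPCAResults:
    mean_fn: np.ndarray
    eigenfunctions: np.ndarray  # (K, T), orthonormal rows
    eigenvalues: np.ndarray     # (K,), nonincreasing
    scores: np.ndarray          # (n, K)
    var_explained: np.ndarray
    bin_minutes: int = 10

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.mean_fn + self.scores @ self.eigenfunctions

    def summary(self) -> str:
        lines = [
            "Functional PCA (%d components, %d-minute bins)"
            % (self.n_components, self.bin_minutes),
            "component  eigenvalue   var.explained",
        ]
        for i, (ev, ve) in enumerate(zip(self.eigenvalues, self.var_explained), 1):
            lines.append("fPC%-7d %11.4g   %6.1f%%" % (i, ev, 100 * ve))
        lines.append("cumulative var. explained: %.1f%%" % (100 * self.var_explained.sum()))
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "bin_minutes": self.bin_minutes,
                    "mean_fn": self.mean_fn.tolist(),
                    "eigenfunctions": self.eigenfunctions.tolist(),
                    "eigenvalues": self.eigenvalues.tolist(),
                    "var_explained": self.var_explained.tolist(),
                },
                indent=2,
            )
        )


def component_sign(v: np.ndarray, tol: float = 1e-8) -> float:
    """Deterministic orientation of a component vector.

    Positive integral wins; when the integral is near zero relative to the
    vector's scale, the sign of the entry of maximum magnitude decides.
    """
    total = float(np.sum(v))
    scale = float(np.max(np.abs(v)))
    if scale == 0:
        return 1.0
    if abs(total) > tol * scale * v.size:
        return 1.0 if total > 0 else -1.0
    return 1.0 if v[int(np.argmax(np.abs(v)))] > 0 else -1.0


def orient_components(res: FPCAResults) -> FPCAResults:
    """Fix eigenfunction signs by convention, flipping scores consistently.

    Idempotent; leaves the reconstruction mean + scores @ eigenfunctions
    unchanged.
    """
    signs = np.array([component_sign(f) for f in res.eigenfunctions])
    return FPCAResults(
        mean_fn=res.mean_fn,
        eigenfunctions=res.eigenfunctions * signs[:, None],
        eigenvalues=res.eigenvalues.copy(),
        scores=res.scores * signs[None, :],
        var_explained=res.var_explained.copy(),
        bin_minutes=res.bin_minutes,
    )
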