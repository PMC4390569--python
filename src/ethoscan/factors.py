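"""Factor analysis of line-mean transition probabilities.

The 25 joint transition probabilities averaged per line form a lines x 25
matrix of compositional phenotypes. To look for a lower-dimensional
covariance structure among courtship transitions the pipeline applies:

1. PCA on the correlation matrix of the 25 phenotypes (standardization is
   the factor-analytic convention for variables on different scales).
2. Kaiser retention: keep components with eigenvalue > 1.
3. Principal-component factoring: loading of variable j on factor m is
   eigvec[j, m] * sqrt(eigval[m]); the eigenvalue divided by the number of
   variables gives the factor's % variance explained.
4. Varimax rotation of the retained loadings (orthogonal; maximizes the
   variance of squared loadings per factor), with optional Kaiser row
   normalization. Rotation preserves communalities and total explained
   variance, only redistributing it among factors for interpretability.
5. Regression-method factor scores for each line.

Sign convention: after rotation each factor's largest-magnitude loading is
made positive, so outputs are reproducible run to run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "correlation_pca",
    "kaiser_retain",
    "pc_factor_loadings",
    "varimax",
    "varimax_criterion",
    "TransitionFactorModel",
    "FactorResults",
]


def correlation_pca(X: np.ndarray):
    """Eigendecomposition of the correlation matrix of columns of X.

    Constant columns are dropped with a warning (their correlation is
    undefined). Returns (eigenvalues descending, eigenvectors as columns,
    kept column indices).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows (lines) for a PCA")
    sd = X.std(axis=0, ddof=1)
    # relative tolerance: a constant column's sd is rounding noise, not 0
    keep = np.flatnonzero(sd > 1e-12 * (np.abs(X).max(axis=0) + 1.0))
    if len(keep) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(keep)} constant column(s) from PCA"
        )
    Xk = X[:, keep]
    R = np.corrcoef(Xk, rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order], keep


def kaiser_retain(eigenvalues: np.ndarray) -> int:
    """Number of components with eigenvalue > 1 (Kaiser criterion)."""
    eig = np.asarray(eigenvalues, dtype=float)
    k = int(np.sum(eig > 1.0))
    if k == 0:
        warnings.warn("no eigenvalue exceeds 1; retaining zero factors")
    return k


def pc_factor_loadings(eigenvalues, eigenvectors, k: int) -> np.ndarray:
    """Unrotated principal-component loadings for the top k components."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if k > len(eigenvalues):
        raise ValueError(f"k={k} exceeds {len(eigenvalues)} components")
    return eigenvectors[:, :k] * np.sqrt(eigenvalues[:k])


def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax criterion: sum over factors of var of squared loadings."""
    L2 = np.asarray(L) ** 2
    p = L.shape[0]
    return float(np.sum(L2.var(axis=0)) * p)


def varimax(
    loadings: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
    kaiser_normalize: bool = True,
):
    """Varimax rotation by pairwise (Jacobi) planar rotations.

    Each sweep visits every factor pair and applies the closed-form angle
    that maximizes the pair's varimax criterion, so the criterion is
    non-decreasing sweep to sweep. Rows are optionally rescaled to unit
    communality during rotation (Kaiser normalization) and restored after.

    Returns (rotated loadings, rotation matrix, n_sweeps, converged,
    criterion trace per sweep). k=1 input is returned unchanged.
    """
    L = np.array(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L, np.eye(k), 0, True, [varimax_criterion(L)]
    h = np.sqrt(np.sum(L**2, axis=1))
    if kaiser_normalize:
        scale = np.where(h > 0, h, 1.0)
        L = L / scale[:, None]
    R = np.eye(k)
    trace = [varimax_criterion(L)]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        max_angle = 0.0
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = L[:, a], L[:, b]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = np.sum(u**2 - v**2)
                D = np.sum(2.0 * u * v)
                num = D - 2.0 * A * B / p
                den = C - (A**2 - B**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                max_angle = max(max_angle, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                L[:, [a, b]] = L[:, [a, b]] @ G
                R[:, [a, b]] = R[:, [a, b]] @ G
        trace.append(varimax_criterion(L))
        if max_angle < tol:
            converged = True
            break
    if not converged:
        warnings.warn("varimax did not converge within max_iter sweeps")
    if kaiser_normalize:
        L = L * scale[:, None]
    # sign convention: dominant loading per factor positive
    signs = np.sign(L[np.abs(L).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    L *= signs
    R *= signs
    return L, R, sweeps, converged, trace


class TransitionFactorModel:
    """Model: PCA + varimax factor analysis of line-mean phenotypes.

    Parameters
    ----------
    line_means : DataFrame, lines x variables (typically the 25 transition
        phenotypes from :func:`ethoscan.ethogram.line_mean_table`).
    """

    def __init__(self, line_means: pd.DataFrame):
        self.line_means = line_means
        self.variables = list(line_means.columns)

    def fit(
        self,
        n_factors: int | None = None,
        kaiser_normalize: bool = True,
        tol: float = 1e-10,
        max_iter: int = 1000,
    ) -> "FactorResults":
        """Fit; ``n_factors=None`` retains components with eigenvalue > 1."""
        X = self.line_means.to_numpy(dtype=float)
        eigvals, eigvecs, keep = correlation_pca(X)
        k = kaiser_retain(eigvals) if n_factors is None else int(n_factors)
        if k < 1:
            raise ValueError("no factors to extract")
        unrotated = pc_factor_loadings(eigvals, eigvecs, k)
        rotated, R, sweeps, converged, trace = varimax(
            unrotated, tol=tol, max_iter=max_iter,
            kaiser_normalize=kaiser_normalize,
        )
        return FactorResults(
            model=self,
            eigenvalues=eigvals,
            kept_columns=keep,
            n_factors=k,
            loadings_unrotated=unrotated,
            loadings=rotated,
            rotation=R,
            rotation_sweeps=sweeps,
            rotation_converged=converged,
            criterion_trace=trace,
        )


@dataclass
class FactorResults:
    """Fitted factor model: loadings, variance explained, scores."""

    model: TransitionFactorModel
    eigenvalues: np.ndarray
    kept_columns: np.ndarray
    n_factors: int
    loadings_unrotated: np.ndarray
    loadings: np.ndarray
    rotation: np.ndarray
    rotation_sweeps: int
    rotation_converged: bool
    criterion_trace: list = field(repr=False, default_factory=list)

    @property
    def variable_names(self) -> list[str]:
        return [self.model.variables[i] for i in self.kept_columns]

    @property
    def communalities(self) -> np.ndarray:
        """Per-variable sum of squared loadings (rotation-invariant)."""
        return np.sum(self.loadings**2, axis=1)

    @property
    def variance_explained(self) -> np.ndarray:
        """Per rotated factor, % of total variance explained."""
        p = self.loadings.shape[0]
        return 100.0 * np.sum(self.loadings**2, axis=0) / p

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"F{m + 1}" for m in range(self.n_factors)]
        return pd.DataFrame(self.loadings, index=self.variable_names,
                            columns=cols)

    def loading_correlation(self, i: int = 0, j: int = 1):
        """Pearson r (and P) between two factors' loading vectors."""
        from scipy import stats
        r, p = stats.pearsonr(self.loadings[:, i], self.loadings[:, j])
        return float(r), float(p)

    def scores(self) -> pd.DataFrame:
        """Regression-method factor scores per line (zero-mean columns)."""
        X = self.model.line_means.to_numpy(dtype=float)[:, self.kept_columns]
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        R = np.corrcoef(X, rowvar=False)
        B = np.linalg.solve(R, self.loadings)
        F = Z @ B
        cols = [f"F{m + 1}" for m in range(self.n_factors)]
        return pd.DataFrame(F, index=self.model.line_means.index,
                            columns=cols)

    def summary(self) -> str:
        ve = self.variance_explained
        head = [
            f"Factor analysis: {len(self.variable_names)} variables, "
            f"{self.n_factors} factors "
            f"(varimax, {self.rotation_sweeps} sweeps, "
            f"converged={self.rotation_converged})",
            "factor   % variance",
        ]
        head += [f"  F{m + 1:<5d} {ve[m]:8.2f}" for m in range(len(ve))]
        head.append(f"  total  {ve.sum():8.2f}")
        return "\n".join(head)
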