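"""Thought-space decomposition of multi-dimensional experience-sampling (mDES) reports.

Probe-level item ratings (16 items, 1-10 scale) are decomposed with an
unrotated PCA of the item correlation matrix into a small set of experience
components ("thought space").  Component reproducibility is quantified by a
bootstrapped split-half analysis: the data are repeatedly halved, each half is
decomposed independently, and homologous components across halves are matched
by maximising summed absolute loading correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ThoughtSpaceDecomposition",
    "ReliabilityResult",
    "DEFAULT_COMPONENT_NAMES",
    "fit_thought_space",
    "score_probes",
    "match_homologues",
    "split_half_reliability",
    "varimax",
    "scree_report",
]

# The four experience components reported for movie-watching mDES data.
DEFAULT_COMPONENT_NAMES = (
    "Episodic Knowledge",
    "Intrusive Distraction",
    "Verbal Detail",
    "Sensory Engagement",
)


def _as_item_matrix(responses) -> tuple[np.ndarray, list[str]]:
    if isinstance(responses, pd.DataFrame):
        items = [c for c in responses.columns if str(c).startswith("item_")]
        if not items:
            items = list(responses.columns)
        return responses[items].to_numpy(dtype=float), [str(c) for c in items]
    arr = np.asarray(responses, dtype=float)
    if arr.ndim != 2:
        raise ValueError("responses must be a 2-D probes x items array")
    return arr, [f"item_{i + 1}" for i in range(arr.shape[1])]


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix."""
    p, k = loadings.shape
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return loadings @ R


class ThoughtSpaceDecomposition(BaseEstimator, TransformerMixin):
    """PCA of the item correlation matrix with stored standardisation constants.

    Parameters
    ----------
    n_components : int
        Number of experience components to retain (no automatic cutoff; see
        :func:`scree_report` for an elbow diagnostic).
    rotation : {None, "varimax"}
        Optional orthogonal rotation.  The default (unrotated eigenvectors)
        yields the strictly decreasing variance profile characteristic of the
        movie-watching mDES decomposition.

    Attributes
    ----------
    loadings_ : ndarray of shape (n_items, n_components)
        Unit-norm item loadings; the sign of each column is fixed so that its
        largest-|loading| item loads positively.
    explained_variance_pct_ : ndarray of shape (n_components,)
        Eigenvalue_k / n_items * 100, non-increasing.
    eigenvalues_ : ndarray of shape (n_items,)
        Full eigenvalue spectrum of the item correlation matrix.
    item_means_, item_sds_ : ndarray of shape (n_items,)
        Standardisation constants reused when scoring new probes.
    component_names_ : list of str
    """

    def __init__(self, n_components: int = 4, rotation: str | None = None,
                 component_names: tuple[str, ...] | None = None):
        self.n_components = n_components
        self.rotation = rotation
        self.component_names = component_names

    def fit(self, X, y=None):
        X, item_names = _as_item_matrix(X)
        n, p = X.shape
        if self.n_components > p:
            raise ValueError(f"n_components={self.n_components} exceeds {p} items")
        if n < 2:
            raise ValueError("need at least 2 probe responses")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        constant = np.where(sds == 0)[0]
        if constant.size:
            bad = ", ".join(item_names[i] for i in constant)
            raise ValueError(f"constant item(s) with zero variance: {bad}")
        Z = (X - means) / sds
        corr = (Z.T @ Z) / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]

        k = self.n_components
        load = eigvecs[:, :k].copy()
        if self.rotation == "varimax" and k > 1:
            # rotate the sqrt(eigenvalue)-scaled pattern, then restore unit columns
            pattern = varimax(load * np.sqrt(eigvals[:k]))
            contrib = (pattern**2).sum(axis=0)
            order2 = np.argsort(contrib)[::-1]
            pattern = pattern[:, order2]
            expl = contrib[order2] / p * 100.0
            load = pattern / np.linalg.norm(pattern, axis=0)
        elif self.rotation not in (None, "varimax"):
            raise ValueError(f"unknown rotation {self.rotation!r}")
        else:
            expl = eigvals[:k] / p * 100.0
        # sign convention: largest-|loading| item of each component loads positively
        for j in range(k):
            i_max = np.argmax(np.abs(load[:, j]))
            if load[i_max, j] < 0:
                load[:, j] = -load[:, j]

        self.item_names_ = item_names
        self.item_means_ = means
        self.item_sds_ = sds
        self.eigenvalues_ = eigvals
        self.loadings_ = load
        self.explained_variance_pct_ = np.asarray(expl)
        names = self.component_names
        if names is None:
            names = [f"PCA_{j + 1}" for j in range(k)]
        self.component_names_ = list(names)[:k]
        return self

    def transform(self, X) -> np.ndarray:
        """Project standardised item vectors onto the loadings (component scores)."""
        check_is_fitted(self, "loadings_")
        X, _ = _as_item_matrix(X)
        if X.shape[1] != len(self.item_means_):
            raise ValueError(
                f"expected {len(self.item_means_)} items, got {X.shape[1]} "
                "(missing items are an error; no imputation)"
            )
        if np.isnan(X).any():
            raise ValueError("missing item responses are not imputed")
        Z = (X - self.item_means_) / self.item_sds_
        return Z @ self.loadings_


def fit_thought_space(responses, n_components: int,
                      rotation: str | None = None) -> ThoughtSpaceDecomposition:
    """Functional wrapper: fit a :class:`ThoughtSpaceDecomposition` on probe responses."""
    return ThoughtSpaceDecomposition(n_components=n_components, rotation=rotation).fit(responses)


def score_probes(space: ThoughtSpaceDecomposition, responses) -> np.ndarray:
    """Component scores for probe responses under a fitted thought space."""
    return space.transform(responses)


def match_homologues(loadings_a: np.ndarray, loadings_b: np.ndarray,
                     return_signs: bool = False):
    """Optimal one-to-one component matching maximising summed |column correlations|.

    Returns ``(matching, abs_corrs, similarity)`` where ``matching[j]`` is the
    column of ``loadings_b`` homologous to column ``j`` of ``loadings_a`` and
    ``similarity`` is the mean matched absolute correlation.  Exact over all
    K! assignments (Hungarian algorithm).  With ``return_signs`` a fourth
    element gives the sign of each matched correlation (useful to align the
    direction of matched components, since |r| is sign-blind).
    """
    A = np.asarray(loadings_a, dtype=float)
    B = np.asarray(loadings_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"loading shapes differ: {A.shape} vs {B.shape}")
    k = A.shape[1]
    C = np.empty((k, k))
    for i, j in itertools.product(range(k), range(k)):
        C[i, j] = np.corrcoef(A[:, i], B[:, j])[0, 1]
    absC = np.abs(C)
    rows, cols = linear_sum_assignment(-absC)
    matching = cols[np.argsort(rows)]
    abs_corrs = absC[np.arange(k), matching]
    if return_signs:
        signs = np.sign(C[np.arange(k), matching])
        return matching, abs_corrs, float(abs_corrs.mean()), signs
    return matching, abs_corrs, float(abs_corrs.mean())


@dataclass
class ReliabilityResult:
    """Bootstrapped split-half homologue reliability of a decomposition."""

    mean_similarity: float
    ci_low: float
    ci_high: float
    per_iteration: np.ndarray
    n_boot: int


def split_half_reliability(responses, n_components: int, n_boot: int = 1000,
                           seed: int = 0) -> ReliabilityResult:
    """Repeatedly half-split the probes, decompose each half and record homologue similarity."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X, _ = _as_item_matrix(responses)
    n = X.shape[0]
    if n < 4 * n_components:
        raise ValueError("too few responses for a split-half decomposition")
    rng = np.random.default_rng(seed)
    sims = np.empty(n_boot)
    for b in range(n_boot):
        perm = rng.permutation(n)
        half = n // 2
        a = ThoughtSpaceDecomposition(n_components).fit(X[perm[:half]])
        c = ThoughtSpaceDecomposition(n_components).fit(X[perm[half:]])
        _, _, sims[b] = match_homologues(a.loadings_, c.loadings_)
    lo, hi = np.percentile(sims, [2.5, 97.5])
    return ReliabilityResult(float(sims.mean()), float(lo), float(hi), sims, n_boot)


def scree_report(responses) -> pd.DataFrame:
    """Eigenvalue spectrum and cumulative explained variance for component selection."""
    X, _ = _as_item_matrix(responses)
    p = X.shape[1]
    space = ThoughtSpaceDecomposition(n_components=p).fit(X)
    pct = space.eigenvalues_ / p * 100.0
    return pd.DataFrame(
        {
            "component": np.arange(1, p + 1),
            "eigenvalue": space.eigenvalues_,
            "explained_variance_pct": pct,
            "cumulative_pct": np.cumsum(pct),
        }
    )
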