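"""Spatial-permutation ("spin") test for the gradient location of a cluster.

The observed statistic is the mean gradient value over a cluster's units.
The null rotates parcel centroids on the sphere (mirrored rotations across
hemispheres), re-maps each cluster unit to the nearest rotated unit, and
recomputes the statistic — permuting locations while preserving the map's
spatial structure and its actual values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.stats import special_ortho_group

__all__ = ["SphereModel", "SpinResult", "build_spin_null", "spin_pvalue", "spin_test"]


@dataclass
class SphereModel:
    """Parcel centroids on the unit sphere with hemisphere labels."""

    coords: np.ndarray  # units x 3
    hemisphere: np.ndarray  # 'L' / 'R' per unit

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        norms = np.linalg.norm(self.coords, axis=1)
        if np.any(np.abs(norms - 1) > 1e-9):
            raise ValueError("sphere coordinates must have unit norm (tolerance 1e-9)")
        if self.hemisphere.shape[0] != self.coords.shape[0]:
            raise ValueError("hemisphere labels must match coordinate rows")


@dataclass
class SpinResult:
    observed: float
    null: np.ndarray
    p_two_tailed: float | None
    n_perm: int
    seed: int
    tail: str = "two_tailed"
    n_redraws: int = 0


_MIRROR = np.diag([-1.0, 1.0, 1.0])  # left-right flip about the sagittal plane


def build_spin_null(
    sphere: SphereModel,
    gradient: np.ndarray,
    cluster_units: np.ndarray,
    n_perm: int,
    seed: int,
    mask: np.ndarray | None = None,
    max_redraw_factor: int = 50,
) -> SpinResult:
    """Rotation null for the cluster's mean gradient value.

    Per permutation a uniform random 3-D rotation is applied to the unit
    coordinates (the mirrored rotation to the opposite hemisphere); each
    cluster unit is re-assigned to the nearest rotated unit and the mean
    gradient value over the landed units is recorded.  Landed units outside
    ``mask`` take the value of the nearest in-mask unit; a permutation whose
    landed units all fall outside the mask is redrawn (redraws capped at
    ``max_redraw_factor * n_perm`` and counted in the result).
    """
    gradient = np.asarray(gradient, dtype=float)
    cluster_units = np.asarray(cluster_units, dtype=int)
    if cluster_units.size == 0:
        raise ValueError("cluster is empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_units = sphere.coords.shape[0]
    if mask is None:
        mask = np.ones(n_units, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask[cluster_units].all():
        raise ValueError("cluster units must lie inside the gradient mask")

    # nearest in-mask neighbour lookup for masked-out landing sites
    in_mask_idx = np.where(mask)[0]
    tree_mask = cKDTree(sphere.coords[in_mask_idx])

    def value_at(units: np.ndarray) -> np.ndarray:
        vals = np.empty(len(units))
        inside = mask[units]
        vals[inside] = gradient[units[inside]]
        if (~inside).any():
            _, nn = tree_mask.query(sphere.coords[units[~inside]])
            vals[~inside] = gradient[in_mask_idx[nn]]
        return vals

    observed = float(gradient[cluster_units].mean())

    hemis = list(np.unique(sphere.hemisphere))
    hemi_idx = {h: np.where(sphere.hemisphere == h)[0] for h in hemis}

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n_redraws = 0
    max_draws = max_redraw_factor * n_perm
    draws = 0
    p = 0
    while p < n_perm:
        if draws >= max_draws:
            raise RuntimeError(
                f"exceeded {max_draws} rotation draws with the cluster repeatedly "
                "landing outside the mask"
            )
        R = special_ortho_group.rvs(3, random_state=rng)
        draws += 1
        # one-to-one assignment of original to rotated positions per hemisphere:
        # a genuine permutation of locations, so values are never duplicated
        landed_all = np.empty(sphere.coords.shape[0], dtype=int)
        for h in hemis:
            idx = hemi_idx[h]
            Rh = R if h == hemis[0] else _MIRROR @ R @ _MIRROR
            rotated = sphere.coords[idx] @ Rh.T
            cost = -sphere.coords[idx] @ rotated.T  # maximise cosine similarity
            rows, cols = linear_sum_assignment(cost)
            landed_all[idx[rows]] = idx[cols]
        landed = landed_all[cluster_units]
        if not mask[landed].any():
            n_redraws += 1
            continue
        null[p] = value_at(landed).mean()
        p += 1

    return SpinResult(
        observed=observed,
        null=null,
        p_two_tailed=None,
        n_perm=n_perm,
        seed=seed,
        n_redraws=n_redraws,
    )


def spin_pvalue(precursor: SpinResult, tail: str = "two_tailed") -> SpinResult:
    """Permutation p with the (count + 1) / (n_perm + 1) estimator, capped at 1."""
    null, obs, n = precursor.null, precursor.observed, precursor.n_perm
    p_ge = (1 + int((null >= obs).sum())) / (n + 1)
    p_le = (1 + int((null <= obs).sum())) / (n + 1)
    if tail == "two_tailed":
        p = min(1.0, 2 * min(p_ge, p_le))
    elif tail == "greater":
        p = min(1.0, p_ge)
    elif tail == "less":
        p = min(1.0, p_le)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return SpinResult(
        observed=obs,
        null=null,
        p_two_tailed=p,
        n_perm=n,
        seed=precursor.seed,
        tail=tail,
        n_redraws=precursor.n_redraws,
    )


def spin_test(sphere: SphereModel, gradient, cluster_units, n_perm: int = 2500,
              seed: int = 0, tail: str = "two_tailed",
              mask: np.ndarray | None = None) -> SpinResult:
    """Build the rotation null and return the finished :class:`SpinResult`."""
    pre = build_spin_null(sphere, gradient, cluster_units, n_perm, seed, mask=mask)
    return spin_pvalue(pre, tail=tail)
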