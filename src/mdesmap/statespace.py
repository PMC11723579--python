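"""Gradient state-space projection of group-average movie-watching activity.

Each subject's parcel (or voxel) time series is z-scored per unit and averaged
across the cohort; the group map at every TR is then rank-correlated
(Spearman, average ranks for ties) with each of five macroscale gradient maps
inside a binary mask.  The five correlations constitute the coordinates of
that movie moment in "brain space".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ParcelTimeSeries",
    "GradientSet",
    "StateCoords",
    "GradientProjector",
    "zscore_units",
    "group_average_zscore",
    "project_to_gradients",
    "coords_at_probes",
]

GRADIENT_NAMES = (
    "G1 association-primary",
    "G2 visual-motor",
    "G3 frontoparietal-DMN",
    "G4 DAN/visual-DMN",
    "G5 lateralDMN-primary",
)


@dataclass
class ParcelTimeSeries:
    """units x TR activity matrix for one subject (or the group average)."""

    subject_id: str
    movie_id: str
    data: np.ndarray
    zscored: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D units x TR matrix")
        if np.isnan(self.data).any():
            raise ValueError("missing values inside the mask are not allowed")

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]


@dataclass
class GradientSet:
    """unit x 5 gradient weights plus a binary inclusion mask."""

    values: np.ndarray
    mask: np.ndarray
    names: tuple[str, ...] = GRADIENT_NAMES

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape[0] != self.values.shape[0]:
            raise ValueError("mask length must match gradient rows")
        if not self.mask.any():
            raise ValueError("gradient mask is empty")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("gradient values inside the mask must be finite")

    @classmethod
    def from_values(cls, values: np.ndarray, names=None) -> "GradientSet":
        """Mask = units with nonzero values in *all* gradient maps."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        mask = np.all(values != 0, axis=1) & np.isfinite(values).all(axis=1)
        kw = {} if names is None else {"names": tuple(names)}
        return cls(values=values, mask=mask, **kw)

    @property
    def n_gradients(self) -> int:
        return self.values.shape[1]


@dataclass
class StateCoords:
    """TR x n_gradients rank-correlation coordinates; NaN marks undefined TRs."""

    movie_id: str
    coords: np.ndarray
    tr_s: float = 1.0
    start_s: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        finite = self.coords[np.isfinite(self.coords)]
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("correlation coordinates must lie in [-1, 1]")

    @property
    def times_s(self) -> np.ndarray:
        return self.start_s + self.tr_s * np.arange(self.coords.shape[0])


def zscore_units(data: np.ndarray) -> np.ndarray:
    """Z-score each unit's time series; constant units become all-zero with a warning."""
    data = np.asarray(data, dtype=float)
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant unit(s); z-score defined as all-zero",
            RuntimeWarning,
            stacklevel=2,
        )
    sd = np.where(sd == 0, 1.0, sd)
    out = (data - mean) / sd
    out[constant] = 0.0
    return out


def group_average_zscore(subjects: list[ParcelTimeSeries]) -> ParcelTimeSeries:
    """Per-unit z-score of every subject, then elementwise mean across the cohort."""
    if not subjects:
        raise ValueError("no subjects")
    shape = subjects[0].data.shape
    for s in subjects[1:]:
        if s.data.shape != shape:
            raise ValueError(
                f"shape mismatch: {s.subject_id} has {s.data.shape}, expected {shape}"
            )
    acc = np.zeros(shape)
    for s in subjects:
        acc += s.data if s.zscored else zscore_units(s.data)
    return ParcelTimeSeries(
        subject_id="group",
        movie_id=subjects[0].movie_id,
        data=acc / len(subjects),
        zscored=True,
    )


class GradientProjector(BaseEstimator, TransformerMixin):
    """Transformer mapping unit x TR brain maps to per-TR gradient coordinates.

    ``fit`` stores the rank-transformed, masked gradient maps; ``transform``
    rank-correlates every TR's masked map with each gradient (Spearman with
    average ranks).  Zero-variance maps yield NaN coordinates, never a silent
    zero.
    """

    def __init__(self, min_units: int = 3):
        self.min_units = min_units

    def fit(self, gradients: GradientSet, y=None):
        if int(gradients.mask.sum()) < self.min_units:
            raise ValueError(
                f"only {int(gradients.mask.sum())} masked units; need >= {self.min_units}"
            )
        self.mask_ = gradients.mask
        self.names_ = gradients.names
        ranks = np.column_stack(
            [rankdata(gradients.values[gradients.mask, g])
             for g in range(gradients.n_gradients)]
        )
        centered = ranks - ranks.mean(axis=0)
        self.grad_ranks_centered_ = centered
        self.grad_ss_ = (centered**2).sum(axis=0)
        if np.any(self.grad_ss_ == 0):
            warnings.warn("constant gradient map inside mask", RuntimeWarning, stacklevel=2)
        return self

    def transform(self, maps: np.ndarray) -> np.ndarray:
        """maps: units x TR (full-length units; the stored mask is applied here)."""
        check_is_fitted(self, "grad_ranks_centered_")
        maps = np.asarray(maps, dtype=float)
        if maps.ndim == 1:
            maps = maps[:, None]
        if maps.shape[0] != self.mask_.shape[0]:
            raise ValueError(
                f"map has {maps.shape[0]} units but gradients have {self.mask_.shape[0]}"
            )
        sub = maps[self.mask_, :]  # masked units x TR
        ranks = np.apply_along_axis(rankdata, 0, sub)
        centered = ranks - ranks.mean(axis=0)
        ss_map = (centered**2).sum(axis=0)  # per TR
        # numerator uses the same axis-0 pairwise reduction as the sums of
        # squares, so a map identical to a gradient correlates at exactly 1.0
        n_tr = centered.shape[1]
        num = np.empty((n_tr, self.grad_ranks_centered_.shape[1]))
        for t in range(n_tr):
            num[t] = (centered[:, t][:, None] * self.grad_ranks_centered_).sum(axis=0)
        denom = np.sqrt(ss_map[:, None] * self.grad_ss_[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            coords = num / denom
        degenerate = (ss_map == 0) | np.any(self.grad_ss_ == 0)
        if np.any(degenerate):
            warnings.warn(
                "zero-variance map at one or more TRs; coordinates set to NaN",
                RuntimeWarning,
                stacklevel=2,
            )
            coords[ss_map == 0, :] = np.nan
        coords[:, self.grad_ss_ == 0] = np.nan
        return coords


def project_to_gradients(group: ParcelTimeSeries, gradients: GradientSet,
                         tr_s: float | None = None, start_s: float = 0.0) -> StateCoords:
    """Per-TR Spearman correlation between the group map and each gradient, inside the mask."""
    proj = GradientProjector().fit(gradients)
    coords = proj.transform(group.data)
    return StateCoords(
        movie_id=group.movie_id,
        coords=coords,
        tr_s=tr_s if tr_s is not None else 1.0,
        start_s=start_s,
    )


def coords_at_probes(coords: StateCoords, probe_times_s, window_s: float = 15.0) -> np.ndarray:
    """Per-probe gradient coordinates: mean over TRs in ``[t - window_s, t)``.

    ``window_s = 0`` returns the single TR at the probe time.  Probes outside
    the coordinate series' span are an error.
    """
    times = coords.times_s
    # a probe at t reports on experience just before t, so t may fall anywhere
    # in (start, end of last TR]: the last valid onset plus one TR period
    t_max = times[-1] + coords.tr_s
    out = np.empty((len(probe_times_s), coords.coords.shape[1]))
    for i, t in enumerate(np.asarray(probe_times_s, dtype=float)):
        if t < times[0] or t > t_max:
            raise ValueError(f"probe at {t} s outside coordinate span [{times[0]}, {t_max}]")
        if window_s == 0:
            j = min(int(round((t - coords.start_s) / coords.tr_s)), len(times) - 1)
            out[i] = coords.coords[j]
        else:
            sel = (times >= t - window_s) & (times < t)
            if not sel.any():  # window precedes the series: fall back to the probe TR
                j = int(round((t - coords.start_s) / coords.tr_s))
                out[i] = coords.coords[j]
            else:
                out[i] = coords.coords[sel].mean(axis=0)
    return out
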