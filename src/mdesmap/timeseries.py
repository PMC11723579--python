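"""Group-level experience time series: 15-s bin means interpolated to TR resolution.

Sparse per-participant component scores tile the clip at the sampling-grid
resolution once pooled over the counterbalanced orders; the binned group means
are then interpolated to the fMRI sampling period (TR = 1 s) to serve as
regressors for brain activity recorded in an independent cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["BinSeries", "RegressorSeries", "bin_scores", "interpolate_to_tr"]


@dataclass
class BinSeries:
    """Mean component score per sampling slot, with observation counts."""

    movie_id: str
    component: str
    bin_times_s: np.ndarray
    bin_means: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self):
        self.bin_times_s = np.asarray(self.bin_times_s, dtype=float)
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if np.any(np.diff(self.bin_times_s) <= 0):
            raise ValueError("bin times must be strictly increasing")


@dataclass
class RegressorSeries:
    """A component's experience signal at TR resolution over the sampled section."""

    movie_id: str
    component: str
    tr_s: float
    start_s: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("regressor values must be finite")

    @property
    def times_s(self) -> np.ndarray:
        return self.start_s + self.tr_s * np.arange(len(self.values))


def bin_scores(
    probe_times_s,
    scores,
    grid_s: float,
    first_probe_s: float,
    movie_id: str = "",
    component: str = "",
) -> BinSeries:
    """Average scores of all participants probed at each grid slot.

    Every probe time must lie exactly on the sampling grid (multiples of
    ``grid_s`` offset by ``first_probe_s``); off-grid probes are an error.
    Slots with no observations are omitted (callers see the gap via
    ``bin_times_s``).
    """
    t = np.asarray(probe_times_s, dtype=float)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("probe_times_s and scores must have equal length")
    frac = (t - first_probe_s) / grid_s
    idx = np.round(frac).astype(int)
    if np.any(np.abs(frac - idx) > 1e-6) or np.any(idx < 0):
        bad = t[(np.abs(frac - idx) > 1e-6) | (idx < 0)][:5]
        raise ValueError(f"probe times off the {grid_s}-s grid: {bad}")
    slots = np.unique(idx)
    means = np.array([s[idx == k].mean() for k in slots])
    counts = np.array([(idx == k).sum() for k in slots])
    return BinSeries(
        movie_id=movie_id,
        component=component,
        bin_times_s=first_probe_s + grid_s * slots,
        bin_means=means,
        n_obs=counts,
    )


def interpolate_to_tr(
    bins: BinSeries,
    tr_s: float,
    section_start_s: float,
    section_end_s: float,
    kind: str = "linear",
) -> RegressorSeries:
    """Interpolate bin means to one value per TR over ``[section_start_s, section_end_s)``.

    Piecewise-linear between bin anchors with constant extrapolation beyond
    the first/last anchor (``kind="cubic"`` uses a natural cubic spline inside
    the anchored span, still flat outside it).
    """
    if len(bins.bin_times_s) < 2:
        raise ValueError("need at least 2 non-empty bins to interpolate")
    n = int(round((section_end_s - section_start_s) / tr_s))
    if n < 1:
        raise ValueError("empty section")
    t_out = section_start_s + tr_s * np.arange(n)
    xt, xv = bins.bin_times_s, bins.bin_means
    if kind == "linear":
        vals = np.interp(t_out, xt, xv)
    elif kind == "cubic":
        spl = CubicSpline(xt, xv, bc_type="natural")
        vals = spl(np.clip(t_out, xt[0], xt[-1]))
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    return RegressorSeries(
        movie_id=bins.movie_id,
        component=bins.component,
        tr_s=tr_s,
        start_s=section_start_s,
        values=vals,
    )
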