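"""Counterbalanced jittered probe-order design.

A cohort watching an 11-minute clip is sampled sparsely per person (5 probes,
one per 2-minute jitter window) but densely as a group: the 16 probe orders
tile every 15-s slot of the sampled span, each slot appearing in exactly two
orders (once in the first block of 8 mutually disjoint orders, once in the
second block, whose orders each overlap any single first-block order in at
most one probe time).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProbeSchedule",
    "DesignReport",
    "OrderAssignment",
    "InfeasibleDesignError",
    "slot_grid",
    "jitter_windows",
    "build_probe_orders",
    "assign_orders",
    "validate_design",
]


class InfeasibleDesignError(ValueError):
    """Raised when the requested design constraints cannot all be satisfied."""


@dataclass(frozen=True)
class ProbeSchedule:
    """One counterbalanced order of probe onset times for a clip."""

    order_id: int
    probe_times_s: tuple[float, ...]

    def __post_init__(self):
        times = tuple(float(t) for t in self.probe_times_s)
        object.__setattr__(self, "probe_times_s", times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"probe times must be strictly increasing: {times}")

    def __len__(self) -> int:
        return len(self.probe_times_s)


@dataclass
class DesignReport:
    """Validation summary for a set of probe schedules."""

    slot_coverage: dict[float, int]
    orders_per_slot_ok: bool
    disjoint_first_block: bool
    spacing_ok: bool
    expected_coverage: int

    @property
    def ok(self) -> bool:
        return self.orders_per_slot_ok and self.disjoint_first_block and self.spacing_ok


@dataclass(frozen=True)
class OrderAssignment:
    participant_id: str
    movie_id: str
    order_id: int


def slot_grid(clip_len_s: float, first_probe_s: float, grid_s: float) -> np.ndarray:
    """Legal probe slots: multiples of ``grid_s`` from ``first_probe_s``, closed at both ends."""
    if grid_s <= 0:
        raise InfeasibleDesignError("grid_s must be positive")
    if first_probe_s > clip_len_s:
        raise InfeasibleDesignError(
            f"first legal slot {first_probe_s} s lies beyond clip end {clip_len_s} s"
        )
    n = int(np.floor((clip_len_s - first_probe_s) / grid_s + 1e-9)) + 1
    return first_probe_s + grid_s * np.arange(n)


def jitter_windows(n_probes: int, first_probe_s: float, window_s: float) -> list[tuple[float, float]]:
    """Consecutive half-open jitter windows ``[start, start + window_s)`` beginning at the first legal slot."""
    return [
        (first_probe_s + j * window_s, first_probe_s + (j + 1) * window_s)
        for j in range(n_probes)
    ]


def _slots_by_window(slots: np.ndarray, windows: list[tuple[float, float]]) -> list[np.ndarray]:
    return [slots[(slots >= lo) & (slots < hi)] for lo, hi in windows]


def build_probe_orders(
    n_orders: int,
    n_probes: int,
    clip_len_s: float,
    first_probe_s: float,
    grid_s: float,
    window_s: float,
    seed: int,
) -> list[ProbeSchedule]:
    """Construct ``n_orders`` jittered probe schedules with the two-block overlap structure.

    The first ``n_orders // 2`` schedules are pairwise disjoint and, when each
    jitter window holds exactly ``n_orders // 2`` slots, their union is the
    full slot grid.  Each second-block schedule re-uses one first-block slot
    per window, drawn from ``n_probes`` *distinct* first-block orders, so any
    single pair of orders shares at most one probe time and every slot ends up
    covered exactly twice.

    Deterministic for a fixed ``seed``.
    """
    if n_orders < 1:
        raise InfeasibleDesignError("n_orders must be >= 1")
    if n_probes < 1:
        raise InfeasibleDesignError("n_probes must be >= 1")
    if window_s < grid_s:
        raise InfeasibleDesignError(
            f"jitter window ({window_s} s) narrower than slot grid ({grid_s} s)"
        )
    rng = np.random.default_rng(seed)
    slots = slot_grid(clip_len_s, first_probe_s, grid_s)
    windows = jitter_windows(n_probes, first_probe_s, window_s)
    per_window = _slots_by_window(slots, windows)

    if n_orders == 1:
        times = []
        for j, ws in enumerate(per_window):
            if len(ws) == 0:
                raise InfeasibleDesignError(f"jitter window {j + 1} contains no grid slot")
            times.append(float(rng.choice(ws)))
        return [ProbeSchedule(order_id=1, probe_times_s=tuple(times))]

    if n_orders % 2:
        raise InfeasibleDesignError(
            "two-block counterbalancing requires an even number of orders (or exactly 1)"
        )
    n_half = n_orders // 2
    if len(slots) < n_half * n_probes:
        raise InfeasibleDesignError(
            f"only {len(slots)} grid slots for {n_half} disjoint orders x {n_probes} probes"
        )
    for j, ws in enumerate(per_window):
        if len(ws) < n_half:
            raise InfeasibleDesignError(
                f"jitter window {j + 1} holds {len(ws)} slots; {n_half} disjoint orders need one each"
            )

    # First block: within each window, assign n_half slots to the n_half orders.
    first_block = np.empty((n_half, n_probes))
    for j, ws in enumerate(per_window):
        chosen = rng.choice(ws, size=n_half, replace=False)
        first_block[:, j] = chosen

    # Second block: order n_half + i takes, in window j, the slot of first-block
    # order (i + offset_j) mod n_half.  Distinct offsets keep the n_probes
    # first-block partners of each second-block order distinct.
    if n_probes <= n_half:
        offsets = rng.choice(n_half, size=n_probes, replace=False)
    else:  # degenerate small designs: partners must repeat
        offsets = rng.integers(0, n_half, size=n_probes)
    relabel = rng.permutation(n_half)
    second_block = np.empty_like(first_block)
    for j in range(n_probes):
        for i in range(n_half):
            second_block[i, j] = first_block[relabel[(i + offsets[j]) % n_half], j]

    schedules = [
        ProbeSchedule(order_id=i + 1, probe_times_s=tuple(sorted(first_block[i])))
        for i in range(n_half)
    ]
    schedules += [
        ProbeSchedule(order_id=n_half + i + 1, probe_times_s=tuple(sorted(second_block[i])))
        for i in range(n_half)
    ]
    return schedules


def assign_orders(
    participant_ids: list[str],
    schedules_per_movie: dict[str, list[ProbeSchedule]],
    seed: int,
) -> list[OrderAssignment]:
    """Assign each participant one distinct probe order per movie, balanced per (movie, order).

    Uses a cyclic Latin-rectangle construction: participant i (after a seeded
    shuffle) gets order ``tau[(i + c_m) % n_orders]`` for movie m, with
    distinct per-movie shifts ``c_m`` and a seeded relabelling ``tau``.  Within
    a participant the orders are therefore pairwise distinct and per
    (movie, order) cell counts differ by at most one.
    """
    movies = list(schedules_per_movie)
    n_orders_per_movie = {m: len(schedules_per_movie[m]) for m in movies}
    n_orders = min(n_orders_per_movie.values())
    if n_orders < len(movies):
        raise InfeasibleDesignError(
            f"{n_orders} orders cannot give {len(movies)} distinct orders per participant"
        )
    rng = np.random.default_rng(seed)
    participants = list(participant_ids)
    perm = rng.permutation(len(participants))
    tau = rng.permutation(n_orders)
    shifts = rng.choice(n_orders, size=len(movies), replace=False)

    order_ids = {m: [s.order_id for s in schedules_per_movie[m]] for m in movies}
    out = []
    for rank, p_idx in enumerate(perm):
        pid = participants[p_idx]
        for m_idx, m in enumerate(movies):
            k = int(tau[(rank + shifts[m_idx]) % n_orders])
            out.append(OrderAssignment(pid, m, order_ids[m][k]))
    out.sort(key=lambda a: (a.movie_id, str(a.participant_id)))
    return out


def validate_design(
    schedules: list[ProbeSchedule],
    expected_coverage: int | None = None,
    window_s: float | None = None,
    grid_s: float | None = None,
) -> DesignReport:
    """Check coverage, first-block disjointness and probe spacing; violations are reported, not raised."""
    if not schedules:
        raise ValueError("empty schedule list")
    counts: dict[float, int] = {}
    for s in schedules:
        for t in s.probe_times_s:
            counts[t] = counts.get(t, 0) + 1
    if expected_coverage is None:
        expected_coverage = 2 if len(schedules) >= 2 else 1
    orders_ok = all(c == expected_coverage for c in counts.values())

    n_half = max(1, len(schedules) // 2)
    first = [set(s.probe_times_s) for s in schedules[:n_half]]
    disjoint = all(
        not (a & b) for a, b in itertools.combinations(first, 2)
    ) if len(first) > 1 else True

    spacing_ok = True
    if window_s is not None:
        g = grid_s if grid_s is not None else 0.0
        lo, hi = g, 2 * window_s - g
        for s in schedules:
            gaps = np.diff(s.probe_times_s)
            if len(gaps) and (gaps.min() < lo - 1e-9 or gaps.max() > hi + 1e-9):
                spacing_ok = False
    return DesignReport(
        slot_coverage=dict(sorted(counts.items())),
        orders_per_slot_ok=orders_ok,
        disjoint_first_block=disjoint,
        spacing_ok=spacing_ok,
        expected_coverage=expected_coverage,
    )
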