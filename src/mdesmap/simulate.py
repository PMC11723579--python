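"""Synthetic study generator with known ground truth.

Emulates the full two-cohort design: smooth latent thought trajectories per
movie; probe-level item responses generated from planted loadings at each
participant's jittered probe times; parcel BOLD for an independent fMRI
cohort whose per-TR spatial maps couple to gradient-structured patterns as
the latents wax and wane; and comprehension scores with planted associations
to latent exposure.  Parcels live on a unit sphere (Fibonacci lattice) and
the gradient maps are low-order spherical harmonics — smooth, mutually
near-orthogonal maps with genuine spatial autocorrelation, so spin tests are
meaningfully exercised.

Every statistical assumption the analysis pipeline makes (participant random
intercepts, linear component-to-item map, linear component-to-gradient
coupling, additive Gaussian noise) is explicitly parameterised here so that
calibration and recovery suites can vary each one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .design import ProbeSchedule, assign_orders, build_probe_orders
from .statespace import GradientSet, ParcelTimeSeries
from .spin import SphereModel

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "StudyBundle",
    "default_loadings",
    "default_couplings",
    "fibonacci_sphere",
    "harmonic_gradients",
    "generate_latents",
    "generate_probe_responses",
    "generate_brain",
    "generate_comprehension",
    "generate_study",
]

ITEM_NAMES = (
    "past", "self", "knowledge", "future", "memory", "people",
    "intrusive", "distracting", "spontaneous", "unwanted", "repetitive",
    "words", "detail", "deliberate",
    "images", "sounds",
)

COMPONENT_NAMES = (
    "Episodic Knowledge",
    "Intrusive Distraction",
    "Verbal Detail",
    "Sensory Engagement",
)

MOVIE_IDS = ("citizenfour", "little_miss_sunshine", "500_days_of_summer")

# items per planted component: unequal blocks give well-separated eigenvalues,
# i.e. the strictly decreasing variance profile real mDES decompositions show
DEFAULT_BLOCK_SIZES = (6, 5, 3, 2)


def default_loadings(n_items: int = 16, n_components: int = 4,
                     block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES) -> np.ndarray:
    """Planted item loadings: orthogonal unit-norm blocks of unequal size."""
    if n_components != len(block_sizes) or sum(block_sizes) != n_items:
        block = n_items // n_components
        block_sizes = (block,) * (n_components - 1) + (n_items - block * (n_components - 1),)
    L = np.zeros((n_items, n_components))
    start = 0
    for k, size in enumerate(block_sizes):
        L[start:start + size, k] = 1.0
        start += size
    return L / np.linalg.norm(L, axis=0)


def default_couplings(n_components: int = 4, n_gradients: int = 5) -> np.ndarray:
    """Planted component-gradient couplings: Episodic Knowledge +0.5 on G4,
    Sensory Engagement -0.5 on G1 (directions of the study's two headline effects)."""
    C = np.zeros((n_components, n_gradients))
    C[0, 3] = 0.5
    C[3, 0] = -0.5
    return C


@dataclass
class StudyConfig:
    """Parameters of a synthetic study; defaults mirror the real design."""

    n_participants_mdes: int = 120
    n_subjects_fmri: int = 20
    movie_ids: tuple[str, ...] = MOVIE_IDS
    clip_len_s: float = 660.0
    tr_s: float = 1.0
    n_items: int = 16
    n_components: int = 4
    n_parcels: int = 400
    n_orders: int = 16
    n_probes: int = 5
    first_probe_s: float = 75.0
    grid_s: float = 15.0
    window_s: float = 120.0
    latent_smooth_sd_s: float = 30.0  # Gaussian kernel sd; autocorr(tau)=exp(-tau^2/(4 sd^2))
    item_mean: float = 5.5
    latent_scale: float = 2.0
    item_noise_sd: float = 0.5
    participant_sd: float = 0.5
    parcel_shared_noise_sd: float = 0.5
    parcel_subject_noise_sd: float = 1.0
    comprehension_base: float = 2.5
    comprehension_noise_sd: float = 0.8
    loadings: np.ndarray = field(default_factory=default_loadings)
    couplings: np.ndarray = field(default_factory=default_couplings)
    comprehension_effects: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -1.0, 0.0, 1.0])
    )
    seed: int = 0

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        self.comprehension_effects = np.asarray(self.comprehension_effects, dtype=float)
        for name in ("n_participants_mdes", "n_subjects_fmri", "n_items",
                     "n_components", "n_parcels", "n_orders", "n_probes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not np.isfinite(self.couplings).all():
            raise ValueError("couplings must be finite")

    @property
    def n_trs(self) -> int:
        return int(round(self.clip_len_s / self.tr_s))


@dataclass
class GroundTruth:
    latent_series: dict[str, np.ndarray]  # movie -> components x TR
    true_loadings: np.ndarray
    true_couplings: np.ndarray
    true_comprehension_effects: np.ndarray


@dataclass
class StudyBundle:
    config: StudyConfig
    schedules: dict[str, list[ProbeSchedule]]
    assignments: list
    responses: pd.DataFrame
    brain: dict[str, list[ParcelTimeSeries]]
    gradients: GradientSet
    sphere: SphereModel
    comprehension: pd.DataFrame
    ground_truth: GroundTruth


def fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def harmonic_gradients(coords: np.ndarray) -> np.ndarray:
    """Five low-order real spherical harmonics, standardised per map.

    On a near-uniform lattice the harmonics are pairwise near-orthogonal and
    spatially smooth, mimicking macroscale gradient maps.
    """
    x, y, z = coords.T
    maps = np.column_stack([z, x, 0.5 * (3 * z**2 - 1), x * z, x**2 - y**2])
    maps = maps - maps.mean(axis=0)
    return maps / maps.std(axis=0)


def generate_latents(config: StudyConfig, seed: int | None = None) -> dict[str, np.ndarray]:
    """Smooth standardised latent thought trajectories, one K x TR array per movie.

    White noise smoothed with a circular Gaussian kernel of sd
    ``latent_smooth_sd_s``; the model-implied autocorrelation is
    ``rho(tau) = exp(-tau^2 / (4 sd^2))``.  Zero smoothing yields white noise.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.n_trs
    sd_tr = config.latent_smooth_sd_s / config.tr_s
    out = {}
    for movie in config.movie_ids:
        raw = rng.standard_normal((config.n_components, T))
        if sd_tr > 0:
            raw = gaussian_filter1d(raw, sigma=sd_tr, axis=1, mode="wrap")
        raw = raw - raw.mean(axis=1, keepdims=True)
        # components are *dimensions* of experience: make the planted
        # trajectories exactly uncorrelated within each movie (a smooth
        # trajectory holds few effective samples, so raw sample correlations
        # would otherwise be large and the planted structure unidentifiable)
        if config.n_components > 1 and T > config.n_components:
            q, r = np.linalg.qr(raw.T)
            raw = (q * np.sign(np.diag(r))).T
        raw = raw - raw.mean(axis=1, keepdims=True)
        sds = raw.std(axis=1, keepdims=True)
        raw = raw / np.where(sds == 0, 1, sds)
        out[movie] = raw
    return out


def _latent_at(latents: np.ndarray, t_s: float, tr_s: float) -> np.ndarray:
    idx = min(int(round(t_s / tr_s)), latents.shape[1] - 1)
    return latents[:, idx]


def generate_probe_responses(
    latents: dict[str, np.ndarray],
    schedules: dict[str, list[ProbeSchedule]],
    assignments,
    config: StudyConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Item responses at each participant's assigned probe times.

    item = clip_to_[1,10]( item_mean + latent_scale * (L @ f(t)) + participant
    intercept + noise ).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    pids = sorted({a.participant_id for a in assignments})
    intercepts = dict(zip(pids, rng.normal(0, config.participant_sd, len(pids))))
    sched_by_key = {
        (m, s.order_id): s for m, ss in schedules.items() for s in ss
    }
    rows = []
    for a in assignments:
        sched = sched_by_key[(a.movie_id, a.order_id)]
        for t in sched.probe_times_s:
            f = _latent_at(latents[a.movie_id], t, config.tr_s)
            signal = config.item_mean + config.latent_scale * (config.loadings @ f)
            vals = signal + intercepts[a.participant_id] + rng.normal(
                0, config.item_noise_sd, config.n_items
            )
            vals = np.clip(vals, 1.0, 10.0)
            row = {
                "participant_id": a.participant_id,
                "movie_id": a.movie_id,
                "order_id": a.order_id,
                "probe_time_s": t,
            }
            row.update({f"item_{i + 1}": v for i, v in enumerate(vals)})
            rows.append(row)
    return pd.DataFrame(rows)


def generate_brain(
    latents: dict[str, np.ndarray],
    gradients: GradientSet,
    config: StudyConfig,
    seed: int | None = None,
) -> dict[str, list[ParcelTimeSeries]]:
    """Per-subject parcel x TR series: gradient-structured signal plus shared and subject noise."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    out: dict[str, list[ParcelTimeSeries]] = {}
    pattern = gradients.values @ config.couplings.T  # parcels x components
    for movie in config.movie_ids:
        signal = pattern @ latents[movie]  # parcels x TR
        shared = (
            rng.standard_normal(signal.shape) * config.parcel_shared_noise_sd
            if config.parcel_shared_noise_sd > 0
            else 0.0
        )
        subjects = []
        for s in range(config.n_subjects_fmri):
            noise = (
                rng.standard_normal(signal.shape) * config.parcel_subject_noise_sd
                if config.parcel_subject_noise_sd > 0
                else 0.0
            )
            subjects.append(
                ParcelTimeSeries(
                    subject_id=f"sub-{s + 1:02d}",
                    movie_id=movie,
                    data=signal + shared + noise,
                )
            )
        out[movie] = subjects
    return out


def generate_comprehension(
    latents: dict[str, np.ndarray],
    assignments,
    schedules: dict[str, list[ProbeSchedule]],
    config: StudyConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Comprehension scores (0-4) with planted linear effects of latent exposure.

    A participant's exposure to component k in a movie is the mean latent value
    at their probe times; the continuous score is base + effects . exposure +
    noise, rounded and clipped into {0..4}.
    """
    lookup = {(m, s.order_id): s for m, ss in schedules.items() for s in ss}
    return _comprehension_from_exposure(
        latents, assignments, lookup, config,
        seed=config.seed + 3 if seed is None else seed,
    )


def generate_study(config: StudyConfig, out_dir=None) -> StudyBundle:
    """Generate a complete synthetic study; optionally write it to disk via :mod:`mdesmap.io`."""
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)
    schedules = {
        m: build_probe_orders(
            config.n_orders, config.n_probes, config.clip_len_s,
            config.first_probe_s, config.grid_s, config.window_s,
            seed=int(seeds[0]) + i,
        )
        for i, m in enumerate(config.movie_ids)
    }
    participant_ids = [f"p{i + 1:03d}" for i in range(config.n_participants_mdes)]
    assignments = assign_orders(participant_ids, schedules, seed=int(seeds[1]))
    latents = generate_latents(config, seed=int(seeds[2]))
    responses = generate_probe_responses(latents, schedules, assignments, config,
                                         seed=int(seeds[3]))
    # one synthetic "hemisphere": the whole lattice rotates as a single sphere
    coords = fibonacci_sphere(config.n_parcels)
    sphere = SphereModel(coords=coords, hemisphere=np.full(config.n_parcels, "A"))
    gradients = GradientSet.from_values(harmonic_gradients(coords))
    brain = generate_brain(latents, gradients, config, seed=int(seeds[4]))
    comprehension = generate_comprehension(latents, assignments, schedules, config,
                                           seed=int(seeds[5]))
    bundle = StudyBundle(
        config=config,
        schedules=schedules,
        assignments=assignments,
        responses=responses,
        brain=brain,
        gradients=gradients,
        sphere=sphere,
        comprehension=comprehension,
        ground_truth=GroundTruth(
            latent_series=latents,
            true_loadings=config.loadings,
            true_couplings=config.couplings,
            true_comprehension_effects=config.comprehension_effects,
        ),
    )
    if out_dir is not None:
        from . import io as _io

        _io.write_study(bundle, out_dir)
    return bundle


def _comprehension_from_exposure(latents, assignments, schedule_lookup, config,
                                 seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for a in sorted(assignments, key=lambda a: (str(a.participant_id), a.movie_id)):
        sched = schedule_lookup[(a.movie_id, a.order_id)]
        exposure = np.mean(
            [_latent_at(latents[a.movie_id], t, config.tr_s) for t in sched.probe_times_s],
            axis=0,
        )
        cont = (
            config.comprehension_base
            + float(config.comprehension_effects @ exposure)
            + rng.normal(0, config.comprehension_noise_sd)
        )
        score = int(np.clip(np.round(cont), 0, 4))
        rows.append({"participant_id": a.participant_id, "movie_id": a.movie_id,
                     "score": score})
    return pd.DataFrame(rows)
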