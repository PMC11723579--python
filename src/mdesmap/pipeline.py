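"""End-to-end orchestration: design -> thought space -> regressors -> voxel
mapping -> state space -> behavioural models -> spin tests, from one config,
with a results manifest (seeds, parameters, output hashes)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import io as _io
from .models import (anova_across_bins, lmm_comprehension, lmm_gradient_thought,
                     lmm_thought_by_movie)
from .spin import spin_test
from .statespace import coords_at_probes, group_average_zscore, project_to_gradients
from .thought import ThoughtSpaceDecomposition, split_half_reliability
from .timeseries import bin_scores, interpolate_to_tr
from .voxelmap import (DEFAULT_ALPHA_FWE, DEFAULT_Z_THRESH, first_level_glm,
                       group_inference, summarize_clusters)

log = logging.getLogger("mdesmap")

ALL_STAGES = ("thoughtspace", "regressors", "statespace", "voxelmap", "models", "spin")


@dataclass
class PipelineConfig:
    study_dir: str
    out_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    n_components: int = 4
    n_boot: int = 200
    grid_s: float = 15.0
    first_probe_s: float = 75.0
    tr_s: float = 1.0
    section_start_s: float = 60.0
    window_s: float = 15.0
    z_thresh: float = DEFAULT_Z_THRESH
    n_perm: int = 1000
    spin_n_perm: int = 2500
    alpha_fwe: float = DEFAULT_ALPHA_FWE
    adjacency_k: int = 6
    seed: int = 0
    # (component, gradient index) pairs whose largest cluster is spin-tested;
    # defaults are the two brain-thought mappings singled out by the analysis
    spin_pairs: tuple = (("Sensory Engagement", 0), ("Episodic Knowledge", 3))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        payload["stages"] = tuple(payload.get("stages", ALL_STAGES))
        payload["spin_pairs"] = tuple(tuple(p) for p in payload.get(
            "spin_pairs", cls.spin_pairs))
        return cls(**payload)


def parcel_adjacency(coords: np.ndarray, k: int = 6) -> np.ndarray:
    """Symmetric k-nearest-neighbour edge list over parcel centroids."""
    tree = cKDTree(coords)
    _, nn = tree.query(coords, k=k + 1)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(nn) for j in row[1:]}
    return np.array(sorted(edges), dtype=int)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages_run": [],
        "outputs": {},
        "errors": None,
    }
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(x) for s, x in
                   zip(ALL_STAGES, rng.integers(0, 2**31 - 1, len(ALL_STAGES)))}
    manifest["stage_seeds"] = stage_seeds

    def record(stage: str, *paths: Path):
        manifest["stages_run"].append(stage)
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)

    try:
        study = _io.read_study(config.study_dir)
        responses = study["responses"]
        item_cols = [c for c in responses.columns if c.startswith("item_")]
        movies = sorted(responses["movie_id"].unique())
        section_end = config.section_start_s + _section_len(study, config)

        scores_df = None
        comp_names = None
        if "thoughtspace" in config.stages:
            log.info("stage thoughtspace")
            space = ThoughtSpaceDecomposition(
                n_components=config.n_components,
                component_names=_default_names(config.n_components),
            ).fit(responses[item_cols])
            rel = split_half_reliability(
                responses[item_cols], config.n_components,
                n_boot=config.n_boot, seed=stage_seeds["thoughtspace"],
            )
            _io.write_thought_space(space, out / "thought_space.json",
                                    out / "loadings.tsv")
            scores = space.transform(responses[item_cols])
            comp_names = space.component_names_
            scores_df = responses[["participant_id", "movie_id", "order_id",
                                   "probe_time_s"]].copy()
            for j, name in enumerate(comp_names):
                scores_df[name] = scores[:, j]
            scores_df.to_csv(out / "component_scores.tsv", sep="\t", index=False)
            (out / "reliability.json").write_text(json.dumps({
                "mean_similarity": rel.mean_similarity,
                "ci_low": rel.ci_low, "ci_high": rel.ci_high, "n_boot": rel.n_boot,
            }, indent=1))
            record("thoughtspace", out / "thought_space.json", out / "loadings.tsv",
                   out / "component_scores.tsv", out / "reliability.json")
        else:
            p = out / "component_scores.tsv"
            if not p.exists():
                raise RuntimeError(
                    "stage 'thoughtspace' disabled and no prior component_scores.tsv "
                    "found; downstream stages need it"
                )
            scores_df = pd.read_csv(p, sep="\t")
            comp_names = [c for c in scores_df.columns
                          if c not in ("participant_id", "movie_id", "order_id",
                                       "probe_time_s")]

        regressors = {}
        if "regressors" in config.stages or "voxelmap" in config.stages:
            log.info("stage regressors")
            rows = []
            for movie in movies:
                sub = scores_df[scores_df["movie_id"] == movie]
                regressors[movie] = []
                for name in comp_names:
                    bins = bin_scores(sub["probe_time_s"], sub[name],
                                      config.grid_s, config.first_probe_s,
                                      movie_id=movie, component=name)
                    reg = interpolate_to_tr(bins, config.tr_s,
                                            config.section_start_s, section_end)
                    regressors[movie].append(reg)
                    rows += [{"movie_id": movie, "component": name,
                              "time_s": t, "value": v}
                             for t, v in zip(reg.times_s, reg.values)]
            if "regressors" in config.stages:
                pd.DataFrame(rows).to_csv(out / "regressors.tsv", sep="\t", index=False)
                record("regressors", out / "regressors.tsv")

        probe_coords = None
        if "statespace" in config.stages:
            log.info("stage statespace")
            coord_paths = []
            pieces = []
            for movie in movies:
                group = group_average_zscore(study["brain"][movie])
                coords = project_to_gradients(group, study["gradients"],
                                              tr_s=config.tr_s)
                p = out / f"state_coords_{movie}.tsv"
                _io.write_state_coords(coords, p)
                coord_paths.append(p)
                sub = scores_df[scores_df["movie_id"] == movie]
                pc = coords_at_probes(coords, sub["probe_time_s"].to_numpy(),
                                      window_s=config.window_s)
                piece = sub.copy()
                for g in range(pc.shape[1]):
                    piece[f"g{g + 1}"] = pc[:, g]
                pieces.append(piece)
            probe_coords = pd.concat(pieces, ignore_index=True)
            probe_coords.to_csv(out / "probe_coords.tsv", sep="\t", index=False)
            record("statespace", *coord_paths, out / "probe_coords.tsv")

        stat_maps = {}
        betas_pooled = []
        if "voxelmap" in config.stages:
            log.info("stage voxelmap")
            # subject-level betas per movie, then averaged within subject across
            # movies so group inference pools the three clips
            per_subject: dict[str, list] = {}
            for movie in movies:
                for subj in study["brain"][movie]:
                    start = int(round(config.section_start_s / config.tr_s))
                    end = start + len(regressors[movie][0].values)
                    trimmed = type(subj)(subject_id=subj.subject_id,
                                         movie_id=movie,
                                         data=subj.data[:, start:end])
                    bm = first_level_glm(trimmed, regressors[movie])
                    per_subject.setdefault(subj.subject_id, []).append(bm)
            for sid, maps in sorted(per_subject.items()):
                pooled = maps[0]
                pooled.beta = np.mean([m.beta for m in maps], axis=0)
                pooled.movie_id = "pooled"
                betas_pooled.append(pooled)
            adjacency = parcel_adjacency(study["sphere"].coords, k=config.adjacency_k)
            cluster_rows = []
            for j, name in enumerate(comp_names):
                stat = group_inference(
                    betas_pooled, name, z_thresh=config.z_thresh,
                    n_perm=config.n_perm, adjacency=adjacency,
                    seed=stage_seeds["voxelmap"] + j, alpha_fwe=config.alpha_fwe,
                )
                summarize_clusters(stat, betas_pooled,
                                   seed=stage_seeds["voxelmap"] + 100 + j)
                stat_maps[name] = stat
                for cl in stat.clusters:
                    cluster_rows.append({
                        "component": name, "cluster_id": cl.cluster_id,
                        "sign": cl.sign, "n_units": len(cl.units),
                        "peak_unit": cl.peak_unit, "mass": cl.mass,
                        "p_cluster": cl.p_cluster,
                        "significant": cl.p_cluster <= config.alpha_fwe,
                        "mean_beta": cl.mean_beta, "ci_low": cl.ci_low,
                        "ci_high": cl.ci_high,
                        "units": ";".join(map(str, cl.units)),
                    })
            pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t",
                                              index=False)
            zmat = pd.DataFrame({n: s.z for n, s in stat_maps.items()})
            zmat.to_csv(out / "group_z.tsv", sep="\t", index=False)
            record("voxelmap", out / "clusters.tsv", out / "group_z.tsv")

        if "models" in config.stages:
            log.info("stage models")
            payload = {}
            payload["thought_by_movie"] = _jsonable(
                lmm_thought_by_movie(scores_df, comp_names))
            bins_idx = ((scores_df["probe_time_s"] - config.first_probe_s)
                        / config.grid_s).round().astype(int)
            sdf = scores_df.assign(bin_index=bins_idx)
            payload["anova_bins"] = {
                movie: {name: _jsonable(anova_across_bins(sdf, name, movie=movie))
                        for name in comp_names}
                for movie in movies
            }
            pattern_means = (scores_df
                             .groupby(["participant_id", "movie_id"])[comp_names]
                             .mean().reset_index())
            pattern_means.columns = (["participant_id", "movie_id"]
                                     + [f"pat_{j + 1}" for j in range(len(comp_names))])
            comp_df = study["comprehension"]
            payload["comprehension"] = _jsonable(lmm_comprehension(
                comp_df, pattern_means, [f"pat_{j + 1}" for j in range(len(comp_names))]))
            if probe_coords is None:
                p = out / "probe_coords.tsv"
                if p.exists():
                    probe_coords = pd.read_csv(p, sep="\t")
            if probe_coords is not None:
                payload["gradient_thought"] = _jsonable(
                    lmm_gradient_thought(probe_coords, comp_names))
            (out / "models.json").write_text(json.dumps(payload, indent=1))
            record("models", out / "models.json")

        if "spin" in config.stages:
            log.info("stage spin")
            results = {}
            for comp, g_idx in config.spin_pairs:
                if comp not in stat_maps:
                    continue
                sig = [c for c in stat_maps[comp].clusters
                       if c.p_cluster <= config.alpha_fwe]
                pool = sig if sig else stat_maps[comp].clusters
                if not pool:
                    results[comp] = {"note": "no cluster available"}
                    continue
                cl = max(pool, key=lambda c: c.mass)
                res = spin_test(
                    study["sphere"], study["gradients"].values[:, g_idx],
                    cl.units, n_perm=config.spin_n_perm,
                    seed=stage_seeds["spin"], mask=study["gradients"].mask,
                )
                results[comp] = {
                    "gradient": g_idx + 1, "observed": res.observed,
                    "p_two_tailed": res.p_two_tailed, "n_perm": res.n_perm,
                    "null_mean": float(res.null.mean()),
                    "cluster_significant": bool(sig),
                }
            (out / "spin.json").write_text(json.dumps(results, indent=1))
            record("spin", out / "spin.json")
    except Exception as exc:  # abort with stage context + partial manifest
        manifest["errors"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _section_len(study, config) -> float:
    any_movie = next(iter(study["brain"]))
    n_tr = study["brain"][any_movie][0].n_trs
    return n_tr * config.tr_s - config.section_start_s


def _default_names(k: int) -> list[str]:
    from .simulate import COMPONENT_NAMES

    if k <= len(COMPONENT_NAMES):
        return list(COMPONENT_NAMES[:k])
    return list(COMPONENT_NAMES) + [f"PCA_{j + 1}" for j in range(len(COMPONENT_NAMES), k)]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__}
    return obj
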