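"""Readers and writers for the study-directory layout.

All on-disk formats are plain text: long-format CSV for mDES responses and
comprehension, TSV for schedules, parcel series, gradients, sphere model and
state coordinates, JSON for the thought space and ground truth.  A 4-D NIfTI
loader is provided for volumetric use (optional nibabel dependency).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import OrderAssignment, ProbeSchedule
from .spin import SphereModel
from .statespace import GradientSet, ParcelTimeSeries, StateCoords
from .thought import ThoughtSpaceDecomposition

__all__ = [
    "write_schedules", "read_schedules",
    "write_assignments", "read_assignments",
    "write_mdes", "read_mdes",
    "write_parcel_series", "read_parcel_series",
    "write_gradients", "read_gradients",
    "write_sphere", "read_sphere",
    "write_state_coords", "read_state_coords",
    "write_thought_space", "read_thought_space",
    "write_study", "read_study",
    "load_nifti_timeseries",
]


def write_schedules(schedules: dict[str, list[ProbeSchedule]], path) -> None:
    rows = [
        {"movie_id": m, "order_id": s.order_id, "probe_index": i + 1, "time_s": t}
        for m, ss in schedules.items()
        for s in ss
        for i, t in enumerate(s.probe_times_s)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_schedules(path) -> dict[str, list[ProbeSchedule]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[ProbeSchedule]] = {}
    for (m, oid), grp in df.groupby(["movie_id", "order_id"]):
        grp = grp.sort_values("probe_index")
        out.setdefault(str(m), []).append(
            ProbeSchedule(order_id=int(oid), probe_times_s=tuple(grp["time_s"]))
        )
    for ss in out.values():
        ss.sort(key=lambda s: s.order_id)
    return out


def write_assignments(assignments: list[OrderAssignment], path) -> None:
    pd.DataFrame([vars(a) for a in assignments]).to_csv(path, sep="\t", index=False)


def read_assignments(path) -> list[OrderAssignment]:
    df = pd.read_csv(path, sep="\t")
    return [
        OrderAssignment(str(r.participant_id), str(r.movie_id), int(r.order_id))
        for r in df.itertuples()
    ]


def write_mdes(responses: pd.DataFrame, path) -> None:
    responses.to_csv(path, index=False)


def read_mdes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    items = [c for c in df.columns if c.startswith("item_")]
    bad = df[items].apply(lambda c: (c < 1) | (c > 10)).any().any()
    if bad:
        raise ValueError("item scores outside the 1-10 rating scale")
    return df


def write_parcel_series(series: ParcelTimeSeries, path) -> None:
    pd.DataFrame(series.data).to_csv(path, sep="\t", index=False, header=False)


def read_parcel_series(path, subject_id: str = "", movie_id: str = "",
                       zscored: bool = False) -> ParcelTimeSeries:
    data = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    return ParcelTimeSeries(subject_id=subject_id, movie_id=movie_id, data=data,
                            zscored=zscored)


def write_gradients(gradients: GradientSet, path) -> None:
    df = pd.DataFrame(gradients.values, columns=[f"g{i + 1}" for i in
                                                 range(gradients.n_gradients)])
    df.insert(0, "unit", np.arange(len(df)))
    df["mask"] = gradients.mask.astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_gradients(path) -> GradientSet:
    df = pd.read_csv(path, sep="\t")
    gcols = [c for c in df.columns if c.startswith("g")]
    return GradientSet(values=df[gcols].to_numpy(dtype=float),
                       mask=df["mask"].to_numpy(dtype=bool))


def write_sphere(sphere: SphereModel, path) -> None:
    df = pd.DataFrame(sphere.coords, columns=["x", "y", "z"])
    df.insert(0, "unit", np.arange(len(df)))
    df["hemisphere"] = sphere.hemisphere
    df.to_csv(path, sep="\t", index=False)


def read_sphere(path) -> SphereModel:
    df = pd.read_csv(path, sep="\t")
    return SphereModel(coords=df[["x", "y", "z"]].to_numpy(dtype=float),
                       hemisphere=df["hemisphere"].to_numpy())


def write_state_coords(coords: StateCoords, path) -> None:
    df = pd.DataFrame(coords.coords,
                      columns=[f"g{i + 1}" for i in range(coords.coords.shape[1])])
    df.insert(0, "time_s", coords.times_s)
    df.to_csv(path, sep="\t", index=False)


def read_state_coords(path, movie_id: str = "") -> StateCoords:
    df = pd.read_csv(path, sep="\t")
    gcols = [c for c in df.columns if c.startswith("g")]
    t = df["time_s"].to_numpy(dtype=float)
    tr = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return StateCoords(movie_id=movie_id, coords=df[gcols].to_numpy(dtype=float),
                       tr_s=tr, start_s=float(t[0]))


def write_thought_space(space: ThoughtSpaceDecomposition, json_path,
                        loadings_path=None) -> None:
    payload = {
        "n_components": space.n_components,
        "rotation": space.rotation,
        "component_names": space.component_names_,
        "item_names": space.item_names_,
        "item_means": space.item_means_.tolist(),
        "item_sds": space.item_sds_.tolist(),
        "eigenvalues": space.eigenvalues_.tolist(),
        "explained_variance_pct": space.explained_variance_pct_.tolist(),
        "loadings": space.loadings_.tolist(),
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))
    if loadings_path is not None:
        df = pd.DataFrame(space.loadings_, columns=space.component_names_)
        df.insert(0, "item", space.item_names_)
        df.to_csv(loadings_path, sep="\t", index=False)


def read_thought_space(json_path) -> ThoughtSpaceDecomposition:
    payload = json.loads(Path(json_path).read_text())
    space = ThoughtSpaceDecomposition(
        n_components=payload["n_components"], rotation=payload["rotation"]
    )
    space.item_names_ = payload["item_names"]
    space.item_means_ = np.array(payload["item_means"])
    space.item_sds_ = np.array(payload["item_sds"])
    space.eigenvalues_ = np.array(payload["eigenvalues"])
    space.explained_variance_pct_ = np.array(payload["explained_variance_pct"])
    space.loadings_ = np.array(payload["loadings"])
    space.component_names_ = payload["component_names"]
    return space


def write_study(bundle, out_dir) -> None:
    """Write a complete study directory in the pipeline's input formats."""
    out = Path(out_dir)
    (out / "brain").mkdir(parents=True, exist_ok=True)
    write_schedules(bundle.schedules, out / "schedules.tsv")
    write_assignments(bundle.assignments, out / "assignments.tsv")
    write_mdes(bundle.responses, out / "mdes.csv")
    write_gradients(bundle.gradients, out / "gradients.tsv")
    write_sphere(bundle.sphere, out / "sphere.tsv")
    bundle.comprehension.to_csv(out / "comprehension.csv", index=False)
    for movie, subjects in bundle.brain.items():
        for s in subjects:
            write_parcel_series(s, out / "brain" / f"{s.subject_id}_{movie}.tsv")
    gt = bundle.ground_truth
    payload = {
        "latent_series": {m: v.tolist() for m, v in gt.latent_series.items()},
        "true_loadings": gt.true_loadings.tolist(),
        "true_couplings": gt.true_couplings.tolist(),
        "true_comprehension_effects": gt.true_comprehension_effects.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))


def read_study(in_dir):
    """Load a study directory back into a :class:`~mdesmap.simulate.StudyBundle`-like dict."""
    from .simulate import GroundTruth

    d = Path(in_dir)
    schedules = read_schedules(d / "schedules.tsv")
    assignments = read_assignments(d / "assignments.tsv")
    responses = read_mdes(d / "mdes.csv")
    gradients = read_gradients(d / "gradients.tsv")
    sphere = read_sphere(d / "sphere.tsv")
    comprehension = pd.read_csv(d / "comprehension.csv")
    brain: dict[str, list[ParcelTimeSeries]] = {}
    for f in sorted((d / "brain").glob("*.tsv")):
        sub, movie = f.stem.split("_", 1)
        brain.setdefault(movie, []).append(
            read_parcel_series(f, subject_id=sub, movie_id=movie)
        )
    gt = None
    gt_path = d / "ground_truth.json"
    if gt_path.exists():
        payload = json.loads(gt_path.read_text())
        gt = GroundTruth(
            latent_series={m: np.array(v) for m, v in payload["latent_series"].items()},
            true_loadings=np.array(payload["true_loadings"]),
            true_couplings=np.array(payload["true_couplings"]),
            true_comprehension_effects=np.array(payload["true_comprehension_effects"]),
        )
    return {
        "schedules": schedules,
        "assignments": assignments,
        "responses": responses,
        "gradients": gradients,
        "sphere": sphere,
        "comprehension": comprehension,
        "brain": brain,
        "ground_truth": gt,
    }


def load_nifti_timeseries(bold_path, mask_path, subject_id: str = "",
                          movie_id: str = "") -> ParcelTimeSeries:
    """Load a 4-D NIfTI volume as a voxels-in-mask x TR series (requires nibabel)."""
    import nibabel as nib

    img = nib.load(str(bold_path))
    mask = nib.load(str(mask_path)).get_fdata() > 0
    data = img.get_fdata()[mask]  # voxels x TR
    return ParcelTimeSeries(subject_id=subject_id, movie_id=movie_id, data=data)
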