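"""CSV / YAML interchange for trajectories, labels, changepoints, datasets.

All tables are plain CSV with 0-based frame indices and pixel units:

* trajectories: ``traj_id,frame,x,y``
* labels:       ``traj_id,frame,alpha,K,state``
* changepoints: ``traj_id,cp_frame``
* predictions:  ``traj_id,frame,alpha_hat,logK_hat,state_hat``

The dataset manifest is YAML listing the file paths, the split membership
of every trajectory, the seed and the recipe.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import LabelSeries, Trajectory

__all__ = [
    "trajectories_to_frame",
    "frame_to_trajectories",
    "labels_to_frame",
    "frame_to_labels",
    "changepoints_to_frame",
    "write_dataset",
    "read_dataset",
]


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    parts = [
        pd.DataFrame(
            {"traj_id": t.traj_id, "frame": np.arange(len(t)), "x": t.x, "y": t.y}
        )
        for t in trajectories
    ]
    return pd.concat(parts, ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    _require(df, ["traj_id", "frame", "x", "y"])
    out = []
    for tid, g in df.groupby("traj_id", sort=False):
        g = g.sort_values("frame")
        if not np.array_equal(g["frame"].to_numpy(), np.arange(len(g))):
            raise ValueError(f"trajectory {tid!r}: frames must be 0..T-1 without gaps")
        out.append(Trajectory(str(tid), g["x"].to_numpy(), g["y"].to_numpy()))
    return out


def labels_to_frame(ids: list[str], labels: list[LabelSeries]) -> pd.DataFrame:
    parts = [
        pd.DataFrame(
            {
                "traj_id": tid,
                "frame": np.arange(len(lab)),
                "alpha": lab.alpha,
                "K": lab.K,
                "state": lab.state,
            }
        )
        for tid, lab in zip(ids, labels)
    ]
    return pd.concat(parts, ignore_index=True)


def frame_to_labels(df: pd.DataFrame, cps: pd.DataFrame | None = None) -> dict[str, LabelSeries]:
    _require(df, ["traj_id", "frame", "alpha", "K", "state"])
    cp_map: dict[str, np.ndarray] = {}
    if cps is not None and len(cps):
        _require(cps, ["traj_id", "cp_frame"])
        for tid, g in cps.groupby("traj_id", sort=False):
            cp_map[str(tid)] = np.sort(g["cp_frame"].to_numpy().astype(int))
    out = {}
    for tid, g in df.groupby("traj_id", sort=False):
        g = g.sort_values("frame")
        out[str(tid)] = LabelSeries(
            g["alpha"].to_numpy(),
            g["K"].to_numpy(),
            g["state"].to_numpy().astype(int),
            cp_map.get(str(tid), np.array([], dtype=int)),
        )
    return out


def changepoints_to_frame(ids: list[str], cps: list[np.ndarray]) -> pd.DataFrame:
    rows = [
        {"traj_id": tid, "cp_frame": int(c)} for tid, arr in zip(ids, cps) for c in arr
    ]
    return pd.DataFrame(rows, columns=["traj_id", "cp_frame"])


def write_dataset(dataset: dict, outdir: str | Path) -> Path:
    """Write a ``build_dataset`` result as CSV files plus a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = [t.traj_id for t in dataset["trajectories"]]
    trajectories_to_frame(dataset["trajectories"]).to_csv(
        outdir / "trajectories.csv", index=False
    )
    labels_to_frame(ids, dataset["labels"]).to_csv(outdir / "labels.csv", index=False)
    changepoints_to_frame(ids, [l.changepoints for l in dataset["labels"]]).to_csv(
        outdir / "changepoints.csv", index=False
    )
    manifest = dict(dataset["manifest"])
    manifest["files"] = {
        "trajectories": "trajectories.csv",
        "labels": "labels.csv",
        "changepoints": "changepoints.csv",
    }
    manifest["split"] = {tid: str(s) for tid, s in zip(ids, dataset["split"])}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir / "manifest.yaml"


def read_dataset(manifest_path: str | Path) -> dict:
    """Read a dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    traj_df = pd.read_csv(base / manifest["files"]["trajectories"])
    lab_df = pd.read_csv(base / manifest["files"]["labels"])
    cp_df = pd.read_csv(base / manifest["files"]["changepoints"])
    trajectories = frame_to_trajectories(traj_df)
    label_map = frame_to_labels(lab_df, cp_df)
    labels = [label_map[t.traj_id] for t in trajectories]
    split = np.array([manifest["split"][t.traj_id] for t in trajectories], dtype=object)
    return {
        "trajectories": trajectories,
        "labels": labels,
        "split": split,
        "manifest": manifest,
    }


def _require(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
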