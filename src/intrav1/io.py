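"""Plain-text readers and writers.

A subject bundle is a directory with one tab-delimited BOLD matrix
(time x vertex) and one confound matrix per run, a vertex table, and a JSON
sidecar holding the TR, seed and block schedule.  Fixation tables follow
the de facto eye-tracker export shape (participant, trial, condition,
onset_ms, duration_ms, x_px, y_px).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import RunData, SubjectDataset
from .design import BlockSchedule
from .retinotopy import RetinotopicMap

_FMT = "%.8g"


def write_matrix(path: Path, matrix: np.ndarray) -> None:
    np.savetxt(path, matrix, fmt=_FMT, delimiter="\t")


def read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def vertex_table(rmap: RetinotopicMap) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "vertex_id": rmap.vertex_id,
            "hemisphere": rmap.hemisphere,
            "vf_x": rmap.vf_x,
            "vf_y": rmap.vf_y,
            "eccentricity": rmap.eccentricity,
            "quadrant": rmap.quadrant,
        }
    )


def write_vertex_table(path: Path, rmap: RetinotopicMap) -> None:
    vertex_table(rmap).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_vertex_table(path: Path) -> RetinotopicMap:
    df = pd.read_csv(path, sep="\t")
    return RetinotopicMap(
        vertex_id=df["vertex_id"].to_numpy(),
        hemisphere=df["hemisphere"].to_numpy(dtype=object),
        vf_x=df["vf_x"].to_numpy(),
        vf_y=df["vf_y"].to_numpy(),
        max_ecc=float(np.ceil(df["eccentricity"].max())),
    )


def write_subject_bundle(ds: SubjectDataset, outdir: Path) -> Path:
    outdir = Path(outdir) / ds.subject_id
    outdir.mkdir(parents=True, exist_ok=True)
    run_files = []
    for r, run in enumerate(ds.runs):
        bold_file = f"run-{r:02d}_bold.tsv"
        conf_file = f"run-{r:02d}_confounds.tsv"
        write_matrix(outdir / bold_file, run.bold)
        write_matrix(outdir / conf_file, run.confounds)
        run_files.append({"bold": bold_file, "confounds": conf_file, "tr": run.tr})
    write_vertex_table(outdir / "vertices.tsv", ds.rmap)
    sidecar = {
        "subject_id": ds.subject_id,
        "seed": ds.seed,
        "schedule": ds.schedule.to_dict(),
        "runs": run_files,
        "n_confounds": int(ds.runs[0].confounds.shape[1]),
    }
    (outdir / "subject.json").write_text(json.dumps(sidecar, indent=1))
    return outdir


def read_subject_bundle(bundle_dir: Path) -> SubjectDataset:
    bundle_dir = Path(bundle_dir)
    sidecar = json.loads((bundle_dir / "subject.json").read_text())
    schedule = BlockSchedule.from_dict(sidecar["schedule"])
    rmap = read_vertex_table(bundle_dir / "vertices.tsv")
    runs = [
        RunData(
            bold=read_matrix(bundle_dir / spec["bold"]),
            tr=float(spec["tr"]),
            confounds=read_matrix(bundle_dir / spec["confounds"]),
        )
        for spec in sidecar["runs"]
    ]
    return SubjectDataset(
        subject_id=sidecar["subject_id"],
        runs=runs,
        schedule=schedule,
        rmap=rmap,
        seed=int(sidecar["seed"]),
    )


def write_edge_table(path: Path, partition, median_map=None,
                     local_edges=None, global_edges=None) -> None:
    """Edge-level TSV: endpoints, sub-network, optional weight and flags."""
    df = pd.DataFrame(
        {
            "edge_id": np.arange(partition.n_edges),
            "vertex_i": partition.edge_i,
            "vertex_j": partition.edge_j,
            "subnetwork": partition.labels,
        }
    )
    if median_map is not None:
        df["median_weight"] = median_map
        flags = np.array([""] * partition.n_edges, dtype=object)
        if local_edges is not None:
            flags[np.asarray(local_edges, dtype=int)] = "Local"
        if global_edges is not None:
            flags[np.asarray(global_edges, dtype=int)] = "Global"
        df["supported_level"] = flags
        df["significant"] = flags != ""
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_fixations(path: Path, rows: pd.DataFrame) -> None:
    cols = ["participant", "trial", "condition", "onset_ms", "duration_ms",
            "x_px", "y_px"]
    rows[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_fixations(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def trajectories_to_frame(
    per_trial: dict[tuple[str, int, str], "object"],
) -> pd.DataFrame:
    """Flatten {(participant, trial, condition): GazeTrajectory} to rows."""
    records = []
    for (participant, trial, condition), traj in per_trial.items():
        for x, y, dur, onset in zip(
            traj.x_px, traj.y_px, traj.duration_ms, traj.onset_ms
        ):
            records.append(
                {
                    "participant": participant,
                    "trial": trial,
                    "condition": condition,
                    "onset_ms": onset,
                    "duration_ms": dur,
                    "x_px": x,
                    "y_px": y,
                }
            )
    return pd.DataFrame.from_records(records)
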