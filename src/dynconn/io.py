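"""Delimited-text readers and writers for every pipeline artifact.

All artifacts are plain TSV or JSON: per-subject time-course matrices
(T rows x R components with a header of component names), the phenotype
table, ground-truth latent labels, per-subject windowed connectivity,
centroid matrices, and structured reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import GroundTruth, SubjectRecord, config_to_dict
from .windows import WindowedConnectivity


def component_names(n_components: int) -> list[str]:
    return [f"comp{i:02d}" for i in range(n_components)]


def pair_names(pairs: list[tuple[int, int]]) -> list[str]:
    return [f"comp{i:02d}_comp{j:02d}" for i, j in pairs]


def write_timecourses(path: Path, timecourses: np.ndarray) -> None:
    df = pd.DataFrame(timecourses, columns=component_names(timecourses.shape[1]))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timecourses(path: Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_cohort(
    out_dir: Path,
    subjects: list[SubjectRecord],
    phenotypes: pd.DataFrame,
    truth: GroundTruth | None = None,
    config=None,
) -> None:
    out_dir = Path(out_dir)
    tc_dir = out_dir / "timecourses"
    tc_dir.mkdir(parents=True, exist_ok=True)
    for subj in subjects:
        write_timecourses(tc_dir / f"{subj.subject_id}.tsv", subj.timecourses)
    phenotypes.to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)
    if truth is not None:
        rows = []
        for sid, labels in truth.labels.items():
            for t, s in enumerate(labels):
                rows.append((sid, t, int(s)))
        pd.DataFrame(rows, columns=["subject_id", "timepoint", "state"]).to_csv(
            out_dir / "ground_truth_labels.tsv", sep="\t", index=False
        )
    if config is not None:
        (out_dir / "cohort_config.yaml").write_text(
            yaml.safe_dump(config_to_dict(config), sort_keys=False)
        )


def read_cohort_dir(cohort_dir: Path) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Load (timecourses by subject, phenotype table) from a cohort directory."""
    cohort_dir = Path(cohort_dir)
    phenotypes = pd.read_csv(cohort_dir / "phenotypes.tsv", sep="\t")
    tc = {
        sid: read_timecourses(cohort_dir / "timecourses" / f"{sid}.tsv")
        for sid in phenotypes["subject_id"]
    }
    return tc, phenotypes


def read_ground_truth_labels(path: Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {
        sid: grp.sort_values("timepoint")["state"].to_numpy()
        for sid, grp in df.groupby("subject_id")
    }


def write_windowed(path: Path, wc: WindowedConnectivity) -> None:
    df = pd.DataFrame(wc.vectors, columns=pair_names(wc.pair_index))
    df.insert(0, "window_start", wc.window_starts)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_windowed(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (window_starts, W x P vectors)."""
    df = pd.read_csv(path, sep="\t")
    return df["window_start"].to_numpy(), df.drop(columns="window_start").to_numpy()


def write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
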