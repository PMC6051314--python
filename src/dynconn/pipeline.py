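"""End-to-end orchestration of the dynamic-connectivity pipeline.

Stages: (optional) cohort simulation -> band-pass filtering -> windowed /
static connectivity -> state decomposition -> per-state group statistics
-> per-state and nested LS-SVM classification -> bootstrap comparison of
dynamic vs static classifiers.  Stages communicate through written TSV /
JSON artifacts plus in-memory containers, so any stage can be rerun from
the previous stage's outputs; a manifest records every output with a
configuration hash for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, io, states, stats
from .cohort import CohortConfig, generate_cohort
from .filtering import FilterSpec, bandpass
from .windows import TaperSpec, compute_dfnc, compute_sfnc, pair_index

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full run configuration with defaults mirroring the study constants."""

    output_dir: str = "results/run"
    #: directory with per-subject time-course TSVs + phenotypes.tsv;
    #: None -> simulate a cohort first
    cohort_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    taper: TaperSpec = field(default_factory=TaperSpec)
    #: pin the number of states; None -> elbow selection over k_range
    k: int | None = None
    k_range: tuple = states.DEFAULT_K_RANGE
    kmeans_replicates: int = 10
    clustering_seed: int = 0
    bootstrap_seed: int = 0
    thresholds: tuple = classify.DEFAULT_THRESHOLDS
    C: float = 0.1
    alpha: float = 0.05
    n_boot: int = 10_000
    fisher_z: bool = False
    l1_kmeans: bool = False
    #: "inner" (strict no-leakage) or "outer" feature-selection t-values
    leakage_mode: str = "inner"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("cohort", CohortConfig), ("filter", FilterSpec), ("taper", TaperSpec)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return yaml.safe_load(yaml.safe_dump(d, default_flow_style=False))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def validate_inputs(cohort_dir: str | Path) -> dict:
    """Machine-readable sanity report on a cohort directory.

    Checks that every subject's matrix has the same shape, that phenotypes
    are complete, and that group labels are binary; failures are carried
    in the report rather than raised.
    """
    issues = []
    cohort_dir = Path(cohort_dir)
    try:
        timecourses, phenotypes = io.read_cohort_dir(cohort_dir)
    except Exception as exc:  # unreadable layout is itself the finding
        return {"issues": [f"cannot read cohort directory: {exc}"], "ok": False}
    shapes = {sid: tc.shape for sid, tc in timecourses.items()}
    ref = next(iter(shapes.values()))
    for sid, shape in shapes.items():
        if shape != ref:
            issues.append(f"{sid}: matrix shape {shape} != {ref}")
        if not np.isfinite(timecourses[sid]).all():
            issues.append(f"{sid}: non-finite values")
    groups = set(phenotypes["group"])
    if not groups <= {"control", "patient"}:
        issues.append(f"unexpected group labels: {sorted(groups)}")
    for col in ("subject_id", "group", "sex", "age", "edu", "wtar"):
        if col not in phenotypes.columns:
            issues.append(f"phenotype column missing: {col} (dependent stages disabled)")
        elif phenotypes[col].isna().any():
            bad = phenotypes.loc[phenotypes[col].isna(), "subject_id"].tolist()
            issues.append(f"missing {col} for {bad} (regression stage will be disabled)")
    return {"issues": issues, "ok": not issues, "n_subjects": len(shapes), "shape": list(ref)}


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Deterministic (byte-identical outputs) for fixed seeds; any stage
    failure aborts with the stage name and cause.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    stage = "simulate"
    try:
        if config.cohort_dir is None:
            subjects, phenotypes, truth = generate_cohort(config.cohort)
            cohort_out = out / "cohort"
            io.write_cohort(cohort_out, subjects, phenotypes, truth, config.cohort)
            timecourses = {s.subject_id: s.timecourses for s in subjects}
            manifest["stages"][stage] = str(cohort_out)
        else:
            timecourses, phenotypes = io.read_cohort_dir(config.cohort_dir)
            manifest["stages"][stage] = f"loaded:{config.cohort_dir}"

        stage = "filter"
        filtered = {sid: bandpass(tc, config.filter) for sid, tc in timecourses.items()}
        manifest["stages"][stage] = "in-memory"

        stage = "dfnc"
        dfnc_dir = out / "dfnc"
        dfnc_dir.mkdir(exist_ok=True)
        vectors = {}
        sfnc_rows = {}
        for sid, tc in filtered.items():
            wc = compute_dfnc(tc, config.taper, subject_id=sid)
            io.write_windowed(dfnc_dir / f"{sid}.tsv", wc)
            vectors[sid] = wc.vectors
            sfnc_rows[sid] = compute_sfnc(tc)
        n_comp = next(iter(filtered.values())).shape[1]
        pairs = pair_index(n_comp)
        sfnc_df = pd.DataFrame(
            np.vstack([sfnc_rows[sid] for sid in sfnc_rows]),
            index=list(sfnc_rows),
            columns=io.pair_names(pairs),
        )
        sfnc_df.to_csv(out / "sfnc.tsv", sep="\t", float_format="%.8g")
        manifest["stages"][stage] = str(dfnc_dir)

        stage = "states"
        model = states.fit_state_model(
            vectors,
            k=config.k,
            k_range=tuple(config.k_range),
            seed=config.clustering_seed,
            n_replicates=config.kmeans_replicates,
            metric="l1" if config.l1_kmeans else "euclidean",
            fisher_z=config.fisher_z,
        )
        states_dir = out / "states"
        states_dir.mkdir(exist_ok=True)
        for s in range(model.k):
            pd.DataFrame(
                model.centroids[s][None, :], columns=io.pair_names(pairs)
            ).to_csv(states_dir / f"centroid_state{s + 1}.tsv", sep="\t", index=False)
        label_rows = []
        for sid, lab in model.labels.items():
            for w, s in enumerate(lab):
                label_rows.append((sid, w, int(s)))
        pd.DataFrame(label_rows, columns=["subject_id", "window_start", "state"]).to_csv(
            states_dir / "window_labels.tsv", sep="\t", index=False
        )
        io.write_json(
            states_dir / "state_report.json",
            {
                "k": model.k,
                "k_source": model.k_source if config.k is None else "pinned",
                "occupancy": model.occupancy,
                "subject_counts": model.subject_counts,
                "validity_curve": {str(k): v for k, v in model.validity_curve.items()},
            },
        )
        manifest["stages"][stage] = str(states_dir)

        stage = "group_stats"
        stats_dir = out / "group_stats"
        stats_dir.mkdir(exist_ok=True)
        results = stats.statewise_group_diff(model, phenotypes, alpha=config.alpha)
        for res in results:
            pd.DataFrame(
                {
                    "pair": io.pair_names(pairs),
                    "t_value": res.t_values,
                    "p_value": res.p_values,
                    "fdr_significant": res.fdr_mask,
                }
            ).to_csv(stats_dir / f"state{res.state + 1}_ttests.tsv", sep="\t", index=False)
        rosters = {"all": phenotypes["subject_id"].tolist()}
        for s in range(model.k):
            rosters[f"state{s + 1}"] = model.roster(s)
        stats.demographics_table(phenotypes, rosters).to_csv(
            stats_dir / "demographics.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = str(stats_dir)

        stage = "classify"
        clf_dir = out / "classification"
        clf_dir.mkdir(exist_ok=True)
        labels = {
            row.subject_id: (1 if row.group == "patient" else -1)
            for row in phenotypes.itertuples()
        }
        state_feats = {}
        for s in range(model.k):
            roster = model.roster(s)
            state_feats[s] = (
                roster,
                np.vstack([model.subject_state_means[sid][s] for sid in roster]),
            )
        dfnc_report = classify.nested_loocv(
            state_feats,
            labels,
            thresholds=tuple(config.thresholds),
            C=config.C,
            t_mode=config.leakage_mode,
        )
        sfnc_report = classify.sfnc_nested_loocv(
            sfnc_df.to_numpy(),
            list(sfnc_df.index),
            labels,
            thresholds=tuple(config.thresholds),
            C=config.C,
            t_mode=config.leakage_mode,
        )
        for name, rep in (("dfnc", dfnc_report), ("sfnc", sfnc_report)):
            io.write_json(
                clf_dir / f"{name}_cv_report.json",
                {
                    "per_state_auc": {str(k): v for k, v in rep.per_state_auc.items()},
                    "overall_auc": rep.overall_auc,
                    "selection_histogram": {
                        f"state{s + 1}|tau={tau}": n
                        for (s, tau), n in rep.selection_histogram.items()
                    },
                    "excluded": rep.excluded,
                },
            )
            pd.DataFrame(rep.per_fold_choice).to_csv(
                clf_dir / f"{name}_fold_choices.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                [(sid, sc, lab) for sid, (sc, lab) in rep.pooled_scores.items()],
                columns=["subject_id", "score", "label"],
            ).to_csv(clf_dir / f"{name}_scores.tsv", sep="\t", index=False)
        manifest["stages"][stage] = str(clf_dir)

        stage = "compare"
        comp = classify.bootstrap_compare(
            dfnc_report, sfnc_report, n_boot=config.n_boot, seed=config.bootstrap_seed
        )
        io.write_json(
            out / "bootstrap_comparison.json",
            {
                "t": comp["t"],
                "df": comp["df"],
                "p": comp["p"],
                "dfnc_mean_auc": float(comp["auc_samples_a"].mean()),
                "sfnc_mean_auc": float(comp["auc_samples_b"].mean()),
                "dfnc_sd": float(comp["auc_samples_a"].std(ddof=1)),
                "sfnc_sd": float(comp["auc_samples_b"].std(ddof=1)),
                "n_boot": config.n_boot,
            },
        )
        manifest["stages"][stage] = str(out / "bootstrap_comparison.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    io.write_json(out / "manifest.json", manifest)
    return out
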