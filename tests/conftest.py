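"""Shared fixtures: a tiny cohort for unit tests and the study-scale runs.

The study-scale fixtures reproduce the emulated study conditions
(96 subjects, 48 components, 145 timepoints, K = 4 states) once per
session; acceptance-level property tests all read from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from dynconn.cohort import CohortConfig, generate_cohort
from dynconn.filtering import FilterSpec, bandpass
from dynconn.windows import TaperSpec, compute_dfnc, compute_sfnc, make_taper, pair_index
from dynconn.states import (
    StateModel,
    best_permutation_accuracy,
    fit_state_model,
    windowed_majority_labels,
)
from dynconn.stats import statewise_group_diff
from dynconn.classify import loocv_state_auc, nested_loocv


@dataclass
class PipelineRun:
    """Everything downstream tests need from one simulated cohort run."""

    config: CohortConfig
    phenotypes: object
    truth: object
    windowed: dict[str, np.ndarray]
    window_starts: dict[str, np.ndarray]
    sfnc: dict[str, np.ndarray]
    model: StateModel
    labels: dict[str, int]
    group_stats: list
    state_aucs: dict[int, float]
    window_accuracy: float
    cluster_to_latent: dict[int, int]
    effect_pair_cols: list[int]


def _run_pipeline(config: CohortConfig, k=None, seed=0) -> PipelineRun:
    subjects, phenotypes, truth = generate_cohort(config)
    fspec = FilterSpec(tr_seconds=config.tr_seconds)
    tspec = TaperSpec()
    taper = make_taper(tspec)
    windowed, starts, sfnc = {}, {}, {}
    for subj in subjects:
        filtered = bandpass(subj.timecourses, fspec)
        wc = compute_dfnc(filtered, tspec, subj.subject_id)
        windowed[subj.subject_id] = wc.vectors
        starts[subj.subject_id] = wc.window_starts
        sfnc[subj.subject_id] = compute_sfnc(filtered)
    model = fit_state_model(windowed, k=k, seed=seed)
    truth_w = np.concatenate(
        [
            windowed_majority_labels(truth.labels[sid], starts[sid], taper)
            for sid in windowed
        ]
    )
    pred_w = np.concatenate([model.labels[sid] for sid in windowed])
    n_match = max(model.k, config.n_states)
    accuracy, mapping = best_permutation_accuracy(truth_w, pred_w, n_match)
    labels = {
        row.subject_id: (1 if row.group == "patient" else -1)
        for row in phenotypes.itertuples()
    }
    group_stats = statewise_group_diff(model, phenotypes)
    state_aucs = {}
    for s in range(model.k):
        roster = model.roster(s)
        x = np.vstack([model.subject_state_means[sid][s] for sid in roster])
        y = np.array([labels[sid] for sid in roster], dtype=float)
        state_aucs[s], _ = loocv_state_auc(x, y)
    pairs = pair_index(config.n_components)
    pcol = {p: i for i, p in enumerate(pairs)}
    effect_cols = [pcol[p] for p in config.resolved_effect_pairs()]
    return PipelineRun(
        config=config,
        phenotypes=phenotypes,
        truth=truth,
        windowed=windowed,
        window_starts=starts,
        sfnc=sfnc,
        model=model,
        labels=labels,
        group_stats=group_stats,
        state_aucs=state_aucs,
        window_accuracy=accuracy,
        cluster_to_latent=mapping,
        effect_pair_cols=effect_cols,
    )


def state_feature_dict(run: PipelineRun) -> dict[int, tuple[list[str], np.ndarray]]:
    out = {}
    for s in range(run.model.k):
        roster = run.model.roster(s)
        out[s] = (
            roster,
            np.vstack([run.model.subject_state_means[sid][s] for sid in roster]),
        )
    return out


@pytest.fixture(scope="session")
def tiny_run() -> PipelineRun:
    """Small cohort (16 subjects, 12 components) with the effect injected."""
    config = CohortConfig(
        n_per_group=8,
        n_components=12,
        n_timepoints=120,
        n_states=3,
        dwell_mean=40,
        seed=3,
    )
    return _run_pipeline(config, k=3)


@pytest.fixture(scope="session")
def study_run() -> PipelineRun:
    """Study-scale effect cohort with elbow-selected k (expensive; shared)."""
    return _run_pipeline(CohortConfig(seed=0), k=None)


@pytest.fixture(scope="session")
def null_run() -> PipelineRun:
    """Study-scale cohort with the group effect removed, k pinned at the
    generative number of states."""
    return _run_pipeline(CohortConfig(effect_delta=0.0, seed=0), k=4)


@pytest.fixture(scope="session")
def study_nested(study_run):
    """Nested LOOCV report on the study cohort (expensive; shared)."""
    return nested_loocv(state_feature_dict(study_run), study_run.labels)
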