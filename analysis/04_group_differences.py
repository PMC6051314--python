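#!/usr/bin/env python
"""Per-state patient-vs-control statistics with FDR control.

Rebuilds each subject's representative state matrices from the saved
window labels, runs the 1128 pooled two-sample t-tests per state with
Benjamini-Hochberg correction (within-state family), writes the per-state
t/p tables, the state-wise demographics table, and an OLS covariate
regression (sex, age, edu, WTAR) for every FDR-significant pair.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dynconn import io
from dynconn.states import StateModel, summarize_states
from dynconn.stats import covariate_regression, demographics_table, statewise_group_diff
from dynconn.windows import pair_index

DFNC = Path("results/dfnc")
STATES = Path("results/states")
OUT = Path("results/group_stats")


def load_model() -> tuple[StateModel, dict]:
    labels_df = pd.read_csv(STATES / "window_labels.tsv", sep="\t")
    vectors, labels = {}, {}
    for sid, grp in labels_df.groupby("subject_id"):
        _, vecs = io.read_windowed(DFNC / f"{sid}.tsv")
        vectors[sid] = vecs
        labels[sid] = grp.sort_values("window_start")["state"].to_numpy()
    k = int(labels_df["state"].max()) + 1
    centroids = np.vstack(
        [
            pd.read_csv(STATES / f"centroid_state{s + 1}.tsv", sep="\t").to_numpy()
            for s in range(k)
        ]
    )
    occupancy, counts, means = summarize_states(vectors, labels, k)
    model = StateModel(
        k=k,
        centroids=centroids,
        labels=labels,
        occupancy=occupancy,
        subject_counts=counts,
        subject_state_means=means,
    )
    return model, vectors


def main() -> None:
    model, _ = load_model()
    phenotypes = pd.read_csv(Path("results/cohort") / "phenotypes.tsv", sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)
    n_comp = int((1 + (1 + 8 * model.centroids.shape[1]) ** 0.5) / 2)
    names = io.pair_names(pair_index(n_comp))
    results = statewise_group_diff(model, phenotypes)
    regression_rows = []
    for res in results:
        pd.DataFrame(
            {
                "pair": names,
                "t_value": res.t_values,
                "p_value": res.p_values,
                "fdr_significant": res.fdr_mask,
            }
        ).to_csv(OUT / f"state{res.state + 1}_ttests.tsv", sep="\t", index=False)
        n_sig = int(res.fdr_mask.sum())
        print(
            f"state {res.state + 1}: {res.n_hc} HC / {res.n_mtbi} mTBI, "
            f"{n_sig} FDR-significant pair(s)"
        )
        roster = model.roster(res.state)
        sub_phen = phenotypes.set_index("subject_id").loc[roster].reset_index()
        for col in np.flatnonzero(res.fdr_mask):
            values = np.array(
                [model.subject_state_means[sid][res.state][col] for sid in roster]
            )
            betas, pvals = covariate_regression(values, sub_phen)
            regression_rows.append(
                {
                    "state": res.state + 1,
                    "pair": names[col],
                    "t_value": res.t_values[col],
                    **{f"beta_{c}": betas[c] for c in ("sex", "age", "edu", "wtar")},
                    **{f"p_{c}": pvals[c] for c in ("sex", "age", "edu", "wtar")},
                }
            )
    if regression_rows:
        pd.DataFrame(regression_rows).to_csv(
            OUT / "significant_pair_regression.tsv", sep="\t", index=False
        )
    rosters = {"all": phenotypes["subject_id"].tolist()}
    for s in range(model.k):
        rosters[f"state{s + 1}"] = model.roster(s)
    demographics_table(phenotypes, rosters).to_csv(
        OUT / "demographics.tsv", sep="\t", index=False
    )
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
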