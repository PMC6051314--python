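#!/usr/bin/env python
"""State-aware LS-SVM classification with nested leave-one-out selection.

Computes one plain-LOOCV AUC per state (all 1128 features), then the
nested LOOCV with joint (state, |t|-threshold) selection, and the same
nested procedure on static FNC; writes per-fold choices, the selection
histogram, pooled decision scores, and the AUC summary.
"""

import importlib.util
import json
from pathlib import Path

import numpy as np
import pandas as pd

from dynconn.classify import loocv_state_auc, nested_loocv, sfnc_nested_loocv

_spec = importlib.util.spec_from_file_location(
    "group_diffs", Path(__file__).with_name("04_group_differences.py")
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)

OUT = Path("results/classification")


def main() -> None:
    model, _ = _mod.load_model()
    phenotypes = pd.read_csv(Path("results/cohort") / "phenotypes.tsv", sep="\t")
    labels = {
        row.subject_id: (1 if row.group == "patient" else -1)
        for row in phenotypes.itertuples()
    }
    OUT.mkdir(parents=True, exist_ok=True)
    feats = {}
    summary = {}
    for s in range(model.k):
        roster = model.roster(s)
        x = np.vstack([model.subject_state_means[sid][s] for sid in roster])
        feats[s] = (roster, x)
        y = np.array([labels[sid] for sid in roster], dtype=float)
        auc, mean_w = loocv_state_auc(x, y)
        summary[f"state{s + 1}_auc"] = round(auc, 4)
        np.savetxt(OUT / f"state{s + 1}_mean_weights.tsv", mean_w[None, :], delimiter="\t")
        print(f"state {s + 1}: LOOCV AUC = {auc:.3f} (n = {len(roster)})")

    nested = nested_loocv(feats, labels)
    sfnc = pd.read_csv(Path("results") / "sfnc.tsv", sep="\t", index_col=0)
    sfnc_report = sfnc_nested_loocv(sfnc.to_numpy(), list(sfnc.index), labels)
    summary["nested_overall_auc"] = round(nested.overall_auc, 4)
    summary["sfnc_overall_auc"] = round(sfnc_report.overall_auc, 4)
    print(f"nested dFNC AUC = {nested.overall_auc:.3f}")
    print(f"nested sFNC AUC = {sfnc_report.overall_auc:.3f}")

    for name, rep in (("dfnc", nested), ("sfnc", sfnc_report)):
        pd.DataFrame(rep.per_fold_choice).to_csv(
            OUT / f"{name}_fold_choices.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [(sid, sc, lab) for sid, (sc, lab) in rep.pooled_scores.items()],
            columns=["subject_id", "score", "label"],
        ).to_csv(OUT / f"{name}_scores.tsv", sep="\t", index=False)
    hist = pd.DataFrame(
        [
            {"state": s + 1, "threshold": tau, "times_selected": n}
            for (s, tau), n in sorted(nested.selection_histogram.items())
        ]
    )
    hist.to_csv(OUT / "selection_histogram.tsv", sep="\t", index=False)
    (OUT / "auc_summary.json").write_text(json.dumps(summary, indent=2))
    print(hist.to_string(index=False))


if __name__ == "__main__":
    main()
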