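#!/usr/bin/env python
"""Cluster all windowed connectivity vectors into dynamic states.

Pools every subject's windows, selects the number of states by the elbow
of the cluster validity index over k = 2..9, fits k-means, and writes
centroids, per-window state labels, occupancy rates and subject counts.
"""

import json
from pathlib import Path

import pandas as pd

from dynconn import io
from dynconn.states import fit_state_model
from dynconn.windows import pair_index

DFNC = Path("results/dfnc")
OUT = Path("results/states")


def main() -> None:
    vectors = {}
    for path in sorted(DFNC.glob("*.tsv")):
        _, vecs = io.read_windowed(path)
        vectors[path.stem] = vecs
    model = fit_state_model(vectors, k=None, seed=0)
    OUT.mkdir(parents=True, exist_ok=True)
    n_pairs = model.centroids.shape[1]
    n_comp = int((1 + (1 + 8 * n_pairs) ** 0.5) / 2)
    names = io.pair_names(pair_index(n_comp))
    for s in range(model.k):
        pd.DataFrame(model.centroids[s][None, :], columns=names).to_csv(
            OUT / f"centroid_state{s + 1}.tsv", sep="\t", index=False
        )
    rows = [
        (sid, w, int(state))
        for sid, lab in model.labels.items()
        for w, state in enumerate(lab)
    ]
    pd.DataFrame(rows, columns=["subject_id", "window_start", "state"]).to_csv(
        OUT / "window_labels.tsv", sep="\t", index=False
    )
    report = {
        "k": model.k,
        "k_source": model.k_source,
        "validity_curve": {str(k): v for k, v in model.validity_curve.items()},
        "occupancy": model.occupancy.tolist(),
        "subject_counts": model.subject_counts.tolist(),
    }
    (OUT / "state_report.json").write_text(json.dumps(report, indent=2))
    print(f"selected k = {model.k} ({model.k_source})")
    print("occupancy:", [round(o, 3) for o in model.occupancy])
    print("subjects per state:", model.subject_counts.tolist())


if __name__ == "__main__":
    main()
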