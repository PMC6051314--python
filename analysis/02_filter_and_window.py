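#!/usr/bin/env python
"""Band-pass filter the time courses and compute windowed + static FNC.

Applies the fifth-order Butterworth band-pass [0.01, 0.15] Hz (zero phase)
and the tapered sliding-window correlation (15-TR rectangle convolved with
a sigma = 3 TR Gaussian, stride 1), writing one windowed-connectivity TSV
per subject plus the subjects x pairs static-FNC table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dynconn import io
from dynconn.filtering import FilterSpec, bandpass
from dynconn.windows import TaperSpec, compute_dfnc, compute_sfnc, make_taper, pair_index

COHORT = Path("results/cohort")
OUT = Path("results/dfnc")


def main() -> None:
    timecourses, phenotypes = io.read_cohort_dir(COHORT)
    OUT.mkdir(parents=True, exist_ok=True)
    fspec, tspec = FilterSpec(), TaperSpec()
    taper = make_taper(tspec)
    sfnc_rows = {}
    for sid, tc in timecourses.items():
        filtered = bandpass(tc, fspec)
        wc = compute_dfnc(filtered, tspec, sid)
        io.write_windowed(OUT / f"{sid}.tsv", wc)
        sfnc_rows[sid] = compute_sfnc(filtered)
    n_comp = next(iter(timecourses.values())).shape[1]
    pairs = pair_index(n_comp)
    sfnc = pd.DataFrame(
        np.vstack(list(sfnc_rows.values())),
        index=list(sfnc_rows),
        columns=io.pair_names(pairs),
    )
    sfnc.to_csv(Path("results") / "sfnc.tsv", sep="\t", float_format="%.8g")
    w = len(next(iter(timecourses.values()))) - len(taper) + 1
    print(
        f"taper length {len(taper)} TRs -> {w} windows x {len(pairs)} pairs "
        f"for {len(timecourses)} subjects"
    )


if __name__ == "__main__":
    main()
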