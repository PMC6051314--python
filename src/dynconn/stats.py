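"""Group statistics: mass-univariate t-tests with FDR, demographics, regression.

Within each connectivity state, every component pair's representative
connectivity is compared between patients and controls with a
pooled-variance two-sample t-test (sign convention: patient minus
control), using only the subjects who visited the state; p-values are
Benjamini-Hochberg corrected within the state's family of R(R-1)/2 tests.
Demographic-table helpers reproduce the usual cohort table (two-sample t
for continuous variables, Fisher's exact test for sex), and an OLS
covariate regression (sex, age, education, WTAR) is available for any
connectivity pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GroupStatsResult:
    """Per-state mass-univariate comparison with its FDR mask."""

    state: int
    t_values: np.ndarray
    p_values: np.ndarray
    fdr_mask: np.ndarray
    alpha: float
    n_hc: int
    n_mtbi: int
    tested: bool = True


def _pooled_t(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (m2 - m1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sided t-test; t is signed mean(b) - mean(a).

    With a = controls and b = patients the sign matches the usual
    "patient minus control" table convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    return _pooled_t(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))


def two_sample_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance t from printed summary statistics (t = m2 - m1 signed)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    return _pooled_t(m1, s1, n1, m2, s2, n2)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p (point-probability method)."""
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (tab < 0).any() or not np.issubdtype(tab.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    _, p = sps.fisher_exact(tab, alternative="two-sided")
    return float(min(p, 1.0))


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (significance mask, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    mask, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return mask, adjusted


def pooled_t_vector(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled two-sample t over feature columns (t = mean_b - mean_a).

    Features with zero pooled variance get t = 0, p = 1 (logged), so the
    mass-univariate maps stay finite.
    """
    na, nb = len(xa), len(xb)
    df = na + nb - 2
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va, vb = xa.var(axis=0, ddof=1), xb.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    bad = sp2 <= 0
    if bad.any():
        logger.warning("%d features with zero pooled variance; t set to 0", bad.sum())
        sp2 = np.where(bad, 1.0, sp2)
    t = (mb - ma) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[bad] = 0.0
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p


def statewise_group_diff(
    state_model,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
) -> list[GroupStatsResult]:
    """Mass-univariate patient-vs-control comparison within each state.

    Uses only subjects who visited the state; FDR is applied within each
    state's family separately.  States with fewer than two subjects per
    group are reported untested.
    """
    group_of = dict(zip(phenotypes["subject_id"], phenotypes["group"]))
    results = []
    n_pairs = state_model.centroids.shape[1]
    for s in range(state_model.k):
        roster = state_model.roster(s)
        hc = [sid for sid in roster if group_of[sid] == "control"]
        pt = [sid for sid in roster if group_of[sid] == "patient"]
        if len(hc) < 2 or len(pt) < 2:
            logger.warning("state %d untested: %d HC / %d patients", s, len(hc), len(pt))
            results.append(
                GroupStatsResult(
                    state=s,
                    t_values=np.full(n_pairs, np.nan),
                    p_values=np.full(n_pairs, np.nan),
                    fdr_mask=np.zeros(n_pairs, dtype=bool),
                    alpha=alpha,
                    n_hc=len(hc),
                    n_mtbi=len(pt),
                    tested=False,
                )
            )
            continue
        xa = np.vstack([state_model.subject_state_means[sid][s] for sid in hc])
        xb = np.vstack([state_model.subject_state_means[sid][s] for sid in pt])
        t, p = pooled_t_vector(xa, xb)
        mask, _ = fdr_bh(p, alpha=alpha)
        results.append(
            GroupStatsResult(
                state=s,
                t_values=t,
                p_values=p,
                fdr_mask=mask,
                alpha=alpha,
                n_hc=len(hc),
                n_mtbi=len(pt),
            )
        )
    return results


COVARIATES = ("sex", "age", "edu", "wtar")


def covariate_regression(
    pair_values: np.ndarray, phenotypes: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """OLS of one pair's connectivity on intercept + sex + age + edu + WTAR.

    ``pair_values`` must align with the phenotype table rows.  Returns
    per-coefficient estimates and two-sided t-test p-values.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    if phenotypes[list(COVARIATES)].isna().any().any():
        raise ValueError("missing covariates")
    design = pd.DataFrame(
        {
            "const": 1.0,
            "sex": (phenotypes["sex"] == "M").astype(float).to_numpy(),
            "age": phenotypes["age"].to_numpy(dtype=float),
            "edu": phenotypes["edu"].to_numpy(dtype=float),
            "wtar": phenotypes["wtar"].to_numpy(dtype=float),
        }
    )
    x = design.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = [
            col
            for i, col in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = OLS(np.asarray(pair_values, dtype=float), x).fit()
    betas = pd.Series(fit.params, index=design.columns)
    pvals = pd.Series(fit.pvalues, index=design.columns)
    return betas, pvals


def demographics_table(
    phenotypes: pd.DataFrame, rosters: dict[str, list[str]]
) -> pd.DataFrame:
    """Cohort demographic comparisons, overall and per state roster.

    For each roster ("all" plus one per state): Fisher's exact test on the
    sex table and pooled two-sample t-tests (patient minus control) on
    age, education and WTAR.
    """
    rows = []
    for name, roster in rosters.items():
        sub = phenotypes[phenotypes["subject_id"].isin(roster)]
        hc = sub[sub["group"] == "control"]
        pt = sub[sub["group"] == "patient"]
        sex_table = np.array(
            [
                [(hc["sex"] == "M").sum(), (hc["sex"] == "F").sum()],
                [(pt["sex"] == "M").sum(), (pt["sex"] == "F").sum()],
            ],
            dtype=int,
        )
        rows.append(
            {
                "roster": name,
                "variable": "sex",
                "hc_summary": f"M={sex_table[0,0]} F={sex_table[0,1]}",
                "mtbi_summary": f"M={sex_table[1,0]} F={sex_table[1,1]}",
                "t_value": np.nan,
                "p_value": fisher_exact_2x2(sex_table),
            }
        )
        for var in ("age", "edu", "wtar"):
            t, p = two_sample_t(hc[var].to_numpy(), pt[var].to_numpy())
            rows.append(
                {
                    "roster": name,
                    "variable": var,
                    "hc_summary": f"{hc[var].mean():.2f} ({hc[var].std(ddof=1):.2f})",
                    "mtbi_summary": f"{pt[var].mean():.2f} ({pt[var].std(ddof=1):.2f})",
                    "t_value": t,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
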