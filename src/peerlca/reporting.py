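"""Descriptive surfaces: cohort summaries, class profiles, distributions.

Reports are pure functions of saved fit artifacts and cohort tables: class
profiles centred on the overall (mixing-weighted) mean per indicator, class
prevalences overall vs among peer supporters, within-class supporter rates,
and per-school class-by-supporter breakdowns with zero-supporter flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ALL_COLUMNS, BINARY_COLUMNS, CONTINUOUS_COLUMNS
from .lca import FitResult

SUMMARY_CONTINUOUS = list(CONTINUOUS_COLUMNS) + ["fas"]
SUMMARY_BINARY = list(BINARY_COLUMNS) + ["fsm"]


def cohort_summary(cohort: pd.DataFrame,
                   supporter_flags: np.ndarray | None = None) -> pd.DataFrame:
    """Mean (SD) for continuous and % for binary variables, whole sample vs
    peer supporters. With zero supporters the supporter column is missing."""
    if supporter_flags is None:
        supporter_flags = cohort["supporter"].fillna(0).astype(bool).to_numpy()
    supporter_flags = np.asarray(supporter_flags, dtype=bool)
    groups = {"all": cohort, "supporters": cohort.loc[supporter_flags]}
    rows = []
    for var in SUMMARY_CONTINUOUS:
        if var not in cohort.columns:
            continue
        row = {"variable": var, "kind": "continuous"}
        for name, grp in groups.items():
            vals = grp[var].astype(float)
            row[f"{name}_mean"] = vals.mean() if len(grp) else np.nan
            row[f"{name}_sd"] = vals.std(ddof=1) if len(grp) > 1 else (
                0.0 if len(grp) == 1 else np.nan)
        rows.append(row)
    for var in SUMMARY_BINARY:
        if var not in cohort.columns:
            continue
        row = {"variable": var, "kind": "binary"}
        for name, grp in groups.items():
            vals = grp[var].astype(float)
            row[f"{name}_mean"] = vals.mean() if len(grp) else np.nan
            row[f"{name}_sd"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["n_all"] = len(cohort)
    out["n_supporters"] = int(supporter_flags.sum())
    return out


def profile_table(fit: FitResult, columns=ALL_COLUMNS) -> pd.DataFrame:
    """Per (class, indicator): class mean, overall mean and centred value.

    Class means come from the model parameters (Bernoulli probabilities for
    binary indicators); the overall mean is the mixing-weighted class mean,
    so centred values have mixing-weighted sum zero per indicator.
    """
    params = fit.params
    class_means = np.hstack([params.means, params.probs])  # (K, 12)
    overall = params.mixing @ class_means
    rows = []
    for k in range(params.n_classes):
        for j, col in enumerate(columns):
            rows.append({
                "class": k + 1,
                "indicator": col,
                "class_mean": class_means[k, j],
                "overall_mean": overall[j],
                "centered": class_means[k, j] - overall[j],
                "mixing": params.mixing[k],
            })
    return pd.DataFrame(rows)


def class_distribution(fit: FitResult, supporter_flags: np.ndarray,
                       bch_weight_matrix: np.ndarray | None = None) -> dict:
    """Class shares overall, among supporters, and within-class supporter rates.

    Uses BCH weights when given (classification-error corrected), modal
    counts otherwise; the method used is recorded in the result.
    """
    y = np.asarray(supporter_flags, dtype=float)
    k = fit.params.n_classes
    if bch_weight_matrix is not None:
        w = np.asarray(bch_weight_matrix, dtype=float)
        method = "bch"
    else:
        w = np.zeros((len(y), k))
        w[np.arange(len(y)), fit.modal] = 1.0
        method = "modal"
    overall = np.asarray(fit.params.mixing, dtype=float)
    sup_mass = w.T @ y                      # weighted supporters per class
    total_sup = sup_mass.sum()
    supporter_share = (np.clip(sup_mass, 0, None) /
                       np.clip(sup_mass, 0, None).sum()
                       if total_sup > 0 else np.full(k, np.nan))
    class_mass = w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        within_rate = np.clip(sup_mass / class_mass, 0.0, 1.0)
    return {
        "overall_share": overall,
        "supporter_share": supporter_share,
        "within_class_supporter_rate": within_rate,
        "method": method,
    }


def school_breakdown(modal: np.ndarray, school_ids: np.ndarray,
                     supporter_flags: np.ndarray) -> pd.DataFrame:
    """Per (school, class): modal pupil count, supporter count, zero flag."""
    df = pd.DataFrame({
        "school_id": np.asarray(school_ids),
        "class": np.asarray(modal) + 1,
        "supporter": np.asarray(supporter_flags, dtype=bool),
    })
    k = int(df["class"].max())
    grid = pd.MultiIndex.from_product(
        [sorted(df["school_id"].unique()), range(1, k + 1)],
        names=["school_id", "class"])
    counts = df.groupby(["school_id", "class"]).agg(
        n_pupils=("supporter", "size"),
        n_supporters=("supporter", "sum"),
    ).reindex(grid, fill_value=0).reset_index()
    counts["zero_supporters"] = counts["n_supporters"] == 0
    return counts


def schools_without_supporters(breakdown: pd.DataFrame) -> pd.Series:
    """Per class: number of schools with zero supporters from that class."""
    return breakdown.groupby("class")["zero_supporters"].sum()
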