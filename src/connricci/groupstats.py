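"""Group-comparison statistics.

Two procedures compare the young and old groups:

* **global**: for each global measure (and each average edge curvature), a
  two-tailed two-sample t-test at every grid density, with Benjamini-Hochberg
  FDR applied across the densities within that measure;
* **node-level**: the per-subject summary of a node is the area under its
  node-curvature-versus-density curve (trapezoidal AUC over the grid); a
  two-tailed two-sample t-test per ROI, with BH-FDR across all ROIs within a
  curvature method.

Significance is called at FDR-adjusted p < alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .construct import DensityGrid

ALPHA = 0.05


def two_sample_ttest(x, y, equal_var: bool = True):
    """Two-tailed two-sample t-test; pooled variance by default (Welch with
    ``equal_var=False``). Returns (t, p).

    A degenerate comparison (zero variance in both samples) yields (0, 1)
    when the means agree and raises when they differ, since no finite t
    statistic exists.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values cannot be FDR-adjusted")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def node_auc(values, grid: DensityGrid) -> float:
    """Trapezoidal area under a per-density curve, density on the x-axis."""
    values = np.asarray(values, float)
    if values.size != len(grid):
        raise ValueError("one value per grid density required")
    return float(np.trapezoid(values, x=np.asarray(grid.densities)))


def node_auc_table(node_curves: pd.DataFrame, grid: DensityGrid) -> pd.DataFrame:
    """Collapse a per-density node-curvature table to per-subject AUCs.

    ``node_curves`` columns: subject_id, method, roi, density, value.
    Returns columns: subject_id, method, roi, auc.
    """
    densities = list(grid.densities)
    rows = []
    for (sid, method, roi), sub in node_curves.groupby(
            ["subject_id", "method", "roi"], sort=True):
        sub = sub.set_index("density")["value"]
        if len(sub) != len(densities):
            raise ValueError(
                f"subject {sid} roi {roi}: {len(sub)} densities, "
                f"expected {len(densities)}")
        vals = sub.loc[densities].to_numpy()
        rows.append({"subject_id": sid, "method": method, "roi": roi,
                     "auc": node_auc(vals, grid)})
    return pd.DataFrame(rows)


def _direction(mean_old, mean_young) -> str:
    return "old_higher" if mean_old >= mean_young else "young_higher"


def compare_global(records: pd.DataFrame, manifest: pd.DataFrame,
                   alpha: float = ALPHA, equal_var: bool = True
                   ) -> pd.DataFrame:
    """Density-wise group comparison of global measures.

    ``records`` columns: subject_id, density, plus one column per measure.
    FDR family: the grid densities within one measure.
    """
    groups = manifest.set_index("subject_id")["group"]
    merged = records.merge(groups.rename("group"), left_on="subject_id",
                           right_index=True, how="left")
    if merged["group"].isna().any():
        bad = merged.loc[merged["group"].isna(), "subject_id"].iloc[0]
        raise ValueError(f"subject {bad} missing from manifest")
    measures = [c for c in records.columns
                if c not in ("subject_id", "density")]
    n_densities = merged["density"].nunique()
    counts = merged.groupby("subject_id")["density"].nunique()
    if counts.nunique() > 1 or counts.iloc[0] != n_densities:
        bad = counts.idxmin()
        raise ValueError(f"subject {bad} missing densities")
    out = []
    for measure in measures:
        rows = []
        for density, sub in merged.groupby("density", sort=True):
            x = sub.loc[sub["group"] == "old", measure].dropna()
            y = sub.loc[sub["group"] == "young", measure].dropna()
            t, p = two_sample_ttest(x, y, equal_var=equal_var)
            rows.append({"measure": measure, "density": density,
                         "t_stat": t, "p_raw": p,
                         "direction": _direction(x.mean(), y.mean())})
        sub = pd.DataFrame(rows)
        sub["p_fdr"] = bh_fdr(sub["p_raw"])
        sub["significant"] = sub["p_fdr"] < alpha
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def compare_nodes(auc: pd.DataFrame, manifest: pd.DataFrame,
                  alpha: float = ALPHA, equal_var: bool = True
                  ) -> pd.DataFrame:
    """ROI-level group comparison of node-curvature AUCs.

    ``auc`` columns: subject_id, method, roi, auc. One t-test per ROI;
    FDR family: all ROIs within a method. Returns one row per ROI x method
    with t, raw and adjusted p, direction and the significance call.
    """
    groups = manifest.set_index("subject_id")["group"]
    merged = auc.merge(groups.rename("group"), left_on="subject_id",
                       right_index=True, how="left")
    if merged["group"].isna().any():
        bad = merged.loc[merged["group"].isna(), "subject_id"].iloc[0]
        raise ValueError(f"subject {bad} missing from manifest")
    out = []
    for method, msub in merged.groupby("method", sort=True):
        n_subj = msub["subject_id"].nunique()
        rows = []
        for roi, sub in msub.groupby("roi", sort=True):
            if len(sub) != n_subj:
                raise ValueError(f"roi {roi}: incomplete AUC table")
            x = sub.loc[sub["group"] == "old", "auc"]
            y = sub.loc[sub["group"] == "young", "auc"]
            t, p = two_sample_ttest(x, y, equal_var=equal_var)
            rows.append({"method": method, "roi": roi, "t_stat": t,
                         "p_raw": p,
                         "direction": _direction(x.mean(), y.mean())})
        sub = pd.DataFrame(rows)
        sub["p_fdr"] = bh_fdr(sub["p_raw"])
        sub["significant"] = sub["p_fdr"] < alpha
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def significant_rois(node_comparison: pd.DataFrame, method: str) -> list:
    """ROIs called significant for one curvature method, sorted."""
    sub = node_comparison[(node_comparison["method"] == method)
                          & node_comparison["significant"]]
    return sorted(sub["roi"])
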