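"""Correlation of node curvature with phenotype scores.

For each significant ROI (within a chosen RSN) and each subscore of each
behavioral test, the Spearman rank correlation between the ROI's
node-curvature AUC and the subscore is computed across subjects. Spearman is
used because behavioral scores are often ordinal. BH-FDR is applied within
each test, across ALL (ROI x subscore) pairs of that test — e.g. 10 ROIs and
10 subscores form one 100-value family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .groupstats import ALPHA, bh_fdr


def spearman(x, y):
    """Spearman rank correlation with mid-ranks for ties; two-sided p via the
    t approximation. Raises on constant input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlate_curvature_phenotypes(auc: pd.DataFrame, sig_rois,
                                   phenotypes: pd.DataFrame, method: str,
                                   alpha: float = ALPHA,
                                   group_manifest: pd.DataFrame | None = None,
                                   groups=None) -> pd.DataFrame:
    """Spearman correlations of node-curvature AUC against every subscore.

    Parameters
    ----------
    auc : DataFrame with columns subject_id, method, roi, auc.
    sig_rois : iterable of ROI ids to correlate (significant ROIs in an RSN).
    phenotypes : tidy DataFrame with subject_id, test, subscore, value.
    method : "frc" or "orc".
    group_manifest, groups : optionally restrict to subjects whose manifest
        group is in ``groups`` (default: all subjects pooled).

    Returns one row per (roi, test, subscore) with rho, p_raw, p_fdr, n and
    the significance call; constant-input rows are flagged and excluded from
    the FDR family of their test.
    """
    wide = auc[auc["method"] == method].pivot(index="subject_id",
                                              columns="roi", values="auc")
    subjects = sorted(set(wide.index) & set(phenotypes["subject_id"]))
    if set(phenotypes["subject_id"]) - set(wide.index):
        missing = sorted(set(phenotypes["subject_id"]) - set(wide.index))[0]
        raise ValueError(f"subject {missing} has phenotypes but no AUC")
    if groups is not None:
        if group_manifest is None:
            raise ValueError("groups restriction requires a manifest")
        keep = group_manifest.loc[
            group_manifest["group"].isin(groups), "subject_id"]
        subjects = sorted(set(subjects) & set(keep))
    sig_rois = sorted(sig_rois)
    missing_rois = set(sig_rois) - set(wide.columns)
    if missing_rois:
        raise ValueError(f"ROIs without AUC values: {sorted(missing_rois)}")

    pheno = phenotypes.pivot_table(index="subject_id",
                                   columns=["test", "subscore"],
                                   values="value").loc[subjects]
    rows = []
    for roi in sig_rois:
        x = wide.loc[subjects, roi].to_numpy()
        for (test, subscore) in pheno.columns:
            y = pheno[(test, subscore)].to_numpy()
            try:
                rho, p = spearman(x, y)
                flagged = False
            except ValueError:
                rho, p, flagged = np.nan, np.nan, True
            rows.append({"roi_id": roi, "test": test, "subscore": subscore,
                         "rho": rho, "p_raw": p, "n": len(subjects),
                         "flagged": flagged})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for test, idx in out.groupby("test").groups.items():
        ok = out.loc[idx].index[~out.loc[idx, "flagged"]]
        if len(ok):
            out.loc[ok, "p_fdr"] = bh_fdr(out.loc[ok, "p_raw"])
    out["significant"] = out["p_fdr"] < alpha
    return out
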