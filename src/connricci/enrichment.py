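"""Term enrichment of significant ROIs by resting-state network.

Given the set of ROIs with significant group differences, each ROI is
assigned to its RSN and, per RSN, the occurrences of each associated term
among the significant ROIs are counted. Significance comes from a
permutation-style null: the same number of ROIs is drawn uniformly without
replacement from ALL ROIs (the full atlas, not per RSN), the draw is
partitioned by RSN and counted identically, and the per-(RSN, term) null
mean and standard deviation over the draws yield a z-score that is converted
to a p-value under normality (one-sided upper tail by default). BH-FDR is
applied across terms within each RSN; terms with a degenerate null
(sd = 0) are flagged and excluded from the FDR family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .groupstats import ALPHA, bh_fdr

logger = logging.getLogger(__name__)


def _tables(annotations: pd.DataFrame, terms: pd.DataFrame):
    """Internal: ROI order, RSN label array, and binary ROI x term matrix."""
    roi_ids = list(annotations["roi_id"])
    rsn = annotations["rsn_label"].to_numpy()
    term_names = sorted(terms["term"].unique())
    m = np.zeros((len(roi_ids), len(term_names)), dtype=int)
    roi_pos = {r: i for i, r in enumerate(roi_ids)}
    term_pos = {t: i for i, t in enumerate(term_names)}
    for _, row in terms.iterrows():
        if row["value"]:
            m[roi_pos[row["roi_id"]], term_pos[row["term"]]] = 1
    return roi_ids, rsn, term_names, m


def observed_term_counts(sig_rois, rsn_label: str,
                         annotations: pd.DataFrame,
                         terms: pd.DataFrame) -> pd.Series:
    """Occurrences of each term among the significant ROIs of one RSN
    (each ROI contributes at most one occurrence per term)."""
    roi_ids, rsn, term_names, m = _tables(annotations, terms)
    if rsn_label not in set(rsn):
        raise ValueError(f"unknown RSN label {rsn_label!r}")
    if not set(sig_rois) <= set(roi_ids):
        raise ValueError("significant ROIs outside the annotated set")
    mask = np.array([r in set(sig_rois) and lab == rsn_label
                     for r, lab in zip(roi_ids, rsn)])
    return pd.Series(m[mask].sum(axis=0), index=term_names)


def null_term_distribution(n_sig: int, annotations: pd.DataFrame,
                           terms: pd.DataFrame, n_draws: int = 1000,
                           seed: int = 0) -> pd.DataFrame:
    """Null mean/sd of term counts per (RSN, term) from random ROI sets.

    Each draw samples ``n_sig`` ROIs uniformly without replacement from all
    ROIs; the draw is partitioned by RSN and counted like the observed set.
    Returns columns rsn_label, term, null_mean, null_sd.
    """
    roi_ids, rsn, term_names, m = _tables(annotations, terms)
    n_rois = len(roi_ids)
    if n_sig > n_rois:
        raise ValueError("n_sig exceeds the number of ROIs")
    if n_draws < 2:
        raise ValueError("need at least 2 null draws")
    rng = np.random.default_rng(seed)
    labels = sorted(set(rsn))
    rsn_masks = {lab: rsn == lab for lab in labels}
    counts = {lab: np.empty((n_draws, len(term_names))) for lab in labels}
    for d in range(n_draws):
        pick = np.zeros(n_rois, dtype=bool)
        pick[rng.choice(n_rois, size=n_sig, replace=False)] = True
        for lab in labels:
            counts[lab][d] = m[pick & rsn_masks[lab]].sum(axis=0)
    rows = []
    for lab in labels:
        mu = counts[lab].mean(axis=0)
        sd = counts[lab].std(axis=0, ddof=1)
        for t, term in enumerate(term_names):
            rows.append({"rsn_label": lab, "term": term,
                         "null_mean": mu[t], "null_sd": sd[t]})
    return pd.DataFrame(rows)


def enrich(sig_rois, annotations: pd.DataFrame, terms: pd.DataFrame,
           n_draws: int = 1000, seed: int = 0, alpha: float = ALPHA,
           two_sided: bool = False) -> pd.DataFrame:
    """Full enrichment: observed counts, random-ROI null, z-scores, normal
    p-values, BH-FDR across terms within each RSN.

    Returns one row per (RSN, term) actually observed or nullable, with
    observed_count, null_mean, null_sd, z, p_raw, p_fdr, significant and a
    ``degenerate`` flag for sd = 0 rows (excluded from FDR).
    """
    sig_rois = sorted(set(sig_rois))
    null = null_term_distribution(len(sig_rois), annotations, terms,
                                  n_draws=n_draws, seed=seed)
    labels = sorted(null["rsn_label"].unique())
    frames = []
    for lab in labels:
        obs = observed_term_counts(sig_rois, lab, annotations, terms)
        sub = null[null["rsn_label"] == lab].copy()
        sub["observed_count"] = sub["term"].map(obs).astype(int)
        degen = sub["null_sd"] == 0
        if degen.any():
            logger.warning("RSN %s: %d term(s) with degenerate null excluded "
                           "from FDR", lab, int(degen.sum()))
        sub["degenerate"] = degen
        sub["z"] = np.where(
            degen, np.nan,
            (sub["observed_count"] - sub["null_mean"])
            / sub["null_sd"].where(~degen))
        if two_sided:
            sub["p_raw"] = 2 * stats.norm.sf(np.abs(sub["z"]))
        else:
            sub["p_raw"] = stats.norm.sf(sub["z"])
        sub["p_fdr"] = np.nan
        ok = ~degen
        if ok.any():
            sub.loc[ok, "p_fdr"] = bh_fdr(sub.loc[ok, "p_raw"])
        sub["significant"] = sub["p_fdr"] < alpha
        frames.append(sub)
    cols = ["rsn_label", "term", "observed_count", "null_mean", "null_sd",
            "z", "p_raw", "p_fdr", "significant", "degenerate"]
    return pd.concat(frames, ignore_index=True)[cols]
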