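"""Synthetic two-group cohorts of functional connectivity matrices.

The generator emulates the statistical structure the downstream pipeline
assumes: each group has a block-constant correlation matrix (blocks standing
in for resting-state-network communities), the "old" group carries an
additive correlation shift among a chosen subset of effect ROIs within their
block, and per-subject FC matrices are sample Pearson correlations of
multivariate-normal time series drawn from the group covariance. A per-old-
subject latent factor u_s ~ Uniform(0.5, 1.5) scales the realized shift,
creating both a group difference and within-old-group variation; the same
u_s drives the phenotype scores, so curvature-phenotype coupling is planted
by construction. ROI term associations are random binary draws with the
enriched terms planted deterministically on the effect ROIs.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .construct import FCMatrix

#: eigenvalue floor used by the positive-definiteness repair
EIG_FLOOR = 1e-6

RSN_LABELS = (
    "default", "somatomotor", "dorsal_attention", "ventral_attention",
    "visual", "limbic", "control",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the desk-scale study condition: 60 ROIs in 3 blocks,
    20 + 20 subjects, 300 time points, within/between-block correlations
    0.35 / 0.10, and a +0.3 within-block correlation shift on 10 effect ROIs
    in the old group.
    """

    n_rois: int = 60
    n_blocks: int = 3
    n_young: int = 20
    n_old: int = 20
    n_timepoints: int = 300
    base_within_corr: float = 0.35
    base_between_corr: float = 0.10
    effect_rois: frozenset = frozenset(range(10))
    effect_size: float = 0.3
    pheno_slope: float = 1.0
    pheno_noise_sd: float = 0.5
    n_terms: int = 40
    terms_per_roi: int = 5
    enriched_terms: tuple = ("movement",)
    n_subscores: int = 3
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "effect_rois", frozenset(self.effect_rois))
        object.__setattr__(self, "enriched_terms", tuple(self.enriched_terms))
        for name in ("n_rois", "n_blocks", "n_young", "n_old", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_blocks > self.n_rois:
            raise ValueError("more blocks than ROIs")
        for name in ("base_within_corr", "base_between_corr"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not -1 < self.effect_size < 1:
            raise ValueError("effect_size must lie in (-1, 1)")
        if not self.effect_rois <= set(range(self.n_rois)):
            raise ValueError("effect_rois must be a subset of ROI indices")
        if self.terms_per_roi > self.n_terms:
            raise ValueError("terms_per_roi exceeds n_terms")
        if self.n_timepoints <= self.n_rois + 2:
            raise ValueError("n_timepoints must exceed n_rois + 2")

    @property
    def roi_ids(self) -> tuple:
        return tuple(f"roi_{i:03d}" for i in range(self.n_rois))

    @property
    def block_of(self) -> np.ndarray:
        """Block index per ROI (contiguous near-equal blocks)."""
        return np.repeat(
            np.arange(self.n_blocks),
            np.diff(np.linspace(0, self.n_rois, self.n_blocks + 1).astype(int)),
        )

    @property
    def term_universe(self) -> tuple:
        generic = tuple(
            f"term_{i:03d}" for i in range(self.n_terms - len(self.enriched_terms))
        )
        return self.enriched_terms + generic


@dataclass(frozen=True)
class CohortBundle:
    """A full synthetic cohort with its planted ground truth."""

    fc_matrices: list
    annotations: pd.DataFrame    # roi_id, rsn_label
    term_table: pd.DataFrame     # roi_id, term, value
    phenotypes: pd.DataFrame     # subject_id, test, subscore, value
    ground_truth: dict
    config: SimulationConfig

    def __post_init__(self):
        sids = [m.subject_id for m in self.fc_matrices]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate subject ids in cohort")
        psubj = self.phenotypes["subject_id"].unique()
        if set(psubj) != set(sids):
            raise ValueError("phenotype subjects do not match cohort")
        rois = self.annotations["roi_id"]
        if rois.duplicated().any():
            raise ValueError("duplicate ROI ids in annotations")

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": [m.subject_id for m in self.fc_matrices],
             "group": [m.group for m in self.fc_matrices]}
        )


def _repair_pd(mat: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at EIG_FLOOR and re-normalize to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() > EIG_FLOOR:
        return mat
    vals = np.clip(vals, EIG_FLOOR, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    out = (out + out.T) / 2
    if np.linalg.eigvalsh(out).min() <= 0:
        raise ValueError("covariance not positive definite after repair")
    return out


def build_group_covariance(config: SimulationConfig, group: str,
                           latent: float = 1.0) -> np.ndarray:
    """Block-constant group correlation matrix, PD-repaired if needed.

    For ``group="old"`` the entries among effect ROIs sharing a block are
    shifted by ``latent * effect_size`` and clipped to (-0.99, 0.99);
    ``latent`` is the per-subject factor u_s (1.0 gives the group mean).
    """
    if group not in ("young", "old"):
        raise ValueError(f"unknown group {group!r}")
    block = config.block_of
    same_block = block[:, None] == block[None, :]
    cov = np.where(same_block, config.base_within_corr,
                   config.base_between_corr).astype(float)
    if group == "old" and config.effect_rois:
        idx = np.array(sorted(config.effect_rois))
        mask = np.zeros(config.n_rois, dtype=bool)
        mask[idx] = True
        eff = np.outer(mask, mask) & same_block
        cov = np.where(eff, np.clip(cov + latent * config.effect_size,
                                    -0.99, 0.99), cov)
    np.fill_diagonal(cov, 1.0)
    try:
        return _repair_pd(cov)
    except ValueError as err:
        raise ValueError(
            f"group covariance for {group!r} not repairable: "
            f"within={config.base_within_corr}, between={config.base_between_corr}, "
            f"effect_size={config.effect_size}"
        ) from err


def sample_fc_matrix(cov: np.ndarray, n_timepoints: int, seed,
                     subject_id: str = "subject", group: str = "young",
                     roi_ids=None) -> FCMatrix:
    """Sample Pearson correlation matrix of ``n_timepoints`` i.i.d. draws from
    a zero-mean multivariate normal with the given covariance."""
    cov = np.asarray(cov, float)
    n = cov.shape[0]
    if n_timepoints <= n + 2:
        raise ValueError("n_timepoints must exceed n_rois + 2")
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("covariance must be positive definite")
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(np.zeros(n), cov, size=n_timepoints,
                                method="cholesky")
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    if roi_ids is None:
        roi_ids = tuple(f"roi_{i:03d}" for i in range(n))
    return FCMatrix(subject_id=subject_id, group=group, values=corr,
                    roi_ids=roi_ids)


def generate_annotations(config: SimulationConfig) -> pd.DataFrame:
    """ROI -> pseudo-RSN label table (one canonical label per block)."""
    labels = [RSN_LABELS[b % len(RSN_LABELS)] for b in config.block_of]
    return pd.DataFrame({"roi_id": config.roi_ids, "rsn_label": labels})


def generate_term_table(annotations: pd.DataFrame, effect_rois,
                        config: SimulationConfig, seed=None,
                        universe=None) -> pd.DataFrame:
    """Binary ROI x term table: ``terms_per_roi`` random terms per ROI, with
    every enriched term planted on every effect ROI.

    ``universe`` overrides the config's term universe; the enriched terms
    must be members of it.
    """
    if universe is None:
        universe = config.term_universe
    if not set(config.enriched_terms) <= set(universe):
        raise ValueError("enriched_terms outside the term universe")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    roi_ids = list(annotations["roi_id"])
    for idx, roi in enumerate(roi_ids):
        terms = set(rng.choice(len(universe), size=config.terms_per_roi,
                               replace=False))
        terms = {universe[t] for t in terms}
        if idx in effect_rois:
            terms |= set(config.enriched_terms)
        rows.extend({"roi_id": roi, "term": t, "value": 1}
                    for t in sorted(terms))
    return pd.DataFrame(rows, columns=["roi_id", "term", "value"])


def generate_phenotypes(subject_factors: pd.Series, config: SimulationConfig,
                        test_name: str = "synthetic_affect",
                        seed=None) -> pd.DataFrame:
    """Phenotype subscores: score = pheno_slope * u_s + Normal(0, noise_sd)
    with independent noise per subscore."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    u = subject_factors.to_numpy(float)
    rows = []
    for k in range(config.n_subscores):
        noise = rng.normal(0.0, config.pheno_noise_sd, size=u.size)
        score = config.pheno_slope * u + noise
        for sid, val in zip(subject_factors.index, score):
            rows.append({"subject_id": sid, "test": test_name,
                         "subscore": f"subscore_{k:02d}", "value": val})
    return pd.DataFrame(rows, columns=["subject_id", "test", "subscore", "value"])


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Full deterministic cohort: FC matrices, annotations, terms, phenotypes
    and the planted ground truth."""
    root = np.random.default_rng(config.seed)
    factors = {}
    matrices = []
    cov_young = build_group_covariance(config, "young")
    cov_old = build_group_covariance(config, "old")
    for k in range(config.n_young):
        sid = f"young_{k:03d}"
        factors[sid] = 0.0
        matrices.append(sample_fc_matrix(
            cov_young, config.n_timepoints, root.integers(2**31),
            subject_id=sid, group="young", roi_ids=config.roi_ids))
    for k in range(config.n_old):
        sid = f"old_{k:03d}"
        u = float(root.uniform(0.5, 1.5))
        factors[sid] = u
        cov_s = build_group_covariance(config, "old", latent=u)
        matrices.append(sample_fc_matrix(
            cov_s, config.n_timepoints, root.integers(2**31),
            subject_id=sid, group="old", roi_ids=config.roi_ids))

    annotations = generate_annotations(config)
    term_table = generate_term_table(annotations, config.effect_rois, config,
                                     seed=root.integers(2**31))
    phenotypes = generate_phenotypes(pd.Series(factors), config,
                                     seed=root.integers(2**31))
    ground_truth = {
        "effect_rois": sorted(config.effect_rois),
        "subject_factors": factors,
        "cov_young": cov_young,
        "cov_old": cov_old,
    }
    return CohortBundle(fc_matrices=matrices, annotations=annotations,
                        term_table=term_table, phenotypes=phenotypes,
                        ground_truth=ground_truth, config=config)
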