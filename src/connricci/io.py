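"""Plain-text I/O: TSV matrices and result tables with provenance headers."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .construct import FCMatrix, FCN

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


def write_fc_matrix(fc: FCMatrix, path) -> None:
    """Write a subject FC matrix as TSV with a header row of ROI ids."""
    df = pd.DataFrame(fc.values, columns=fc.roi_ids)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_fc_matrix(path, subject_id: str = "", group: str = "") -> FCMatrix:
    """Read and validate a TSV FC matrix (symmetry, unit diagonal, range)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:
        raise ValueError(f"cannot parse FC matrix {path}: {err}") from err
    return FCMatrix(subject_id=subject_id or Path(path).stem, group=group,
                    values=df.to_numpy(float), roi_ids=tuple(df.columns))


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"manifest missing column {col!r}")
    return df


def write_edgelist(fcn: FCN, path) -> None:
    """Edge list (two 0-based indices per line) plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, j in fcn.edges:
            fh.write(f"{i}\t{j}\n")
    sidecar = {"subject_id": fcn.subject_id, "density": fcn.density,
               "n": fcn.n, "n_edges": len(fcn.edges)}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a result table as TSV with '#'-prefixed provenance header lines
    (version, config hash, seeds) and fixed 12-significant-digit floats."""
    with open(path, "w") as fh:
        fh.write(f"# connricci {__version__}\n")
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
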