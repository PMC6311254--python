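"""Readers and writers for the pipeline's tab-separated formats.

All tables are UTF-8 TSV with a header row; missing values are empty cells
(matching TCGA clinical exports).  Numbers are serialized with full
precision (`repr` round-trip), so writing then reading reproduces the
in-memory values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .screen import CandidateRanking
from .survival import CLINICAL_COLUMNS

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_ranking",
    "write_ranking",
    "write_survival",
    "read_associations",
    "write_roc",
]


#: %.17g round-trips every IEEE double exactly
FLOAT_FORMAT = "%.17g"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column sample ID, remaining columns transcripts."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.empty or df.shape[1] == 0:
        raise InputError(f"expression table {path} has no transcript columns")
    values = df.to_numpy()
    if not np.isfinite(values).all() or (values < 0).any():
        raise InputError(f"expression table {path} contains negative or non-finite values")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)


def read_clinical(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"clinical file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"submitter_id": str, "vital_status": str},
                     float_precision="round_trip")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"clinical table {path} is missing columns: {missing}")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(CLINICAL_COLUMNS))


def write_ranking(ranking: CandidateRanking, path: str | Path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_ranking(path: str | Path) -> CandidateRanking:
    path = Path(path)
    if not path.exists():
        raise InputError(f"ranking file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str},
                     float_precision="round_trip")
    for col in ("transcript_id", "p_value"):
        if col not in df.columns:
            raise InputError(f"ranking table {path} is missing column {col!r}")
    p = df["p_value"].to_numpy(dtype=float)
    if (np.diff(p) < 0).any():
        raise InputError(f"ranking table {path} is not sorted by ascending P")
    return CandidateRanking(transcript_ids=tuple(df["transcript_id"]), p_values=p)


def write_survival(la: pd.Series, events: pd.Series, path: str | Path) -> None:
    pd.DataFrame(
        {
            "submitter_id": la.index,
            "survival_days": la.to_numpy(),
            "event_indicator": events.reindex(la.index).to_numpy(),
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_associations(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of (lncRNA id, disease id) known associations."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"association file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, names=["lncrna", "disease"], dtype=str)
    if df.isna().any().any():
        raise InputError(f"association table {path} has blank fields")
    return list(df.itertuples(index=False, name=None))


def write_roc(curve, path: str | Path) -> None:
    pd.DataFrame({"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
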