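"""Survival response vector from TCGA-dialect clinical records.

Each patient contributes one survival time: ``days_to_death`` when dead,
``days_to_last_follow_up`` when alive.  Formally, with the per-patient
indicator pair (alpha, beta) = (1, 0) for dead and (0, 1) for alive, the
response is ``Dd*alpha + Dl*beta``.  Follow-up time is deliberately used as
the response for alive patients — no censoring-aware modelling is applied.

Blank clinical cells are read as 0, matching the convention that the absent
time field of each record is recorded as 0.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .errors import InputError

__all__ = ["survival_coefficients", "build_survival_vector", "CLINICAL_COLUMNS"]

CLINICAL_COLUMNS = (
    "submitter_id",
    "vital_status",
    "days_to_death",
    "days_to_last_follow_up",
)


def survival_coefficients(vital_status: str) -> tuple[int, int]:
    """Map a vital status to the (alpha, beta) indicator pair.

    ``dead`` -> (1, 0); ``alive`` -> (0, 1); case-insensitive.
    """
    status = str(vital_status).strip().lower()
    if status == "dead":
        return (1, 0)
    if status == "alive":
        return (0, 1)
    raise InputError(f"unrecognized vital_status {vital_status!r} (expected dead/alive)")


def build_survival_vector(clinical: pd.DataFrame, sample_order: Iterable[str]) -> pd.Series:
    """Build the survival response, ordered like the expression matrix rows.

    Parameters
    ----------
    clinical
        Table with the TCGA export columns ``submitter_id``, ``vital_status``,
        ``days_to_death``, ``days_to_last_follow_up``; blanks/NaN read as 0.
    sample_order
        Sample IDs in expression-matrix row order; each must have exactly
        one clinical record.

    Returns
    -------
    pandas.Series
        Strictly positive survival days indexed by sample ID.  A record
        whose relevant time field is 0/missing is rejected: the response
        must be strictly positive to be a meaningful regression target.
    """
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing_cols:
        raise InputError(f"clinical table is missing columns: {missing_cols}")

    records = clinical.set_index("submitter_id", drop=False)
    if records.index.has_duplicates:
        dups = records.index[records.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate clinical records for: {dups[:5]}")

    times: list[float] = []
    order = list(sample_order)
    for sid in order:
        if sid not in records.index:
            raise InputError(f"no clinical record for sample {sid!r}")
        rec = records.loc[sid]
        alpha, beta = survival_coefficients(rec["vital_status"])
        dd = float(pd.to_numeric(rec["days_to_death"], errors="coerce") or 0.0)
        dl = float(pd.to_numeric(rec["days_to_last_follow_up"], errors="coerce") or 0.0)
        dd = 0.0 if pd.isna(dd) else dd
        dl = 0.0 if pd.isna(dl) else dl
        time = dd * alpha + dl * beta
        if time <= 0:
            raise InputError(
                f"sample {sid!r} ({rec['vital_status']}) has no positive survival time"
            )
        times.append(time)
    return pd.Series(times, index=pd.Index(order, name="submitter_id"), name="survival_days")
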