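"""Differential-expression screen and construction of the training matrix.

The screen compares each transcript between the normal and tumor groups,
keeps transcripts with P below a threshold (0.001 by default) and orders
them by ascending P — this ordering is load-bearing: every later selection
vector indexes candidates by their position in it, so the ordering must be
total and reproducible (ties on P break by transcript ID).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = ["CandidateRanking", "differential_screen", "build_led"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateRanking:
    """Transcripts ordered by ascending differential-expression P value."""

    transcript_ids: tuple[str, ...]
    p_values: np.ndarray  # aligned with transcript_ids, non-decreasing

    def __len__(self) -> int:
        return len(self.transcript_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_ids,
                "p_value": self.p_values,
                "rank": np.arange(1, len(self) + 1),
            }
        )


def differential_screen(
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
    alpha: float = 0.001,
    method: str = "welch",
) -> CandidateRanking:
    """Screen transcripts for a group difference and rank the survivors.

    Parameters
    ----------
    normal, tumor
        Samples x transcripts expression matrices sharing the same columns.
    alpha
        Retain transcripts with two-sided P strictly below this threshold.
        No multiple-testing correction is applied: the screen filters on
        raw P by design.
    method
        ``"welch"`` — two-sided Welch unequal-variance t test (default), or
        ``"ranksum"`` — two-sided Mann–Whitney U test.

    Returns
    -------
    CandidateRanking
        Survivors sorted by ascending P, ties broken by transcript ID.
        A transcript with zero variance in both groups gets P = 1 and is
        never selected.
    """
    if set(normal.columns) != set(tumor.columns):
        missing = set(normal.columns) ^ set(tumor.columns)
        raise InputError(f"normal and tumor matrices disagree on transcripts: {sorted(missing)[:5]}")
    if not 0.0 < alpha < 1.0:
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    if method not in ("welch", "ranksum"):
        raise InputError(f"unknown screen method {method!r}")

    tumor = tumor[normal.columns]
    a = normal.to_numpy(dtype=float)
    b = tumor.to_numpy(dtype=float)

    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant columns trip scipy's precision warning; they get P = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "welch":
            _, pvals = stats.ttest_ind(a, b, axis=0, equal_var=False)
        else:
            _, pvals = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    pvals = np.asarray(pvals, dtype=float)
    pvals[~np.isfinite(pvals)] = 1.0
    if degenerate.any():
        logger.info(
            "%d transcripts have zero variance in both groups; assigned P = 1",
            int(degenerate.sum()),
        )
        pvals[degenerate] = 1.0

    frame = pd.DataFrame({"transcript_id": normal.columns, "p_value": pvals})
    frame = frame[frame["p_value"] < alpha]
    frame = frame.sort_values(["p_value", "transcript_id"], kind="stable")
    return CandidateRanking(
        transcript_ids=tuple(frame["transcript_id"]),
        p_values=frame["p_value"].to_numpy(),
    )


def build_led(tumor: pd.DataFrame, ranking: CandidateRanking) -> pd.DataFrame:
    """Build the training matrix: ranked transcripts as columns, rows sorted
    by ascending sample ID."""
    missing = [t for t in ranking.transcript_ids if t not in tumor.columns]
    if missing:
        raise InputError(f"ranked transcripts absent from tumor matrix: {missing[:5]}")
    led = tumor.loc[sorted(tumor.index), list(ranking.transcript_ids)]
    return led
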