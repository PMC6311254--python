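"""Bidirectional stepwise reduction of an active candidate set, scored by AIC.

The reducer maintains a working set that starts empty, alternates a forward
phase (add the candidate whose inclusion lowers AIC most) with a backward
phase (drop the member whose removal lowers AIC most), and terminates only
when a full pass in each direction produces no move — tracked with a pair of
stall flags that any successful move resets.  "Significant effect" is
operationalized as a strict AIC decrease: AIC is the search's sole quality
measure, smaller is better, and strictness guarantees termination (every
accepted move strictly decreases a quantity bounded below over the finite
subset lattice).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["StepwiseResult", "model_aic", "stepwise_select"]

logger = logging.getLogger(__name__)


@dataclass
class StepwiseResult:
    """Outcome of a stepwise reduction."""

    reduced_set: tuple[int, ...]  # surviving candidate indices, ascending
    aic: float
    history: list[tuple[str, int, float]] = field(default_factory=list)  # (action, index, AIC after)


def _design(columns: np.ndarray) -> np.ndarray:
    n = columns.shape[0]
    return np.column_stack([np.ones(n), columns])


def _rss_and_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, residuals, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if residuals.size:
        rss = float(residuals[0])
    else:
        rss = float(np.sum((y - X @ coef) ** 2))
    return rss, int(rank)


def model_aic(columns: np.ndarray, y: np.ndarray) -> float:
    """AIC of the OLS fit of ``y`` on ``columns`` plus an intercept.

    Full Gaussian-likelihood convention counting the error variance:
    ``n*ln(2*pi*RSS/n) + n + 2*(k+2)`` for k predictors.  RSS = 0 yields
    -inf (a perfect fit dominates any penalty).  A rank-deficient design is
    fit on its maximal independent column basis, with the effective k
    reduced accordingly, and a warning is issued.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    columns = np.asarray(columns, dtype=float)
    if columns.ndim == 1:
        columns = columns[:, None]
    if columns.size == 0:
        columns = columns.reshape(n, 0)
    k = columns.shape[1]
    X = _design(columns)
    rss, rank = _rss_and_rank(X, y)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient design ({rank} < {X.shape[1]}): collinear columns ignored",
            stacklevel=2,
        )
        k = rank - 1  # effective predictors excluding the intercept
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss <= 1e-12 * max(tss, 1e-300):  # numerically perfect fit
        return -np.inf
    return n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (k + 2)


def stepwise_select(
    candidates: Sequence[int],
    led_values: np.ndarray,
    la: np.ndarray,
) -> StepwiseResult:
    """Reduce ``candidates`` (column indices into ``led_values``) by the
    flagged add/remove loop and return the surviving set with its AIC.

    Ties between equally improving moves break toward the smaller candidate
    index (the more significant transcript), keeping the procedure
    deterministic.  Candidate sets too large for the sample size are
    truncated to the smallest-index members so the fit keeps residual
    degrees of freedom.
    """
    la = np.asarray(la, dtype=float)
    n = la.size
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        return StepwiseResult(reduced_set=(), aic=model_aic(np.empty((n, 0)), la))
    if len(candidates) >= n - 2:
        warnings.warn(
            f"{len(candidates)} candidates for {n} samples; truncating to {n - 3} "
            "smallest-index candidates",
            stacklevel=2,
        )
        candidates = candidates[: n - 3]

    cols = {c: led_values[:, c] for c in candidates}
    temp: list[int] = []
    current_aic = model_aic(np.empty((n, 0)), la)
    history: list[tuple[str, int, float]] = []
    flag_add = flag_remove = 0

    def aic_of(members: list[int]) -> float:
        if not members:
            return model_aic(np.empty((n, 0)), la)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collinearity inside the search is routine
            return model_aic(np.column_stack([cols[c] for c in members]), la)

    while True:
        # forward phase: best-first additions while any strictly lowers AIC
        while True:
            best_c, best_aic = None, current_aic
            for c in candidates:
                if c in temp:
                    continue
                trial = aic_of(sorted(temp + [c]))
                if trial < best_aic:
                    best_c, best_aic = c, trial
            if best_c is not None:
                temp = sorted(temp + [best_c])
                current_aic = best_aic
                history.append(("add", best_c, current_aic))
                flag_add = flag_remove = 0
            else:
                flag_add = 1
                break
        if flag_add == 1 and flag_remove == 1:
            break
        # backward phase: best-first removals while any strictly lowers AIC
        while True:
            best_c, best_aic = None, current_aic
            for c in temp:
                trial = aic_of([m for m in temp if m != c])
                if trial < best_aic:
                    best_c, best_aic = c, trial
            if best_c is not None:
                temp = [m for m in temp if m != best_c]
                current_aic = best_aic
                history.append(("remove", best_c, current_aic))
                flag_add = flag_remove = 0
            else:
                flag_remove = 1
                break
        if flag_add == 1 and flag_remove == 1:
            break

    logger.debug("stepwise: %d of %d candidates survive, AIC %.2f", len(temp), len(candidates), current_aic)
    return StepwiseResult(reduced_set=tuple(temp), aic=current_aic, history=history)
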