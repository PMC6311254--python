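"""MlrLDAcp: sparse multiple linear regression of survival time on lncRNA
expression, with candidate selection by the Γ-operation search.

The model regresses the survival response (days to death, or to last
follow-up for alive patients) on a subset of P-ranked candidate transcripts.
The subset is found by iterating, for D rounds, a windowed bitwise mutation
of the inclusion vector (Γ operation), a stagnation kick, a retention cap
(Γ correction) and a bidirectional stepwise-AIC reduction, keeping the best
reduced set seen on a bulletin board.  The final fit is ordinary least
squares with intercept; its coefficients Θ map expression units to survival
days and double as per-transcript disease-association weights.

The search contains no randomness: given the same inputs and configuration
it is exactly reproducible.

Usage follows the Model/Results convention::

    model = MlrLDAcp(la, led, p_values=ranking.p_values)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateRangeError, InputError
from .gamma import (
    GammaConfig,
    decay_coefficient,
    gamma_correct,
    gamma_operate,
    variation_center,
    variation_range,
)
from .screen import CandidateRanking
from .stepwise import stepwise_select

__all__ = [
    "MlrLDAcp",
    "MlrLDAcpResults",
    "initialize_selection",
    "stagnation_kick",
    "run_search",
    "model_significance",
]

logger = logging.getLogger(__name__)


def initialize_selection(
    p_values: np.ndarray, init_threshold: float = 1e-12
) -> tuple[np.ndarray, int]:
    """Seed the selection vector with the ultra-significant candidates.

    Bit j is set iff the j-th ranked P value is below ``init_threshold``
    (default 1e-12); the retention cap theta is the resulting population
    count.  If no candidate clears the threshold, the seed falls back to
    the ``max(10, C // 10)`` smallest P values with a warning — the search
    needs a non-empty starting set.
    """
    p_values = np.asarray(p_values, dtype=float)
    C = p_values.size
    if C == 0:
        raise InputError("candidate ranking is empty")
    x0 = (p_values < init_threshold).astype(np.uint8)
    if x0.sum() == 0:
        k = min(max(10, C // 10), C)
        warnings.warn(
            f"no candidate has P < {init_threshold:g}; seeding with the {k} smallest P values",
            stacklevel=2,
        )
        x0 = np.zeros(C, dtype=np.uint8)
        x0[np.argsort(p_values, kind="stable")[:k]] = 1
    return x0, int(x0.sum())


def stagnation_kick(
    x_current: np.ndarray, x_previous: np.ndarray, theta: int
) -> np.ndarray:
    """Escape repeated states: if the leading theta bits of the two vectors
    coincide, flip positions 1..theta of the current vector; otherwise
    return it unchanged.  (A Γ correction follows in the search loop.)"""
    if x_current.size != x_previous.size:
        raise ValueError("selection vectors differ in length")
    t = min(theta, x_current.size)
    if np.array_equal(x_current[:t], x_previous[:t]):
        out = x_current.copy()
        out[:t] ^= 1
        return out
    return x_current


def model_significance(results: "MlrLDAcpResults") -> float:
    """Overall regression P value (F test of the fitted model against the
    intercept-only model); numerically 0 for a perfect fit."""
    return results.model_p


@dataclass
class SearchRecord:
    """Per-iteration trace entry of the Γ search."""

    d: int
    center: float | None
    xi: float | None
    index_range: tuple[int, int] | None
    population: int
    stepwise_aic: float | None
    reduced_size: int | None
    skipped: bool = False


@dataclass
class _SearchOutcome:
    optimal_set: tuple[int, ...]
    aic_optimal: float
    trace: list[SearchRecord] = field(default_factory=list)


class MlrLDAcp:
    """Survival-time regression with Γ-operation transcript selection.

    Parameters
    ----------
    endog
        Survival response in days, one entry per sample (Series or array).
    exog
        Samples x candidate-transcripts expression matrix whose columns are
        already ordered by ascending differential-expression P (the ranked
        training matrix).
    p_values
        Differential-expression P value per column of ``exog``; drives the
        initial selection.  Required unless a ``ranking`` is given.
    ranking
        A :class:`~lncsurv.screen.CandidateRanking` whose transcripts match
        ``exog``'s columns; alternative to ``p_values``.
    config
        :class:`~lncsurv.gamma.GammaConfig` with the iteration budget D,
        retention cap, decay schedule and seed threshold.
    """

    def __init__(
        self,
        endog,
        exog: pd.DataFrame,
        p_values: np.ndarray | None = None,
        ranking: CandidateRanking | None = None,
        config: GammaConfig | None = None,
    ):
        exog = pd.DataFrame(exog)
        endog_values = np.asarray(endog, dtype=float).ravel()
        if endog_values.size != len(exog):
            raise InputError(
                f"response length {endog_values.size} does not match {len(exog)} samples"
            )
        endog = pd.Series(endog_values, index=exog.index, name="survival_days")
        if ranking is not None:
            if list(ranking.transcript_ids) != list(exog.columns):
                raise InputError("ranking transcripts do not match exog columns")
            p_values = ranking.p_values
        if p_values is None:
            raise InputError("either p_values or ranking must be provided")
        p_values = np.asarray(p_values, dtype=float)
        if p_values.size != exog.shape[1]:
            raise InputError(
                f"{p_values.size} P values for {exog.shape[1]} candidate columns"
            )
        if len(endog) != len(exog):
            raise InputError(
                f"response length {len(endog)} does not match {len(exog)} samples"
            )
        config = config or GammaConfig()
        config.validate(C=exog.shape[1])
        self.endog = endog
        self.exog = exog
        self.p_values = p_values
        self.config = config

    @classmethod
    def from_cohort(cls, normal, tumor, clinical, alpha: float = 0.001,
                    method: str = "welch", config: GammaConfig | None = None) -> "MlrLDAcp":
        """Convenience constructor: screen, build the training matrix and
        the survival response, then assemble the model."""
        from .screen import build_led, differential_screen
        from .survival import build_survival_vector

        ranking = differential_screen(normal, tumor, alpha=alpha, method=method)
        led = build_led(tumor, ranking)
        la = build_survival_vector(clinical, led.index)
        return cls(la, led, ranking=ranking, config=config)

    # ------------------------------------------------------------------ #

    def _search(self) -> _SearchOutcome:
        cfg = self.config
        C = self.exog.shape[1]
        led_values = self.exog.to_numpy(dtype=float)
        la = self.endog.to_numpy(dtype=float)

        x0, theta0 = initialize_selection(self.p_values, cfg.init_threshold)
        theta = cfg.theta if cfg.theta is not None else theta0

        init = stepwise_select(np.flatnonzero(x0), led_values, la)
        optimal_set, aic_optimal = init.reduced_set, init.aic
        trace = [
            SearchRecord(
                d=0, center=None, xi=None, index_range=None,
                population=int(x0.sum()), stepwise_aic=init.aic,
                reduced_size=len(init.reduced_set),
            )
        ]
        logger.info("d=0 seed: population %d, stepwise AIC %.2f", x0.sum(), init.aic)

        x_prev = x0
        for d in range(1, cfg.D + 1):
            center = variation_center(C, cfg.D, d)
            xi = decay_coefficient(cfg.D, d, cfg.schedule)
            try:
                rng = variation_range(center, xi, C)
            except DegenerateRangeError:
                logger.warning("d=%d: degenerate variation range, iteration skipped", d)
                trace.append(SearchRecord(d=d, center=center, xi=xi, index_range=None,
                                          population=int(x_prev.sum()), stepwise_aic=None,
                                          reduced_size=None, skipped=True))
                continue
            x_op = gamma_operate(x_prev, rng)
            x_op = stagnation_kick(x_op, x_prev, theta)
            x_d = gamma_correct(x_op, theta)
            active = np.flatnonzero(x_d)
            if active.size == 0:
                logger.warning("d=%d: empty active set after correction, iteration skipped", d)
                trace.append(SearchRecord(d=d, center=center, xi=xi, index_range=rng,
                                          population=0, stepwise_aic=None,
                                          reduced_size=None, skipped=True))
                x_prev = x_d
                continue
            step = stepwise_select(active, led_values, la)
            if step.aic < aic_optimal:
                optimal_set, aic_optimal = step.reduced_set, step.aic
            logger.info(
                "d=%d: center %.1f, xi %.4f, range [%d, %d], population %d, "
                "stepwise AIC %.2f (best %.2f)",
                d, center, xi, rng[0], rng[1], active.size, step.aic, aic_optimal,
            )
            trace.append(SearchRecord(d=d, center=center, xi=xi, index_range=rng,
                                      population=int(active.size), stepwise_aic=step.aic,
                                      reduced_size=len(step.reduced_set)))
            x_prev = x_d

        return _SearchOutcome(optimal_set=tuple(optimal_set), aic_optimal=aic_optimal, trace=trace)

    def fit(self) -> "MlrLDAcpResults":
        """Run the Γ search and fit the final OLS model on the optimal set."""
        return self._finalize(self._search())

    def fit_subset(self, positions) -> "MlrLDAcpResults":
        """Fit the final OLS on a prescribed candidate subset (0-based
        column positions), skipping the Γ search; useful for refitting a
        known selection or for significance calibration of a fixed model."""
        led_values = self.exog.to_numpy(dtype=float)
        positions = tuple(int(p) for p in positions)
        from .stepwise import model_aic

        aic = model_aic(led_values[:, list(positions)], self.endog.to_numpy(dtype=float))
        return self._finalize(_SearchOutcome(optimal_set=positions, aic_optimal=aic, trace=[]))

    def _finalize(self, outcome: _SearchOutcome) -> "MlrLDAcpResults":
        n = len(self.endog)
        selected = list(outcome.optimal_set)
        if len(selected) > n - 2:
            warnings.warn(
                f"optimal set of {len(selected)} exceeds n - 2 = {n - 2}; "
                "truncating to the smallest-P members",
                stacklevel=2,
            )
            selected = selected[: n - 2]

        design = self.exog.iloc[:, selected]
        # drop collinear columns before the final fit, keeping smaller-P ones
        if len(selected):
            keep, rank_now = [], 0
            for j in range(design.shape[1]):
                trial = design.iloc[:, keep + [j]].to_numpy()
                r = np.linalg.matrix_rank(np.column_stack([np.ones(n), trial]))
                if r > rank_now + 1:
                    keep.append(j)
                    rank_now = r - 1
                else:
                    logger.warning("dropping collinear column %s from final fit",
                                   design.columns[j])
            design = design.iloc[:, keep]
            selected = [selected[j] for j in keep]

        X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
        ols = sm.OLS(self.endog.to_numpy(dtype=float), X).fit()
        return MlrLDAcpResults(model=self, ols=ols,
                               selected_positions=tuple(selected),
                               selected_ids=tuple(design.columns),
                               search=outcome)


class MlrLDAcpResults:
    """Fit results: selected transcripts, coefficients Θ and diagnostics.

    Attributes
    ----------
    selected_ids : tuple of str
        Transcript identifiers of the selected subset (g_1..g_Δ).
    delta : int
        Number of selected transcripts Δ.
    theta : pandas.Series
        Intercept followed by one coefficient per selected transcript,
        in survival-days per expression unit.
    bse : pandas.Series
        Standard errors aligned with ``theta``.
    resid_se : float
        Residual standard error in days, on ``df_resid`` degrees of freedom.
    df_resid : int
        n − Δ − 1.
    model_p : float
        Overall F-test P value of the regression.
    aic : float
        AIC of the selected model under the search's convention.
    trace : list of SearchRecord
        Per-iteration record of the Γ search (center, xi, range,
        population, stepwise AIC).
    """

    def __init__(self, model: MlrLDAcp, ols, selected_positions: tuple[int, ...],
                 selected_ids: tuple[str, ...], search: _SearchOutcome):
        self.model = model
        self._ols = ols
        self.selected_positions = selected_positions
        self.selected_ids = selected_ids
        self.search = search
        self.trace = search.trace

        names = ["Intercept", *selected_ids]
        self.theta = pd.Series(ols.params, index=names, name="theta")
        self.params = self.theta
        self.bse = pd.Series(ols.bse, index=names, name="se")
        self.delta = len(selected_ids)
        self.df_resid = int(ols.df_resid)
        self.resid_se = float(np.sqrt(ols.ssr / ols.df_resid)) if ols.df_resid > 0 else float("nan")
        self.aic_optimal = search.aic_optimal
        # statsmodels' Gaussian AIC omits the variance parameter; +2 aligns
        # with the search's convention so the numbers are comparable
        self.aic = float(ols.aic) + 2.0

    @property
    def model_p(self) -> float:
        if self._ols.ssr <= 1e-10 * max(self._ols.centered_tss, 1.0):
            return 0.0
        p = float(self._ols.f_pvalue)
        return 0.0 if np.isnan(p) else p

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._ols.resid)

    def predict(self, exog: pd.DataFrame | None = None) -> pd.Series:
        """Predicted survival days for ``exog`` (default: the training
        matrix); ``exog`` must contain the selected transcript columns."""
        if exog is None:
            exog = self.model.exog
        missing = [t for t in self.selected_ids if t not in exog.columns]
        if missing:
            raise InputError(f"prediction input lacks selected transcripts: {missing[:5]}")
        X = exog[list(self.selected_ids)].to_numpy(dtype=float)
        pred = self.theta.iloc[0] + X @ self.theta.iloc[1:].to_numpy()
        return pd.Series(pred, index=exog.index, name="predicted_survival_days")

    def association_scores(self) -> pd.Series:
        """Per-transcript disease-association weight: the absolute
        standardized coefficient |Θ_j| · SD(g_j), zero for unselected
        transcripts."""
        scores = pd.Series(0.0, index=self.model.exog.columns, name="association_score")
        if self.delta:
            sd = self.model.exog[list(self.selected_ids)].std(ddof=1)
            scores[list(self.selected_ids)] = self.theta.iloc[1:].abs().to_numpy() * sd.to_numpy()
        return scores

    def coefficients_table(self) -> pd.DataFrame:
        """Serial number / transcript / coefficient table (intercept first)."""
        serial = ["Intercept"] + [f"X{p + 1}" for p in self.selected_positions]
        names = ["---------", *self.selected_ids]
        return pd.DataFrame({"serial": serial, "transcript": names,
                             "coefficient": self.theta.to_numpy()})

    def diagnostics(self) -> dict:
        return {
            "n_samples": int(self._ols.nobs),
            "n_selected": self.delta,
            "residual_se": self.resid_se,
            "df_resid": self.df_resid,
            "model_p": self.model_p,
            "aic": self.aic,
            "aic_optimal": self.aic_optimal,
        }

    def summary(self) -> str:
        """Human-readable report: search outcome, diagnostics, coefficients."""
        lines = [
            "Survival-time multiple linear regression (Gamma-operation selection)",
            "=" * 68,
            f"Samples: {int(self._ols.nobs)}   Candidates: {self.model.exog.shape[1]}   "
            f"Selected: {self.delta}",
            f"Residual standard error: {self.resid_se:.2f} on {self.df_resid} degrees of freedom",
            f"Overall model P value: {self.model_p:.3e}",
            f"AIC (selected model): {self.aic:.2f}   best search AIC: {self.aic_optimal:.2f}",
            "-" * 68,
            f"{'term':<20}{'theta':>16}{'std err':>14}",
        ]
        for name, coef, se in zip(self.theta.index, self.theta, self.bse):
            lines.append(f"{name:<20}{coef:>16.4g}{se:>14.4g}")
        return "\n".join(lines)


def run_search(
    led: pd.DataFrame,
    la,
    ranking: CandidateRanking,
    config: GammaConfig | None = None,
) -> MlrLDAcpResults:
    """Functional entry point: build the model and fit it in one call."""
    return MlrLDAcp(la, led, ranking=ranking, config=config).fit()
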