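"""Synthetic cohort generator.

Emulates the data layout the pipeline consumes: a normal and a tumor group of
lncRNA expression profiles in which a subset of transcripts carries a true
group mean shift, and a clinical table in the TCGA export dialect whose
survival response is a sparse linear combination of a planted causal
transcript subset plus Gaussian noise.  A censoring indicator mimics
``vital_status``: alive patients carry their time in
``days_to_last_follow_up``, dead patients in ``days_to_death``.

Censoring is assigned independently of survival time: the downstream response
vector treats follow-up time as the observed outcome for alive patients
without a censoring model, and the generator mirrors that simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["CohortSpec", "Cohort", "generate_cohort"]

#: shape of the reference cohort: 44 normal + 176 tumor samples, with 481
#: transcripts surviving the differential screen and 60 in the final model.
_DEFAULT_N_NORMAL = 44
_DEFAULT_N_TUMOR = 176


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    n_normal, n_tumor
        Sample counts for the two groups.
    n_transcripts
        Total transcripts simulated.
    n_differential
        Transcripts with a true group mean shift of ``effect_size``.
    n_causal
        Transcripts with a nonzero true survival coefficient; always a
        subset of the differential transcripts.
    effect_size
        Group mean shift, in expression units.
    true_coefficients
        Causal-effect weights (survival-days per expression unit).  When
        ``None`` they are drawn once from the seeded RNG as +/- pairs of
        equal magnitude, magnitudes uniform on [150, 450]/sqrt(n_causal)
        days.  The 1/sqrt(n_causal) scaling keeps the linear predictor's
        spread roughly constant as the causal set grows, and the paired
        signs cancel the planted effects in expectation, so survival times
        center on the intercept and stay positive (the floor at 1 day is
        an edge case, not the norm).  For odd n_causal the unpaired last
        coefficient shifts mean survival upward by roughly its magnitude
        times the mean causal expression.
    intercept
        Baseline survival time in days.
    noise_sd
        Survival-noise standard deviation in days.
    censor_fraction
        Fraction of tumor samples marked alive.
    seed
        RNG seed; identical seeds give bit-identical cohorts.
    """

    n_normal: int = _DEFAULT_N_NORMAL
    n_tumor: int = _DEFAULT_N_TUMOR
    n_transcripts: int = 600
    n_differential: int = 481
    n_causal: int = 60
    effect_size: float = 3.0
    true_coefficients: Sequence[float] | None = None
    intercept: float = 2500.0
    noise_sd: float = 30.0
    censor_fraction: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_normal", "n_tumor", "n_transcripts"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_differential < 0 or self.n_causal < 0:
            raise ConfigurationError("n_differential and n_causal must be nonnegative")
        if not (self.n_causal <= self.n_differential <= self.n_transcripts):
            raise ConfigurationError(
                "need n_causal <= n_differential <= n_transcripts, got "
                f"{self.n_causal} / {self.n_differential} / {self.n_transcripts}"
            )
        if not 0.0 <= self.censor_fraction <= 1.0:
            raise ConfigurationError(
                f"censor_fraction must lie in [0, 1], got {self.censor_fraction}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.true_coefficients is not None and len(self.true_coefficients) != self.n_causal:
            raise ConfigurationError(
                f"true_coefficients has length {len(self.true_coefficients)}, "
                f"expected n_causal={self.n_causal}"
            )


@dataclass
class Cohort:
    """A generated cohort plus its ground truth."""

    normal: pd.DataFrame  # samples x transcripts, nonnegative expression
    tumor: pd.DataFrame
    clinical: pd.DataFrame  # submitter_id / vital_status / days_to_death / days_to_last_follow_up
    truth: dict = field(default_factory=dict)


def _transcript_ids(n: int) -> list[str]:
    return [f"LNC{j + 1:05d}" for j in range(n)]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a synthetic two-group expression cohort with planted signal.

    Expression values are log-normal (meanlog 1, sdlog 0.5), so nonnegative
    like RPKM-style quantities.  Differential transcripts get an additive
    shift of ``effect_size`` in the tumor group.  Tumor survival time is

        ``intercept + sum_j coeff_j * expr_ij + N(0, noise_sd)``

    rounded to whole days and floored at 1.  Exactly
    ``round(censor_fraction * n_tumor)`` patients are marked alive.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    transcripts = _transcript_ids(spec.n_transcripts)
    normal_ids = [f"N{i + 1:04d}" for i in range(spec.n_normal)]
    tumor_ids = [f"T{i + 1:04d}" for i in range(spec.n_tumor)]

    normal = rng.lognormal(mean=1.0, sigma=0.5, size=(spec.n_normal, spec.n_transcripts))
    tumor = rng.lognormal(mean=1.0, sigma=0.5, size=(spec.n_tumor, spec.n_transcripts))

    diff_idx = np.sort(rng.choice(spec.n_transcripts, size=spec.n_differential, replace=False))
    causal_idx = np.sort(rng.choice(diff_idx, size=spec.n_causal, replace=False))
    tumor[:, diff_idx] += spec.effect_size

    if spec.true_coefficients is None:
        scale = 1.0 / np.sqrt(max(spec.n_causal, 1))
        magnitudes = rng.uniform(150.0, 450.0, size=(spec.n_causal + 1) // 2) * scale
        paired = np.repeat(magnitudes, 2)[: spec.n_causal]
        signs = np.where(np.arange(spec.n_causal) % 2 == 0, 1.0, -1.0)
        coeffs = paired * signs
    else:
        coeffs = np.asarray(spec.true_coefficients, dtype=float)

    linear = spec.intercept + tumor[:, causal_idx] @ coeffs if spec.n_causal else np.full(
        spec.n_tumor, spec.intercept
    )
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_tumor) if spec.noise_sd > 0 else 0.0
    survival_days = np.maximum(np.rint(linear + noise), 1.0).astype(int)

    n_alive = int(round(spec.censor_fraction * spec.n_tumor))
    alive_idx = rng.choice(spec.n_tumor, size=n_alive, replace=False)
    alive = np.zeros(spec.n_tumor, dtype=bool)
    alive[alive_idx] = True

    clinical = pd.DataFrame(
        {
            "submitter_id": tumor_ids,
            "vital_status": np.where(alive, "alive", "dead"),
            "days_to_death": np.where(alive, np.nan, survival_days.astype(float)),
            "days_to_last_follow_up": np.where(alive, survival_days.astype(float), np.nan),
        }
    )

    truth = {
        "causal_transcripts": [transcripts[j] for j in causal_idx],
        "differential_transcripts": [transcripts[j] for j in diff_idx],
        "coefficients": dict(zip((transcripts[j] for j in causal_idx), coeffs.tolist())),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }

    return Cohort(
        normal=pd.DataFrame(normal, index=normal_ids, columns=transcripts),
        tumor=pd.DataFrame(tumor, index=tumor_ids, columns=transcripts),
        clinical=clinical,
        truth=truth,
    )
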