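"""Synthetic "cynicism study" generator.

Emulates the fictional empirical example used throughout the sensitivity
workflow: n = 100 participants, a binary ``sex`` predictor (men coded 1), a
continuous ``lack_of_trust`` predictor, and a continuous ``cynicism``
outcome.  The real study dataset is not publicly reconstructible, so this is
an emulation, not a replication: the default true effects sit at the centres
of the original analysis priors (trust effect 6, sex effect 0), and the
variable scales are arbitrary choices since the instrument scales of the
fictional study are never stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ConfigurationError, RegressionData

__all__ = ["FixtureSpec", "make_cynicism_like_dataset"]


@dataclass(frozen=True)
class FixtureSpec:
    """Generating values for the synthetic cynicism dataset."""

    n: int = 100
    sex_probability: float = 0.5
    trust_mean: float = 3.0
    trust_sd: float = 1.0
    intercept: float = 10.0
    sex_effect: float = 0.0
    trust_effect: float = 6.0
    residual_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ConfigurationError("fixture requires n >= 10")
        if not 0 < self.sex_probability < 1:
            raise ConfigurationError("sex_probability must lie in (0, 1)")
        if self.trust_sd <= 0:
            raise ConfigurationError("trust_sd must be positive")
        if self.residual_sd < 0:
            raise ConfigurationError("residual_sd must be non-negative")


def make_cynicism_like_dataset(spec: FixtureSpec = FixtureSpec()) -> RegressionData:
    """Generate the synthetic dataset; reproducible given ``spec.seed``.

    cynicism = intercept + sex_effect * sex + trust_effect * lack_of_trust
               + N(0, residual_sd^2)
    """
    rng = np.random.default_rng(spec.seed)
    sex = (rng.random(spec.n) < spec.sex_probability).astype(float)
    trust = rng.normal(spec.trust_mean, spec.trust_sd, size=spec.n)
    noise = rng.normal(0.0, spec.residual_sd, size=spec.n) if spec.residual_sd > 0 else 0.0
    cynicism = spec.intercept + spec.sex_effect * sex + spec.trust_effect * trust + noise
    return RegressionData(
        outcome=cynicism,
        predictors=np.column_stack([sex, trust]),
        predictor_names=("sex", "lack_of_trust"),
    )
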