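"""Prior sensitivity analysis: re-fit a regression under competing prior sets
and compare the posteriors.

The procedure follows the standard workflow: fix an original (comparison)
prior set, specify named alternatives -- each replacing the prior of exactly
one parameter, or a "combined" alternative replacing several at once -- refit
the model under each, check convergence of every analysis, and compare
posterior summaries through percent deviations of the posterior means and
whether zero enters or leaves the HPD interval (the substantive-conclusion
check).  The original prior set is never modified.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import ConvergenceReport, convergence_report
from .model_core import (
    ChainSettings,
    ConfigurationError,
    FixedResidualVariance,
    InverseGammaPrior,
    NormalPrior,
    PosteriorChain,
    PosteriorSummary,
    PriorSet,
    RegressionData,
    gibbs_regression,
    summarize_posterior,
)

__all__ = [
    "Alternative",
    "SensitivityPlan",
    "AnalysisResult",
    "SensitivityResult",
    "percent_deviation",
    "zero_in_hpd",
    "density_grid",
    "DensityGrid",
    "run_sensitivity",
    "label_seed",
]

ORIGINAL_LABEL = "original"


@dataclass(frozen=True)
class Alternative:
    """One competing prior specification.

    ``replacements`` maps parameter names (``intercept``, a predictor name,
    or ``residual_variance``) to replacement priors.  A single-parameter
    alternative has exactly one entry; an entry with several is a "combined"
    analysis.  All other priors are held at the original.
    """

    label: str
    replacements: dict

    def __post_init__(self) -> None:
        if not self.replacements:
            raise ConfigurationError(f"alternative '{self.label}' replaces no priors")
        if self.label == ORIGINAL_LABEL:
            raise ConfigurationError(f"'{ORIGINAL_LABEL}' is reserved for the original analysis")

    @property
    def combined(self) -> bool:
        return len(self.replacements) > 1

    def applied_to(self, original: PriorSet, data: RegressionData) -> PriorSet:
        """Build the alternative PriorSet, leaving the original untouched."""
        coeffs = list(original.coefficients)
        kwargs = {}
        for target, prior in self.replacements.items():
            if target == "intercept":
                if not isinstance(prior, NormalPrior):
                    raise ConfigurationError("intercept prior must be a NormalPrior")
                kwargs["intercept"] = prior
            elif target == "residual_variance":
                if not isinstance(prior, (InverseGammaPrior, FixedResidualVariance)):
                    raise ConfigurationError(
                        "residual_variance prior must be inverse-gamma (or fixed)"
                    )
                kwargs["residual_variance"] = prior
            elif target in data.predictor_names:
                if not isinstance(prior, NormalPrior):
                    raise ConfigurationError("coefficient priors must be NormalPrior")
                coeffs[data.predictor_names.index(target)] = prior
            else:
                raise ConfigurationError(
                    f"alternative '{self.label}' targets unknown parameter '{target}'"
                )
        return replace(original, coefficients=tuple(coeffs), label=self.label, **kwargs)


@dataclass(frozen=True)
class SensitivityPlan:
    """The original prior set plus named alternatives and the HPD level."""

    original: PriorSet
    alternatives: tuple[Alternative, ...] = ()
    level: float = 0.90

    def __post_init__(self) -> None:
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        labels = [a.label for a in self.alternatives]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate alternative labels: {labels}")
        if not 0 < self.level < 1:
            raise ConfigurationError("HPD level must lie in (0, 1)")


@dataclass(frozen=True)
class AnalysisResult:
    """Everything retained for one analysis (original or alternative)."""

    label: str
    priors: PriorSet
    chain: PosteriorChain
    summary: PosteriorSummary
    convergence: ConvergenceReport
    densities: dict  # parameter -> DensityGrid
    seed: int


@dataclass(frozen=True)
class DensityGrid:
    """Kernel density estimate of a posterior sample on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class SensitivityResult:
    """Ordered analyses plus the per-parameter comparison table.

    ``comparison`` has one row per (analysis, parameter) with the posterior
    estimate, SD, HPD bounds, the original analysis's estimate, the percent
    deviation from it, whether zero lies inside the HPD interval, and whether
    that conclusion differs from the original's.
    """

    analyses: dict  # label -> AnalysisResult, insertion-ordered, original first
    comparison: pd.DataFrame
    level: float

    @property
    def original(self) -> AnalysisResult:
        return self.analyses[ORIGINAL_LABEL]

    def deviation(self, label: str, parameter: str) -> float:
        mask = (self.comparison["analysis"] == label) & (
            self.comparison["parameter"] == parameter
        )
        return float(self.comparison.loc[mask, "percent_deviation"].iloc[0])


def percent_deviation(
    original_mean: float, alternative_mean: float, tolerance: float = 1e-8
) -> float:
    """(alternative - original) / original * 100.

    A downward shift from a positive original estimate is negative.  When the
    original mean is within ``tolerance`` of zero the deviation is undefined
    and NaN is returned (reported, never raised).
    """
    if abs(original_mean) <= tolerance:
        return float("nan")
    return (alternative_mean - original_mean) / original_mean * 100.0


def zero_in_hpd(summary: PosteriorSummary, parameter: str) -> bool:
    """True iff the (closed) HPD interval of ``parameter`` contains zero."""
    lo, hi = summary.hpd(parameter)
    return lo <= 0.0 <= hi


def density_grid(samples: np.ndarray, n_points: int = 512) -> DensityGrid:
    """Gaussian KDE (Silverman bandwidth) evaluated on ``n_points`` points
    spanning min - 3h to max + 3h, h being the kernel bandwidth.

    Degenerate (zero-variance) samples yield a flagged spike representation
    rather than an error.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size < 10:
        raise ConfigurationError("density estimation requires at least 10 samples")
    if np.std(samples) == 0:
        c = float(samples[0])
        return DensityGrid(grid=np.array([c]), density=np.array([np.inf]), degenerate=True)
    kde = stats.gaussian_kde(samples, bw_method="silverman")
    h = float(kde.factor * np.std(samples, ddof=1))
    grid = np.linspace(samples.min() - 3 * h, samples.max() + 3 * h, n_points)
    return DensityGrid(grid=grid, density=kde(grid))


def label_seed(base_seed: int, label: str) -> int:
    """Stable per-analysis seed: adding alternatives never perturbs earlier
    results, and permuting the alternatives list permutes but does not change
    them."""
    return int((int(base_seed) + zlib.crc32(label.encode("utf-8"))) % (2**31))


def _analyse(
    data: RegressionData,
    priors: PriorSet,
    settings: ChainSettings,
    label: str,
    level: float,
) -> AnalysisResult:
    seed = label_seed(settings.seed, label)
    chain = gibbs_regression(data, priors, replace(settings, seed=seed))
    summary = summarize_posterior(chain, level)
    report = convergence_report(chain)
    densities = {
        name: density_grid(chain.parameter(name)) for name in chain.parameter_names
    }
    return AnalysisResult(
        label=label,
        priors=priors,
        chain=chain,
        summary=summary,
        convergence=report,
        densities=densities,
        seed=seed,
    )


def run_sensitivity(
    data: RegressionData,
    plan: SensitivityPlan,
    settings: ChainSettings,
) -> SensitivityResult:
    """Run the original analysis and every alternative, then compare.

    Every analysis -- converged or not -- appears in the result with its
    convergence report; non-convergence is flagged, never dropped (it can
    itself be evidence against a prior).  All parameters are reported for
    every analysis, not only the targeted one: replacing one prior can move
    other posteriors.
    """
    plan.original.paired_with(data)
    analyses: dict[str, AnalysisResult] = {}
    analyses[ORIGINAL_LABEL] = _analyse(
        data, plan.original, settings, ORIGINAL_LABEL, plan.level
    )
    for alt in plan.alternatives:
        alt_priors = alt.applied_to(plan.original, data)
        analyses[alt.label] = _analyse(data, alt_priors, settings, alt.label, plan.level)

    original_summary = analyses[ORIGINAL_LABEL].summary
    rows = []
    for label, result in analyses.items():
        for parameter in result.chain.parameter_names:
            est = result.summary.mean(parameter)
            lo, hi = result.summary.hpd(parameter)
            orig_est = original_summary.mean(parameter)
            dev = 0.0 if label == ORIGINAL_LABEL else percent_deviation(orig_est, est)
            z_in = zero_in_hpd(result.summary, parameter)
            rows.append(
                {
                    "analysis": label,
                    "parameter": parameter,
                    "estimate": est,
                    "sd": float(result.summary.table.loc[parameter, "sd"]),
                    "hpd_lower": lo,
                    "hpd_upper": hi,
                    "original_estimate": orig_est,
                    "percent_deviation": dev,
                    "zero_in_hpd": z_in,
                    "conclusion_changed": z_in != zero_in_hpd(original_summary, parameter),
                    "converged": bool(result.convergence.table.loc[parameter, "converged"]),
                }
            )
    comparison = pd.DataFrame(rows)
    return SensitivityResult(analyses=analyses, comparison=comparison, level=plan.level)
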