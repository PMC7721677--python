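"""Conjugate Bayesian normal linear regression fitted by Gibbs sampling.

The model is

    y_i = b0 + x_i' b + e_i,    e_i ~ N(0, sigma^2),

with independent normal priors on the intercept and each regression
coefficient and an inverse-gamma prior on the residual variance.  Because the
priors are conditionally conjugate, the Gibbs sampler alternates two exact
draws:

* coefficients given sigma^2: multivariate normal with covariance
  ``(V0^-1 + X'X / sigma^2)^-1`` and mean ``cov @ (V0^-1 mu0 + X'y / sigma^2)``,
  drawn as one block;
* sigma^2 given coefficients: inverse-gamma ``IG(a0 + n/2, b0 + RSS/2)``.

Normal priors are parameterized as (mean, VARIANCE) throughout -- the second
hyperparameter is never a standard deviation or a precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "EstimationError",
    "RegressionData",
    "NormalPrior",
    "InverseGammaPrior",
    "FixedResidualVariance",
    "PriorSet",
    "ChainSettings",
    "PosteriorChain",
    "PosteriorSummary",
    "gibbs_regression",
    "summarize_posterior",
    "hpd_interval",
]


class ConfigurationError(ValueError):
    """Invalid inputs, priors or settings (user-fixable before estimation)."""


class EstimationError(RuntimeError):
    """The sampler cannot produce a proper draw (e.g. improper conditional)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionData:
    """A single continuous outcome and a fixed n x p predictor matrix.

    The intercept column is *not* stored; it is added internally by the
    sampler.  Requires n >= p + 2 so the design has residual degrees of
    freedom, and no missing values.
    """

    outcome: np.ndarray
    predictors: np.ndarray
    predictor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome, dtype=float)
        x = np.asarray(self.predictors, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if y.ndim != 1:
            raise ConfigurationError("outcome must be a 1-D vector")
        if x.shape[0] != y.shape[0]:
            raise ConfigurationError(
                f"outcome has {y.shape[0]} rows but predictors have {x.shape[0]}"
            )
        names = tuple(str(n) for n in self.predictor_names)
        if len(names) != x.shape[1]:
            raise ConfigurationError(
                f"{len(names)} predictor names for {x.shape[1]} predictor columns"
            )
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
            raise ConfigurationError("missing or non-finite values are not supported")
        if y.shape[0] < x.shape[1] + 2:
            raise ConfigurationError(
                f"need n >= p + 2 observations (got n={y.shape[0]}, p={x.shape[1]})"
            )
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "predictors", x)
        object.__setattr__(self, "predictor_names", names)

    @property
    def n(self) -> int:
        return self.outcome.shape[0]

    @property
    def p(self) -> int:
        return self.predictors.shape[1]

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, outcome: str, predictors: list[str]
    ) -> "RegressionData":
        missing = [c for c in [outcome, *predictors] if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"columns not found in dataset: {missing}")
        return cls(
            outcome=frame[outcome].to_numpy(dtype=float),
            predictors=frame[list(predictors)].to_numpy(dtype=float),
            predictor_names=tuple(predictors),
        )

    @classmethod
    def from_csv(cls, path, outcome: str, predictors: list[str]) -> "RegressionData":
        return cls.from_dataframe(pd.read_csv(path), outcome, predictors)

    def to_dataframe(self, outcome_name: str = "y") -> pd.DataFrame:
        frame = pd.DataFrame(self.predictors, columns=list(self.predictor_names))
        frame.insert(0, outcome_name, self.outcome)
        return frame


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior N(mean, variance).

    ``variance`` is a VARIANCE (squared outcome units), matching the
    N(mean, variance) convention used for all location priors here -- it is
    not a standard deviation and not a precision.
    """

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ConfigurationError("normal prior mean must be finite")
        if not (self.variance > 0 and math.isfinite(self.variance)):
            raise ConfigurationError(
                f"normal prior variance must be positive and finite, got {self.variance}"
            )


@dataclass(frozen=True)
class InverseGammaPrior:
    """Inverse-gamma prior IG(shape, scale) for the residual variance.

    Improper settings (shape <= 0 or scale <= 0, e.g. the IG(-1, 0) flat
    prior on sigma^2) are permitted but must be acknowledged by passing
    ``proper_flag=False``.
    """

    shape: float
    scale: float
    proper_flag: bool = True

    def __post_init__(self) -> None:
        is_proper = self.shape > 0 and self.scale > 0
        if self.proper_flag and not is_proper:
            raise ConfigurationError(
                f"IG({self.shape}, {self.scale}) is improper; "
                "pass proper_flag=False to use it deliberately"
            )
        if not self.proper_flag and is_proper:
            object.__setattr__(self, "proper_flag", True)


@dataclass(frozen=True)
class FixedResidualVariance:
    """Degenerate residual-variance prior: sigma^2 held fixed at ``value``."""

    value: float

    def __post_init__(self) -> None:
        if not (self.value > 0 and math.isfinite(self.value)):
            raise ConfigurationError("fixed residual variance must be positive")


#: Flat (improper) prior on sigma^2; the simulation-software default.
DEFAULT_RESIDUAL_PRIOR = InverseGammaPrior(-1.0, 0.0, proper_flag=False)
#: Near-flat normal prior used for the intercept when none is specified.
DEFAULT_INTERCEPT_PRIOR = NormalPrior(0.0, 1e10)


@dataclass(frozen=True)
class PriorSet:
    """Priors for every parameter of one regression analysis."""

    intercept: NormalPrior = DEFAULT_INTERCEPT_PRIOR
    coefficients: tuple[NormalPrior, ...] = ()
    residual_variance: InverseGammaPrior | FixedResidualVariance = DEFAULT_RESIDUAL_PRIOR
    label: str = "original"

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(self.coefficients))

    def paired_with(self, data: RegressionData) -> "PriorSet":
        """Validate this prior set against a dataset (coefficient count)."""
        if len(self.coefficients) != data.p:
            raise ConfigurationError(
                f"prior set '{self.label}' has {len(self.coefficients)} coefficient "
                f"priors but the data has {data.p} predictors"
            )
        return self


@dataclass(frozen=True)
class ChainSettings:
    """MCMC run-length settings; defaults follow the reference study design
    (5,000 iterations, first half discarded as burn-in, a single chain)."""

    total_iterations: int = 5000
    burn_in: int | None = None
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_iterations < 2:
            raise ConfigurationError("total_iterations must be at least 2")
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", self.total_iterations // 2)
        if not 0 <= self.burn_in < self.total_iterations:
            raise ConfigurationError(
                f"burn_in must lie in [0, total_iterations), got {self.burn_in}"
            )
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be positive")

    @property
    def kept(self) -> int:
        return self.total_iterations - self.burn_in


class PosteriorChain:
    """Raw MCMC draws with the burn-in boundary.

    Parameter order is (intercept, coefficients..., residual variance); when
    fitted without an intercept the leading column is absent.
    """

    def __init__(
        self,
        full_draws: np.ndarray,
        settings: ChainSettings,
        parameter_names: list[str],
    ) -> None:
        full_draws = np.asarray(full_draws, dtype=float)
        if full_draws.ndim == 2:
            full_draws = full_draws[None]
        if full_draws.shape[0] != settings.n_chains:
            raise ConfigurationError("chain count does not match settings")
        if full_draws.shape[1] != settings.total_iterations:
            raise ConfigurationError("iteration count does not match settings")
        if full_draws.shape[2] != len(parameter_names):
            raise ConfigurationError("parameter count does not match names")
        self.full_draws = full_draws
        self.settings = settings
        self.burn_in = settings.burn_in
        self.parameter_names = list(parameter_names)

    @property
    def kept_per_chain(self) -> np.ndarray:
        """Post-burn-in draws, shape (n_chains, kept, n_params)."""
        return self.full_draws[:, self.burn_in :, :]

    @property
    def draws(self) -> np.ndarray:
        """Post-burn-in draws pooled across chains, shape (kept_total, n_params)."""
        kept = self.kept_per_chain
        return kept.reshape(-1, kept.shape[-1])

    def parameter(self, name: str) -> np.ndarray:
        """Pooled kept draws for one named parameter."""
        return self.draws[:, self.parameter_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Full chain as a tidy table: chain, iteration, phase, one column
        per parameter (the trace-plot export format)."""
        frames = []
        for c in range(self.full_draws.shape[0]):
            frame = pd.DataFrame(self.full_draws[c], columns=self.parameter_names)
            frame.insert(0, "phase", np.where(
                np.arange(len(frame)) < self.burn_in, "burn_in", "kept"))
            frame.insert(0, "iteration", np.arange(1, len(frame) + 1))
            frame.insert(0, "chain", c + 1)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean, SD and HPD interval per parameter (kept draws only)."""

    table: pd.DataFrame  # index: parameter; columns: mean, sd, hpd_lower, hpd_upper
    hpd_level: float

    def mean(self, parameter: str) -> float:
        return float(self.table.loc[parameter, "mean"])

    def hpd(self, parameter: str) -> tuple[float, float]:
        row = self.table.loc[parameter]
        return float(row["hpd_lower"]), float(row["hpd_upper"])


# ---------------------------------------------------------------------------
# sampler engine
# ---------------------------------------------------------------------------


def _prior_vectors(
    priors: PriorSet, p: int, fit_intercept: bool
) -> tuple[np.ndarray, np.ndarray]:
    locs = list(priors.coefficients)
    if fit_intercept:
        locs = [priors.intercept, *locs]
    mu0 = np.array([pr.mean for pr in locs])
    v0 = np.array([pr.variance for pr in locs])
    return mu0, v0


def _pregenerate(
    rng: np.random.Generator,
    total: int,
    k: int,
    gamma_shape: float | None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw all raw randomness a chain needs up front.

    The gamma shape ``a0 + n/2`` does not change across iterations, so the
    gamma variates for the sigma^2 conditional can be pre-generated; this is
    what lets the batched engine reproduce single-dataset runs exactly.
    """
    z = rng.standard_normal((total, k))
    g = None
    if gamma_shape is not None:
        g = rng.gamma(gamma_shape, 1.0, size=total)
    return z, g


def gibbs_batch(
    xtx: np.ndarray,
    xty: np.ndarray,
    yty: np.ndarray,
    n_obs: int,
    mu0: np.ndarray,
    v0: np.ndarray,
    residual_prior: InverseGammaPrior | FixedResidualVariance,
    total_iterations: int,
    seeds: list,
    init_sigma2: np.ndarray,
) -> np.ndarray:
    """Run ``B`` independent Gibbs chains that share priors and n.

    Vectorized across the batch axis; used both for single fits (B = 1) and
    for simulation cells (B = number of replications).  Each batch member has
    its own seed (int, SeedSequence or Generator), so results are independent
    of batch composition and execution order.

    Parameters are the sufficient statistics per dataset: ``xtx`` (B, k, k),
    ``xty`` (B, k), ``yty`` (B,).  Returns draws of shape (B, T, k + 1) with
    sigma^2 in the last column.
    """
    xtx = np.asarray(xtx, dtype=float)
    xty = np.asarray(xty, dtype=float)
    yty = np.asarray(yty, dtype=float)
    if xtx.ndim == 2:
        xtx, xty, yty = xtx[None], xty[None], np.atleast_1d(yty)
    batch, k = xty.shape

    fixed = isinstance(residual_prior, FixedResidualVariance)
    if fixed:
        gamma_shape = None
        b0 = 0.0
    else:
        a0, b0 = residual_prior.shape, residual_prior.scale
        gamma_shape = a0 + n_obs / 2.0
        if gamma_shape <= 0:
            raise EstimationError(
                f"residual-variance conditional is improper: shape a0 + n/2 = "
                f"{gamma_shape} <= 0 for IG({a0}, {b0}) with n = {n_obs}"
            )

    z = np.empty((batch, total_iterations, k))
    g = np.empty((batch, total_iterations)) if not fixed else None
    for i, seed in enumerate(seeds):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        z[i], gi = _pregenerate(rng, total_iterations, k, gamma_shape)
        if gi is not None:
            g[i] = gi

    v0inv = 1.0 / v0
    rhs0 = v0inv * mu0
    v0inv_diag = np.diag(v0inv)

    sigma2 = np.asarray(init_sigma2, dtype=float).copy()
    if sigma2.shape != (batch,):
        sigma2 = np.broadcast_to(sigma2, (batch,)).copy()
    out = np.empty((batch, total_iterations, k + 1))

    for t in range(total_iterations):
        inv_s2 = 1.0 / sigma2
        prec = v0inv_diag[None, :, :] + xtx * inv_s2[:, None, None]
        rhs = rhs0[None, :] + xty * inv_s2[:, None]
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
        # noise with covariance prec^-1: solve L' u = z
        noise = np.linalg.solve(np.swapaxes(chol, 1, 2), z[:, t, :, None])[..., 0]
        beta = mean + noise
        if fixed:
            sigma2[:] = residual_prior.value
        else:
            # shape-stable contraction order so a chain is bit-identical
            # whether run alone or inside a batch
            xtx_beta = np.matmul(xtx, beta[:, :, None])[:, :, 0]
            rss = yty - 2.0 * (beta * xty).sum(axis=1) + (beta * xtx_beta).sum(axis=1)
            scale = b0 + 0.5 * rss
            if np.any(scale <= 0):
                raise EstimationError(
                    f"residual-variance conditional has non-positive scale "
                    f"(b0 + RSS/2 <= 0) under IG({a0}, {b0}); the prior scale "
                    "hyperparameter is too small for this data"
                )
            sigma2 = scale / g[:, t]
        out[:, t, :k] = beta
        out[:, t, k] = sigma2
    return out


def gibbs_regression(
    data: RegressionData,
    priors: PriorSet,
    settings: ChainSettings,
    fit_intercept: bool = True,
) -> PosteriorChain:
    """Fit the regression by block Gibbs sampling.

    The coefficient vector is drawn jointly (one multivariate-normal draw per
    iteration) rather than one coordinate at a time, which keeps chain
    autocorrelation near zero for this model.  Draws are reproducible given
    ``settings.seed``; chain ``c`` uses seed ``seed + c``.
    """
    priors.paired_with(data)
    x = data.predictors
    if fit_intercept:
        x = np.column_stack([np.ones(data.n), x])
        names = ["intercept", *data.predictor_names, "residual_variance"]
    else:
        names = [*data.predictor_names, "residual_variance"]
    y = data.outcome

    if isinstance(priors.residual_variance, InverseGammaPrior):
        if not priors.residual_variance.proper_flag and data.n <= data.p + 2:
            raise ConfigurationError(
                "improper residual-variance prior requires n > p + 2"
            )

    mu0, v0 = _prior_vectors(priors, data.p, fit_intercept)
    xtx = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)
    if isinstance(priors.residual_variance, FixedResidualVariance):
        init = np.array([priors.residual_variance.value])
    else:
        init = np.array([float(np.var(y, ddof=1))])
        if init[0] <= 0:
            raise ConfigurationError("outcome has zero variance; cannot initialise sigma^2")

    chains = []
    for c in range(settings.n_chains):
        draws = gibbs_batch(
            xtx[None],
            xty[None],
            np.array([yty]),
            data.n,
            mu0,
            v0,
            priors.residual_variance,
            settings.total_iterations,
            [int(settings.seed) + c],
            init,
        )
        chains.append(draws[0])
    return PosteriorChain(np.stack(chains), settings, names)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def hpd_interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest contiguous window containing ``ceil(level * N)`` sorted samples.

    Ties in window width are broken toward the lowest lower bound.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size < 2:
        raise ConfigurationError("HPD requires a 1-D vector of at least 2 samples")
    if not 0 < level < 1:
        raise ConfigurationError(f"HPD level must lie in (0, 1), got {level}")
    if not np.all(np.isfinite(samples)):
        raise ConfigurationError("HPD samples must be finite")
    ordered = np.sort(samples)
    n = ordered.size
    m = math.ceil(level * n)
    m = max(m, 1)
    if m >= n:
        return float(ordered[0]), float(ordered[-1])
    widths = ordered[m - 1 :] - ordered[: n - m + 1]
    start = int(np.argmin(widths))  # argmin takes the first minimum: lowest lower bound
    return float(ordered[start]), float(ordered[start + m - 1])


def summarize_posterior(chain: PosteriorChain, level: float = 0.90) -> PosteriorSummary:
    """Posterior mean, SD and HPD interval per parameter over kept draws only."""
    draws = chain.draws
    if draws.shape[0] < 2:
        raise ConfigurationError("need at least 2 kept draws to summarize")
    rows = {}
    for j, name in enumerate(chain.parameter_names):
        col = draws[:, j]
        lo, hi = hpd_interval(col, level)
        rows[name] = {
            "mean": float(np.mean(col)),
            "sd": float(np.std(col, ddof=1)),
            "hpd_lower": lo,
            "hpd_upper": hi,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return PosteriorSummary(table=table, hpd_level=level)
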