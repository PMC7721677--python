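"""Convergence and mixing diagnostics for posterior chains.

Implements the classic (non-rank-normalized) split-chain potential scale
reduction factor, an autocorrelation-based effective sample size with
Geyer's initial-monotone-positive-pair truncation, the Geweke head/tail
mean-comparison z score, and a per-parameter pass/fail convergence report
with the thresholds R-hat < 1.01 and ESS > 1,000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ConfigurationError, PosteriorChain

__all__ = [
    "DegenerateChainError",
    "potential_scale_reduction",
    "effective_sample_size",
    "geweke_z",
    "convergence_report",
    "ConvergenceReport",
]


class DegenerateChainError(ValueError):
    """A chain with no internal variance, for which the diagnostic is undefined."""


def _as_segments(chains, split: bool | None) -> np.ndarray:
    """Normalize input to a (m, L) segment array.

    A single chain is split into halves (split-R-hat); multiple chains are
    used as segments directly unless ``split=True``.  Odd lengths drop the
    middle element so both halves have equal length.
    """
    if isinstance(chains, (list, tuple)):
        arr = [np.asarray(c, dtype=float) for c in chains]
    else:
        a = np.asarray(chains, dtype=float)
        arr = [a] if a.ndim == 1 else [a[i] for i in range(a.shape[0])]
    lengths = {len(c) for c in arr}
    if len(lengths) != 1:
        raise ConfigurationError("all chains must have equal length")
    if split is None:
        split = len(arr) == 1
    if split:
        halves = []
        for c in arr:
            half = len(c) // 2
            halves.append(c[:half])
            halves.append(c[len(c) - half :])
        arr = halves
    segments = np.asarray(arr, dtype=float)
    if segments.shape[0] < 2:
        raise ConfigurationError("need at least 2 segments after splitting")
    if segments.shape[1] < 2:
        raise ConfigurationError("each segment must have at least 2 samples")
    return segments


def potential_scale_reduction(chains, split: bool | None = None) -> float:
    """Gelman-Rubin PSRF (R-hat) over chain segments.

    With m segments of length L: W = mean of within-segment variances,
    B = L * variance of segment means, and

        R-hat = sqrt(((L - 1)/L * W + B/L) / W).

    A single chain is first split into halves ("split-R-hat").  Values near 1
    indicate stationarity; the floor is sqrt((L - 1)/L).
    """
    segments = _as_segments(chains, split)
    m, L = segments.shape
    w = float(np.mean(np.var(segments, axis=1, ddof=1)))
    if w <= 0:
        raise DegenerateChainError(
            "zero within-segment variance; R-hat is undefined for a constant chain"
        )
    b = L * float(np.var(np.mean(segments, axis=1), ddof=1))
    var_plus = (L - 1) / L * w + b / L
    return float(np.sqrt(var_plus / w))


def _tau_from_pairs(gamma_pairs: np.ndarray) -> np.ndarray:
    """Integrated autocorrelation time from paired autocorrelations.

    ``gamma_pairs[..., m] = rho[2m] + rho[2m + 1]``.  Geyer's initial
    monotone positive sequence: keep pairs while they remain positive,
    enforce a non-increasing sequence, then tau = 2 * sum - 1.
    """
    positive = gamma_pairs > 0
    # first index where the pair sum is no longer positive, per series
    keep = np.cumprod(positive, axis=-1).astype(bool)
    mono = np.minimum.accumulate(np.where(keep, gamma_pairs, 0.0), axis=-1)
    tau = 2.0 * np.sum(np.where(keep, mono, 0.0), axis=-1) - 1.0
    # antithetic chains can drive the pair sums to zero; keep tau positive so
    # the raw ESS stays finite (it may legitimately exceed N and is capped
    # only when applying the convergence threshold)
    return np.maximum(tau, 1e-12)


def _ess_stack(series: np.ndarray) -> np.ndarray:
    """ESS for a stack of series along the last axis (FFT autocovariance)."""
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    x = x - x.mean(axis=-1, keepdims=True)
    var = np.einsum("...i,...i->...", x, x) / n
    if np.any(var <= 0):
        raise DegenerateChainError("zero-variance chain; ESS is undefined")
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, size, axis=-1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=-1)[..., :n] / n
    rho = acov / var[..., None]
    n_pairs = n // 2
    pairs = rho[..., : 2 * n_pairs].reshape(*rho.shape[:-1], n_pairs, 2).sum(axis=-1)
    tau = _tau_from_pairs(pairs)
    return n / tau


def effective_sample_size(samples: np.ndarray) -> float:
    """ESS = N / (1 + 2 * sum of autocorrelations), truncated by Geyer's
    initial-monotone-positive-pair rule.

    Independent draws give ESS approximately N.  Antithetic chains can give a
    raw value above N; it is returned as-is (the convergence report caps it
    at N when applying the threshold).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size < 4:
        raise ConfigurationError("ESS requires a 1-D vector of at least 4 samples")
    return float(_ess_stack(samples))


def _spectral_variance_at_zero(window: np.ndarray) -> float:
    """Bartlett-tapered estimate of the spectral density at frequency zero,
    with lag truncation at 4% of the window length."""
    n = window.size
    x = window - window.mean()
    max_lag = max(1, int(0.04 * n))
    s = float(x @ x) / n
    for k in range(1, max_lag + 1):
        gamma_k = float(x[:-k] @ x[k:]) / n
        s += 2.0 * (1.0 - k / (max_lag + 1.0)) * gamma_k
    return max(s, 0.0)


def geweke_z(
    samples: np.ndarray,
    head_fraction: float = 0.10,
    tail_fraction: float = 0.50,
) -> float:
    """Geweke diagnostic: z score for equality of head and tail window means.

        z = (mean_head - mean_tail) / sqrt(S_head/n_head + S_tail/n_tail)

    where S is the spectral density at zero of each window.  Approximately
    standard normal when the chain is stationary.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ConfigurationError("geweke_z expects a 1-D vector")
    n = samples.size
    n_head = int(head_fraction * n)
    n_tail = int(tail_fraction * n)
    if n_head < 10 or n_tail < 10:
        raise ConfigurationError(
            f"both windows need at least 10 samples (head={n_head}, tail={n_tail})"
        )
    if n_head + n_tail > n:
        raise ConfigurationError("head and tail windows overlap")
    head = samples[:n_head]
    tail = samples[n - n_tail :]
    return _combine_geweke(
        head.mean(), _spectral_variance_at_zero(head), n_head,
        tail.mean(), _spectral_variance_at_zero(tail), n_tail,
    )


def _combine_geweke(
    mean_a: float, s_a: float, n_a: int, mean_b: float, s_b: float, n_b: int
) -> float:
    """z = (mean_a - mean_b) / sqrt(S_a/n_a + S_b/n_b)."""
    var = s_a / n_a + s_b / n_b
    if var <= 0:
        raise DegenerateChainError("zero spectral variance in both windows")
    return float((mean_a - mean_b) / np.sqrt(var))


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter diagnostics with pass/fail flags.

    ``converged`` per parameter is (R-hat < rhat_max) AND (capped ESS >
    ess_min); the overall flag is the conjunction over parameters.
    Diagnostic failures (e.g. a degenerate chain) appear as NaN entries with
    a note, flagged not-converged rather than raised.
    """

    table: pd.DataFrame
    rhat_max: float
    ess_min: float

    @property
    def converged(self) -> bool:
        return bool(self.table["converged"].all())


def convergence_report(
    chain: PosteriorChain,
    rhat_max: float = 1.01,
    ess_min: float = 1000.0,
    include_geweke: bool = True,
) -> ConvergenceReport:
    """Run all diagnostics on every parameter of a posterior chain.

    R-hat uses the chains of the run if there are several, otherwise split
    halves of the single chain.  ESS and Geweke z are computed on the pooled
    kept draws.
    """
    rows = {}
    kept = chain.kept_per_chain  # (n_chains, kept, params)
    for j, name in enumerate(chain.parameter_names):
        pooled = chain.draws[:, j]
        n = pooled.size
        note = ""
        try:
            rhat = potential_scale_reduction(kept[:, :, j])
        except (DegenerateChainError, ConfigurationError) as err:
            rhat, note = float("nan"), f"rhat: {err}"
        try:
            ess = effective_sample_size(pooled)
        except (DegenerateChainError, ConfigurationError) as err:
            ess, note = float("nan"), (note + "; " if note else "") + f"ess: {err}"
        gz = float("nan")
        if include_geweke:
            try:
                gz = geweke_z(pooled)
            except (DegenerateChainError, ConfigurationError) as err:
                note = (note + "; " if note else "") + f"geweke: {err}"
        ess_capped = min(ess, n) if np.isfinite(ess) else float("nan")
        ok = bool(
            np.isfinite(rhat) and np.isfinite(ess)
            and rhat < rhat_max and ess_capped > ess_min
        )
        rows[name] = {
            "rhat": rhat,
            "ess": ess,
            "geweke_z": gz,
            "converged": ok,
            "note": note,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return ConvergenceReport(table=table, rhat_max=rhat_max, ess_min=ess_min)
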