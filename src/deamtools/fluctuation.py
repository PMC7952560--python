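"""Luria-Delbrück fluctuation-assay mutation-rate estimation.

A fluctuation assay grows many parallel cultures from small mutant-free
inocula, plates each on selective medium, and counts resistant colonies.
Because a mutation arising early founds a large clone ("jackpot"), the
per-culture mutant counts follow the heavy-tailed Luria-Delbrück
distribution, parameterised by ``m``, the expected number of mutational
events per culture.  This module provides:

* :func:`ld_pmf` -- the Ma-Sandri-Sarkar (MSS) probability recursion for the
  Luria-Delbrück distribution,
* :func:`mss_mle` -- the MSS maximum-likelihood estimate of ``m``,
* :func:`p0_estimate` -- the classical P0 estimator ``-ln(f0)``,
* :func:`confidence_interval` -- Stewart's large-sample 95% CI on ``m``,
* :func:`rate_from_m` / :func:`estimate_rate` -- conversion to a mutation
  rate per cell division, ``mu = m / N_t``,
* :func:`compare_rates` -- fold change between two rate estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "FluctuationExperiment",
    "LDDistribution",
    "MutationRateEstimate",
    "EstimatorUndefinedError",
    "ld_pmf",
    "ld_log_likelihood",
    "mss_mle",
    "p0_estimate",
    "confidence_interval",
    "rate_from_m",
    "estimate_rate",
    "compare_rates",
    "round_to_sig",
]

#: Counts above this value are lumped into the distribution's upper-tail mass
#: when evaluating likelihoods, keeping jackpot cultures finite to handle.
DEFAULT_TAIL_CAP = 10_000


class EstimatorUndefinedError(ValueError):
    """Raised when an estimator is undefined for the given data
    (e.g. the P0 method with no zero-count cultures)."""


@dataclass(frozen=True)
class FluctuationExperiment:
    """One fluctuation assay: mutant colony counts plus plating metadata.

    Parameters
    ----------
    counts
        Mutant colonies observed per culture, one non-negative integer per
        independent culture.
    n_final
        Final number of viable cells per culture (``N_t``), the denominator
        of the per-division mutation rate.
    plating_fraction
        Fraction ``z`` of each culture's volume plated on selective medium,
        in ``(0, 1]``.  Only used when the partial plating correction is
        explicitly enabled.
    label
        Free-text identifier (strain / condition).
    """

    counts: tuple[int, ...]
    n_final: float
    plating_fraction: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "counts", counts)
        if len(counts) == 0:
            raise ValueError("at least one culture is required")
        if any(c < 0 for c in counts):
            raise ValueError("mutant counts must be non-negative")
        if not self.n_final > 0:
            raise ValueError("n_final (N_t) must be positive")
        if not 0 < self.plating_fraction <= 1:
            raise ValueError("plating_fraction must be in (0, 1]")

    @property
    def n_cultures(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class LDDistribution:
    """Truncated Luria-Delbrück pmf from the MSS recursion."""

    m: float
    pmf: np.ndarray
    r_max: int

    @property
    def tail_mass(self) -> float:
        """Probability mass beyond ``r_max`` (1 minus the partial sum)."""
        return max(0.0, 1.0 - float(self.pmf.sum()))


@dataclass(frozen=True)
class MutationRateEstimate:
    """Point estimate and 95% CI of a per-division mutation rate."""

    m_hat: float
    mu: float
    ci_low: float
    ci_high: float
    sigma_ln_m: float
    method: str
    n_cultures: int
    n_final: float
    label: str = ""
    plating_correction: bool = False

    @property
    def ci_defined(self) -> bool:
        return math.isfinite(self.ci_low) and math.isfinite(self.ci_high)


def ld_pmf(m: float, r_max: int) -> LDDistribution:
    """Luria-Delbrück probabilities ``p_0..p_rmax`` via the MSS recursion.

    The recursion is ``p_0 = exp(-m)`` and

    .. math:: p_r = (m / r) \\sum_{i=0}^{r-1} p_i / (r - i + 1),

    equivalently a compound Poisson with clone-size law
    ``q_j = 1/(j(j+1))``.

    Parameters
    ----------
    m
        Expected number of mutational events per culture, ``m >= 0``.
    r_max
        Largest mutant count to evaluate (inclusive).
    """
    if m < 0 or not math.isfinite(m):
        raise ValueError(f"m must be a finite non-negative real, got {m}")
    if int(r_max) != r_max or r_max < 0:
        raise ValueError(f"r_max must be a non-negative integer, got {r_max}")
    r_max = int(r_max)
    p = np.zeros(r_max + 1)
    p[0] = math.exp(-m)
    if r_max > 0 and m > 0:
        # w[k] = 1/(k+1); p_r = (m/r) * sum_{k=1..r} p_{r-k} * w[k]
        w = 1.0 / (np.arange(r_max + 1) + 1.0)
        for r in range(1, r_max + 1):
            p[r] = (m / r) * float(np.dot(p[r - 1 :: -1], w[1 : r + 1]))
    return LDDistribution(m=float(m), pmf=p, r_max=r_max)


def ld_log_likelihood(
    m: float, counts: np.ndarray, tail_cap: int = DEFAULT_TAIL_CAP
) -> float:
    """Log-likelihood of ``counts`` under the Luria-Delbrück distribution.

    Counts above ``tail_cap`` contribute the log of the upper-tail mass
    ``1 - sum(p_0..p_cap)`` so that jackpot cultures keep the likelihood
    finite without evaluating an enormous pmf.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if m <= 0:
        return 0.0 if np.all(counts == 0) else -np.inf
    capped = np.minimum(counts, tail_cap)
    r_eval = int(capped.max(initial=0))
    dist = ld_pmf(m, r_eval)
    ll = 0.0
    below = counts <= tail_cap
    probs = dist.pmf[capped[below]]
    if np.any(probs <= 0):
        return -np.inf
    ll += float(np.log(probs).sum())
    n_over = int((~below).sum())
    if n_over:
        tail = dist.tail_mass
        if tail <= 0:
            return -np.inf
        ll += n_over * math.log(tail)
    return ll


def _lea_coulson_seed(counts: np.ndarray) -> float:
    """Lea-Coulson median-based starting value: solve r_med/m - ln m = 1.24."""
    r_med = float(np.median(counts))
    if r_med <= 0:
        return 0.3
    m = max(r_med / 5.0, 0.1)
    for _ in range(50):
        f = r_med / m - math.log(m) - 1.24
        fp = -r_med / m**2 - 1.0 / m
        step = f / fp
        m_new = m - step
        if m_new <= 0:
            m_new = m / 2
        if abs(m_new - m) < 1e-10 * m:
            m = m_new
            break
        m = m_new
    return m


def mss_mle(
    experiment: FluctuationExperiment | np.ndarray,
    tail_cap: int = DEFAULT_TAIL_CAP,
) -> float:
    """Maximum-likelihood estimate of ``m`` under the MSS recursion.

    Accepts either a :class:`FluctuationExperiment` or a bare array of
    counts.  The likelihood is unimodal in ``ln m``; the optimum is located
    by bounded scalar minimisation over
    ``[max(1e-6, P0 seed), 10 * (mean count + 1)]``.
    Returns exactly 0 when every culture has zero mutants (the boundary
    maximum, since ``p_0`` is decreasing in ``m``).
    """
    counts = np.asarray(
        experiment.counts
        if isinstance(experiment, FluctuationExperiment)
        else experiment,
        dtype=np.int64,
    )
    if counts.size == 0:
        raise ValueError("at least one culture is required")
    if np.all(counts == 0):
        return 0.0
    lo = 1e-6
    n_zero = int((counts == 0).sum())
    if n_zero > 0:
        lo = max(lo, -math.log(n_zero / counts.size) / 10.0)
    hi = 10.0 * (float(counts.mean()) + 1.0)
    seed = _lea_coulson_seed(counts)
    hi = max(hi, 2 * seed)

    def neg_ll(log_m: float) -> float:
        return -ld_log_likelihood(math.exp(log_m), counts, tail_cap=tail_cap)

    res = minimize_scalar(
        neg_ll,
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(math.exp(res.x))


def p0_estimate(experiment: FluctuationExperiment | np.ndarray) -> float:
    """P0 estimate ``m_hat = -ln(fraction of zero-count cultures)``.

    Raises
    ------
    EstimatorUndefinedError
        If no culture has a zero count (the estimator is undefined).
    """
    counts = np.asarray(
        experiment.counts
        if isinstance(experiment, FluctuationExperiment)
        else experiment,
        dtype=np.int64,
    )
    if counts.size == 0:
        raise ValueError("at least one culture is required")
    f0 = float((counts == 0).mean())
    if f0 == 0:
        raise EstimatorUndefinedError(
            "P0 estimator undefined: no culture with zero mutants"
        )
    return -math.log(f0)


def sigma_ln_m(m_hat: float, n_cultures: int) -> float:
    """Stewart's approximation to the SD of ``ln m_hat``:
    ``1.225 * m^(-0.315) / sqrt(C)``."""
    if m_hat <= 0:
        raise ValueError("m_hat must be positive")
    if n_cultures < 1:
        raise ValueError("n_cultures must be positive")
    return 1.225 * m_hat ** (-0.315) / math.sqrt(n_cultures)


def confidence_interval(
    m_hat: float,
    n_cultures: int,
    asymmetric: bool = False,
) -> tuple[float, float]:
    """95% confidence interval on ``m`` from Stewart's approximation.

    The default symmetric form places the bounds at
    ``exp(ln m_hat ± 1.96 sigma)`` with ``sigma = 1.225 m^(-0.315) / sqrt(C)``.
    ``asymmetric=True`` applies the exponent correction used by some
    fluctuation calculators, multiplying each half-width by
    ``(e^{1.96 sigma})^{∓0.315}``.

    Returns ``(nan, nan)`` when ``m_hat == 0`` (CI undefined; report the
    point estimate only).
    """
    if m_hat == 0:
        return (math.nan, math.nan)
    if n_cultures < 2:
        raise ValueError("n_cultures must be at least 2 for a CI")
    s = sigma_ln_m(m_hat, n_cultures)
    if asymmetric:
        half = 1.96 * s
        lo = math.exp(math.log(m_hat) - half * math.exp(half) ** -0.315)
        hi = math.exp(math.log(m_hat) + half * math.exp(half) ** 0.315)
    else:
        lo = math.exp(math.log(m_hat) - 1.96 * s)
        hi = math.exp(math.log(m_hat) + 1.96 * s)
    return (lo, hi)


def _plating_correction_factor(z: float) -> float:
    """Stewart (1990) partial-plating factor: m_true = m_plated*(z-1)/(z ln z).

    Tends to 1 as z -> 1; grows as less of the culture is plated."""
    if not 0 < z <= 1:
        raise ValueError("plating fraction must be in (0, 1]")
    if z == 1.0:
        return 1.0
    return (z - 1.0) / (z * math.log(z))


def rate_from_m(
    m_hat: float,
    experiment: FluctuationExperiment,
    plating_correction: bool = False,
    per_generation: bool = False,
    method: str = "mss_mle",
    asymmetric_ci: bool = False,
) -> MutationRateEstimate:
    """Convert ``m_hat`` to a mutation rate per division, ``mu = m / N_t``.

    The partial plating correction is OFF by default: the plated fraction
    ``z`` is ignored and ``m_hat`` taken at face value.  When enabled,
    ``m_hat`` is multiplied by Stewart's factor ``(z-1)/(z ln z)`` before
    division by ``N_t``.  ``per_generation=True`` divides by ``N_t ln 2``
    instead of ``N_t``.
    """
    if m_hat < 0:
        raise ValueError("m_hat must be non-negative")
    m_eff = m_hat
    if plating_correction:
        m_eff = m_hat * _plating_correction_factor(experiment.plating_fraction)
    denom = experiment.n_final * (math.log(2) if per_generation else 1.0)
    mu = m_eff / denom
    if m_hat > 0:
        lo_m, hi_m = confidence_interval(
            m_eff, experiment.n_cultures, asymmetric=asymmetric_ci
        )
        ci_low, ci_high = lo_m / denom, hi_m / denom
        s = sigma_ln_m(m_eff, experiment.n_cultures)
    else:
        ci_low = ci_high = math.nan
        s = math.nan
    return MutationRateEstimate(
        m_hat=m_hat,
        mu=mu,
        ci_low=ci_low,
        ci_high=ci_high,
        sigma_ln_m=s,
        method=method,
        n_cultures=experiment.n_cultures,
        n_final=experiment.n_final,
        label=experiment.label,
        plating_correction=plating_correction,
    )


def estimate_rate(
    experiment: FluctuationExperiment,
    method: str = "mss_mle",
    plating_correction: bool = False,
    **kwargs,
) -> MutationRateEstimate:
    """Run the chosen estimator (``mss_mle`` or ``p0``) and convert to a rate."""
    if method == "mss_mle":
        m_hat = mss_mle(experiment)
    elif method == "p0":
        m_hat = p0_estimate(experiment)
    else:
        raise ValueError(f"unknown method {method!r}; use 'mss_mle' or 'p0'")
    return rate_from_m(
        m_hat, experiment, plating_correction=plating_correction,
        method=method, **kwargs,
    )


def round_to_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (690000 for 687500 at 2 s.f.)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + sig - 1)


def compare_rates(
    a: MutationRateEstimate, b: MutationRateEstimate
) -> tuple[float, float]:
    """Fold change ``a.mu / b.mu`` and the same ratio at 2 significant figures.

    Returns ``(nan, nan)`` when the denominator rate is zero.
    """
    if b.mu == 0:
        return (math.nan, math.nan)
    fold = a.mu / b.mu
    return fold, round_to_sig(fold, 2)
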