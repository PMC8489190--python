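"""Privacy models: k-anonymity and Pitman population-uniqueness estimation.

k-anonymity requires every equivalence class (records indistinguishable on
their quasi-identifiers) to contain at least ``k`` records.

Population uniqueness is a statistical alternative: the dataset is viewed as a
fraction ``pi`` of a larger population, and the model estimates what fraction
of the *population* is unique on the quasi-identifiers.  Class sizes are
modeled with the two-parameter Poisson-Dirichlet distribution PD(alpha, theta)
("Pitman's sampling formula").  Writing ``(x)_m = x (x+1) ... (x+m-1)`` for
the rising factorial, the expected number of classes in a sample of size n is

    E[K_n] = (theta/alpha) * ((theta+alpha)_n / (theta)_n - 1),       alpha > 0
    E[K_n] = theta * (psi(theta+n) - psi(theta)),                     alpha = 0

and the expected number of singleton classes is

    E[K_{n,1}] = n * (theta+alpha)_{n-1} / (theta+1)_{n-1}.

Both follow from the sequential (Chinese-restaurant) construction of the
partition.  The parameters are fitted by method of moments: (theta, alpha)
are chosen so that E[K_n] and E[K_{n,1}] match the observed class count u and
singleton count u1.  The fitted model is then extrapolated to the population
size N = round(n / pi), and the estimated uniqueness is E[K_{N,1}] / N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, gammaln

from .transform import EquivalenceClassHistogram, equivalence_classes

if TYPE_CHECKING:  # pragma: no cover
    from .transform import TransformedDataset

__all__ = [
    "KAnonymity",
    "PopulationUniqueness",
    "PrivacyModel",
    "PitmanFit",
    "check_k_anonymity",
    "fit_pitman",
    "estimate_population_uniqueness",
    "is_satisfied",
    "sample_pitman_partition",
]

# Root-search box and tolerances for the moment-equation solve.
_THETA_MIN = 1e-8
_THETA_MAX = 1e9
_ALPHA_MAX = 1.0 - 1e-6
_RESIDUAL_TOL = 1e-9
_MAX_ITER = 200


@dataclass(frozen=True)
class KAnonymity:
    """Every equivalence class must contain at least ``k`` records."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class PopulationUniqueness:
    """Estimated population uniqueness must not exceed ``threshold``.

    ``sampling_fraction`` is the share of the population present in the
    dataset (e.g. 0.01 if the data cover 1% of the population).
    """

    threshold: float
    sampling_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ValueError("sampling_fraction must be in (0, 1]")


PrivacyModel = Union[KAnonymity, PopulationUniqueness]


@dataclass(frozen=True)
class PitmanFit:
    """Fitted PD(alpha, theta) parameters; ``converged=False`` marks fallback fits."""

    theta: float
    alpha: float
    converged: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.theta <= -self.alpha:
            raise ValueError("theta must exceed -alpha")


def check_k_anonymity(hist: EquivalenceClassHistogram, k: int) -> bool:
    """True iff every class has at least ``k`` members (vacuously true if empty)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return all(s >= k for s in hist.sizes)


# ---------------------------------------------------------------------------
# Poisson-Dirichlet moments
# ---------------------------------------------------------------------------

_CHUNKED_LIMIT = 1 << 23  # above this, fall back to log-gamma differences


def _log_ratio_rising(a: float, b: float, m: int) -> float:
    """log[(a)_m / (b)_m] for rising factorials, computed stably.

    The direct log-gamma difference cancels catastrophically when ``a`` and
    ``b`` are huge relative to ``m`` (e.g. theta near the top of the search
    box), so for moderate ``m`` the sum ``sum_i log1p((a-b)/(b+i))`` is used
    instead.
    """
    if m <= 0:
        return 0.0
    if m <= _CHUNKED_LIMIT:
        i = np.arange(m, dtype=np.float64)
        return float(np.log1p((a - b) / (b + i)).sum())
    return float(gammaln(a + m) - gammaln(a) - gammaln(b + m) + gammaln(b))


def expected_classes(n: int, theta: float, alpha: float) -> float:
    """E[number of classes] in a PD(alpha, theta) sample of size ``n``."""
    if n == 0:
        return 0.0
    if alpha == 0.0:
        return theta * float(digamma(theta + n) - digamma(theta))
    return (theta / alpha) * float(np.expm1(_log_ratio_rising(theta + alpha, theta, n)))


def expected_singletons(n: int, theta: float, alpha: float) -> float:
    """E[number of singleton classes] in a PD(alpha, theta) sample of size ``n``."""
    if n == 0:
        return 0.0
    return n * float(np.exp(_log_ratio_rising(theta + alpha, theta + 1.0, n - 1)))


def _solve_theta(n: int, u: float, alpha: float) -> float | None:
    """theta matching E[K_n](theta, alpha) = u; None if no root in the box.

    E[K_n] is strictly increasing in theta, so a bracketed Brent solve is
    exact and cannot leave the box.
    """
    f = lambda th: expected_classes(n, th, alpha) - u
    lo, hi = _THETA_MIN, _THETA_MAX
    if f(lo) > 0 or f(hi) < 0:
        return None
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=_MAX_ITER))


def fit_pitman(hist: EquivalenceClassHistogram) -> PitmanFit:
    """Method-of-moments fit of PD(alpha, theta) to a class-size histogram.

    Matches the expected class count and expected singleton count to the
    observed values via a nested bracketed root search over the box
    ``alpha in [0, 1), theta in (0, 1e9]``.  When no interior root exists
    (all-singleton samples, no-singleton samples, or moments outside the
    attainable range) a fallback fit with alpha pinned to 0 and theta matched
    to the class count alone is returned with ``converged=False``.  Degenerate
    inputs never raise: the search algorithms evaluate thousands of candidate
    schemes and must always get a defined answer.
    """
    n = hist.n_effective
    if n < 1:
        raise ValueError("cannot fit Pitman model to an empty histogram")
    u = hist.n_classes
    u1 = hist.n_singletons

    def fallback() -> PitmanFit:
        theta = _solve_theta(n, u, 0.0)
        if theta is None:
            theta = _THETA_MAX if u > 1 else _THETA_MIN
        return PitmanFit(theta=theta, alpha=0.0, converged=False)

    if u >= n or u1 == 0 or u <= 1:
        # all singletons (alpha -> 1 boundary), no singletons, or a single class
        return fallback()

    def singleton_gap(alpha: float) -> float | None:
        theta = _solve_theta(n, u, alpha)
        if theta is None:
            return None
        return expected_singletons(n, theta, alpha) - u1

    # Bracket a sign change of the singleton gap on a grid over the alpha box.
    # For alpha beyond a data-dependent point the class-count equation has no
    # theta root (the gap is undefined there), so the grid also finds the
    # feasible range.
    grid = np.linspace(0.0, _ALPHA_MAX, 33)
    prev_a: float | None = None
    prev_g: float | None = None
    bracket: tuple[float, float] | None = None
    for a in grid:
        g = singleton_gap(float(a))
        if g is None:
            break
        if abs(g) <= _RESIDUAL_TOL:
            return PitmanFit(theta=_solve_theta(n, u, float(a)) or _THETA_MIN,
                             alpha=float(a), converged=True)
        if prev_g is not None and prev_g * g < 0:
            bracket = (prev_a, float(a))  # type: ignore[assignment]
            break
        prev_a, prev_g = float(a), g
    if bracket is None:
        return fallback()
    alpha = float(brentq(lambda a: singleton_gap(a), bracket[0], bracket[1],
                         xtol=1e-12, maxiter=_MAX_ITER))
    theta = _solve_theta(n, u, alpha)
    if theta is None:
        return fallback()
    gap = singleton_gap(alpha)
    converged = gap is not None and abs(gap) <= max(_RESIDUAL_TOL, 1e-6 * u1)
    return PitmanFit(theta=theta, alpha=alpha, converged=converged)


def estimate_population_uniqueness(
    hist: EquivalenceClassHistogram, sampling_fraction: float
) -> float:
    """Expected fraction of the population unique on the quasi-identifiers.

    Fits PD(alpha, theta) to the sample histogram and extrapolates the
    expected singleton count to population size ``N = round(n / pi)``.
    Short-circuits: ``pi == 1`` returns exactly ``u1 / n``; no sample
    singletons returns 0.
    """
    if not 0.0 < sampling_fraction <= 1.0:
        raise ValueError("sampling_fraction must be in (0, 1]")
    n = hist.n_effective
    if n == 0:
        return 0.0
    u1 = hist.n_singletons
    if u1 == 0:
        return 0.0
    if sampling_fraction == 1.0:
        return u1 / n
    fit = fit_pitman(hist)
    N = max(n, round(n / sampling_fraction))
    est = expected_singletons(N, fit.theta, fit.alpha) / N
    return float(min(1.0, max(0.0, est)))


def is_satisfied(t: "TransformedDataset", model: PrivacyModel) -> bool:
    """Dispatch: does the transformed dataset satisfy the privacy model?

    An empty output (everything suppressed) satisfies both models.
    """
    hist, _ = equivalence_classes(t)
    if isinstance(model, KAnonymity):
        return check_k_anonymity(hist, model.k)
    if isinstance(model, PopulationUniqueness):
        est = estimate_population_uniqueness(hist, model.sampling_fraction)
        return est <= model.threshold
    raise TypeError(f"unsupported privacy model {model!r}")


def sample_pitman_partition(
    n: int, theta: float, alpha: float, rng: np.random.Generator
) -> EquivalenceClassHistogram:
    """Sequentially simulate a PD(alpha, theta) partition of ``n`` elements.

    Chinese-restaurant construction: element ``i`` joins an existing class of
    size ``s`` with probability proportional to ``s - alpha`` and opens a new
    class with probability proportional to ``theta + k * alpha`` (``k`` =
    current class count).  Used as an independent simulation oracle for the
    moment-equation fit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sizes: list[float] = [1.0]
    for i in range(1, n):
        k = len(sizes)
        total = theta + i
        r = rng.random() * total
        if r < theta + k * alpha:
            sizes.append(1.0)
        else:
            r -= theta + k * alpha
            cum = np.cumsum(np.asarray(sizes) - alpha)
            j = int(np.searchsorted(cum, r, side="right"))
            j = min(j, k - 1)
            sizes[j] += 1.0
    return EquivalenceClassHistogram(tuple(int(s) for s in sizes))
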