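"""Posterior summaries and directional-hypothesis probabilities.

Point estimates are EAP (expected a posteriori, i.e. the posterior mean over
pooled retained draws); uncertainty is reported as the posterior standard
deviation (sample, n-1 convention) and the highest density interval (HDI),
the shortest interval containing the requested posterior mass.

A directional hypothesis mu_i > mu_j is evaluated as the posterior mean of
the draw-wise indicator 1{mu_i(t) - mu_j(t) > 0}; ties count as 0.  The
compound (group) comparison evaluates the joint draw-wise event that every
member of one condition group exceeds every member of the other; the plain
product of the four marginal directional probabilities is also provided,
since the two coincide only when the pairwise events are posterior-
independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditions import N_CONDITIONS, SHAPES

__all__ = [
    "SummaryRow",
    "CompoundSpec",
    "eap",
    "posterior_sd",
    "hdi",
    "directional_probability",
    "probability_matrix",
    "joint_probability",
    "marginal_product",
    "summarize",
]


@dataclass(frozen=True)
class SummaryRow:
    """EAP / posterior SD / HDI summary for one parameter."""

    parameter: str
    eap: float
    sd: float
    hdi_lower: float
    hdi_upper: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.mass < 1:
            raise ValueError("mass must be in (0, 1)")
        if self.hdi_lower > self.hdi_upper:
            raise ValueError("hdi_lower must not exceed hdi_upper")


@dataclass(frozen=True)
class CompoundSpec:
    """Group comparison (i, j) > (k, l) among the four condition indices."""

    group_a: tuple[int, int]
    group_b: tuple[int, int]
    taste: str = ""

    def __post_init__(self) -> None:
        idx = (*self.group_a, *self.group_b)
        if len(set(idx)) != 4:
            raise ValueError("the four condition indices must be distinct")
        if any(i < 0 or i >= N_CONDITIONS for i in idx):
            raise ValueError(f"condition indices must be in 0..{N_CONDITIONS - 1}")


def eap(draws: np.ndarray) -> float:
    """Posterior mean over all pooled retained draws."""
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size == 0:
        raise ValueError("eap requires at least one draw")
    return float(draws.mean())


def posterior_sd(draws: np.ndarray) -> float:
    """Posterior standard deviation (sample convention, ddof=1)."""
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size < 2:
        raise ValueError("posterior_sd requires at least two draws")
    return float(draws.std(ddof=1))


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest density interval by the shortest-window estimator.

    Sorts the draws and scans all contiguous windows of ``ceil(mass * n)``
    draws, returning the narrowest; ties are broken by the smallest lower
    endpoint.  Assumes a unimodal posterior.
    """
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    if draws.size < 20:
        raise ValueError("hdi requires at least 20 draws")
    x = np.sort(draws)
    n = x.size
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    best = int(np.argmin(widths))  # argmin takes the first (lowest) minimum
    return float(x[best]), float(x[best + m - 1])


def directional_probability(draws_i: np.ndarray, draws_j: np.ndarray) -> float:
    """Posterior probability that parameter i exceeds parameter j.

    Draws must be paired by retained-draw index; ties contribute zero.
    """
    a = np.asarray(draws_i, dtype=float).reshape(-1)
    b = np.asarray(draws_j, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("draw vectors must have equal length")
    if a.size == 0:
        raise ValueError("draw vectors must be non-empty")
    return float(np.mean(a > b))


def probability_matrix(
    mu_draws: np.ndarray, labels: tuple[str, ...] = SHAPES
) -> np.ndarray:
    """4x4 matrix of pairwise directional probabilities.

    ``mu_draws`` has shape (4, n_draws); entry (i, j) is
    P(mu_i > mu_j); the diagonal is fixed at 0 by convention.
    """
    mu_draws = np.asarray(mu_draws, dtype=float)
    if mu_draws.ndim != 2 or mu_draws.shape[0] != len(labels):
        raise ValueError(f"mu_draws must be ({len(labels)}, n_draws)")
    k = mu_draws.shape[0]
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                out[i, j] = directional_probability(mu_draws[i], mu_draws[j])
    return out


def joint_probability(mu_draws: np.ndarray, spec: CompoundSpec) -> float:
    """Posterior probability of the joint group event (i, j) > (k, l).

    The four pairwise indicators are multiplied draw-wise, so posterior
    dependence between comparisons is respected.
    """
    mu_draws = np.asarray(mu_draws, dtype=float)
    if mu_draws.ndim != 2 or mu_draws.shape[0] != N_CONDITIONS:
        raise ValueError(f"mu_draws must be ({N_CONDITIONS}, n_draws)")
    i, j = spec.group_a
    k, l = spec.group_b
    ind = (
        (mu_draws[i] > mu_draws[k])
        & (mu_draws[i] > mu_draws[l])
        & (mu_draws[j] > mu_draws[k])
        & (mu_draws[j] > mu_draws[l])
    )
    return float(np.mean(ind))


def marginal_product(p1: float, p2: float, p3: float, p4: float) -> float:
    """Product of four marginal directional probabilities.

    This is the group-comparison arithmetic as reported from the pairwise
    tables; it equals :func:`joint_probability` only under posterior
    independence of the four events.
    """
    probs = (p1, p2, p3, p4)
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probabilities must be in [0, 1], got {p}")
    return float(np.prod(probs))


def summarize(draws: np.ndarray, parameter: str, mass: float = 0.95) -> SummaryRow:
    """EAP / SD / HDI summary row for one pooled draw vector."""
    lo, hi = hdi(draws, mass)
    return SummaryRow(
        parameter=parameter,
        eap=eap(draws),
        sd=posterior_sd(draws),
        hdi_lower=lo,
        hdi_upper=hi,
        mass=mass,
    )
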