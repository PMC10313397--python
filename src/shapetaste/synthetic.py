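"""Synthetic within-subjects VAS rating datasets.

Emulates the chocolate shape–taste study design: every participant rates all
four shape conditions for each taste on a 0–100 VAS, with presentation
orders counterbalanced over the full set of 4! = 24 condition sequences.
Ratings for one taste are drawn per participant from a 4-dimensional
multivariate normal with condition means ``mu``, scales ``sigma`` and
correlation matrix ``corr``; the three tastes are generated independently.

Because the inference model is an untruncated multivariate normal while real
VAS scores live in [0, 100], three bounding behaviours are offered:
``unbounded`` (exactly the model's assumptions; used for parameter-recovery
checks), ``clipped`` (clamp to [0, 100]; the realistic default) and
``truncated`` (redraw until all four components are in range).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import N_CONDITIONS, REFERENCE_EAP, SHAPES, TASTES
from .model import _validate_corr

__all__ = [
    "TrueParams",
    "SimulationConfig",
    "generate_orders",
    "simulate_ratings",
    "make_study_dataset",
    "write_ratings",
]

RATINGS_COLUMNS = ("participant_id", "order_position", "shape", "taste", "score")

# deterministic substream offsets from the master seed
_ORDER_SEED_OFFSET = 1_000_003
_TASTE_SEED_OFFSET = 7_919


@dataclass(frozen=True)
class TrueParams:
    """Generative truth for one taste: means, scales, correlation matrix."""

    mu: np.ndarray
    sigma: np.ndarray
    corr: np.ndarray
    taste_label: str

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        corr = _validate_corr(self.corr)
        if mu.shape != (N_CONDITIONS,) or sigma.shape != (N_CONDITIONS,):
            raise ValueError(f"mu and sigma must be {N_CONDITIONS}-vectors")
        if np.any(sigma <= 0):
            raise ValueError("all sigma must be positive")
        if np.any(mu < 0) or np.any(mu > 100):
            raise ValueError("all mu must lie in [0, 100]")
        if self.taste_label not in TASTES:
            raise ValueError(f"unknown taste label: {self.taste_label!r}")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "corr", corr)


BOUNDS_MODES = ("unbounded", "clipped", "truncated")


@dataclass(frozen=True)
class SimulationConfig:
    """Size, seed and bounding behaviour of a simulated dataset."""

    n_participants: int = 24
    seed: int = 0
    bounds_mode: str = "clipped"
    round_scores: bool = False

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.bounds_mode not in BOUNDS_MODES:
            raise ValueError(
                f"bounds_mode must be one of {BOUNDS_MODES}, got {self.bounds_mode!r}"
            )


def generate_orders(n_participants: int, seed: int) -> list[tuple[str, ...]]:
    """Counterbalanced presentation orders over all 4! = 24 sequences.

    The full lexicographic enumeration of permutations of the four condition
    labels is shuffled once (by ``seed``) and assigned cyclically, so 24
    participants receive 24 pairwise-distinct orders and each condition
    appears in each serial position equally often.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    all_orders = list(itertools.permutations(SHAPES))
    rng = np.random.default_rng(seed + _ORDER_SEED_OFFSET)
    perm = rng.permutation(len(all_orders))
    shuffled = [all_orders[i] for i in perm]
    return [shuffled[i % len(shuffled)] for i in range(n_participants)]


def _draw_scores(
    rng: np.random.Generator,
    params: TrueParams,
    n: int,
    bounds_mode: str,
) -> np.ndarray:
    cov = params.corr * np.outer(params.sigma, params.sigma)
    scores = rng.multivariate_normal(params.mu, cov, size=n, method="cholesky")
    if bounds_mode == "clipped":
        scores = np.clip(scores, 0.0, 100.0)
    elif bounds_mode == "truncated":
        for _ in range(10_000):
            bad = np.any((scores < 0.0) | (scores > 100.0), axis=1)
            if not bad.any():
                break
            scores[bad] = rng.multivariate_normal(
                params.mu, cov, size=int(bad.sum()), method="cholesky"
            )
        else:
            raise RuntimeError(
                "truncated sampling failed to produce in-range draws; "
                "the generating distribution puts almost no mass in [0, 100]^4"
            )
    return scores


def simulate_ratings(
    params_per_taste: list[TrueParams], config: SimulationConfig
) -> pd.DataFrame:
    """Simulate a complete crossed ratings table.

    Returns a long-format frame with columns
    ``participant_id, order_position, shape, taste, score`` containing
    exactly ``n_participants x 4 x n_tastes`` records.  Identical seed and
    config reproduce the table exactly.
    """
    if not params_per_taste:
        raise ValueError("at least one TrueParams is required")
    labels = [p.taste_label for p in params_per_taste]
    if len(set(labels)) != len(labels):
        raise ValueError("taste labels must be distinct")

    n = config.n_participants
    orders = generate_orders(n, config.seed)
    position = {
        (p, shape): pos + 1
        for p, order in enumerate(orders)
        for pos, shape in enumerate(order)
    }
    width = max(2, len(str(n)))
    pids = [f"P{idx + 1:0{width}d}" for idx in range(n)]

    records = []
    for t_idx, params in enumerate(params_per_taste):
        rng = np.random.default_rng(config.seed + _TASTE_SEED_OFFSET * (t_idx + 1))
        scores = _draw_scores(rng, params, n, config.bounds_mode)
        if config.round_scores:
            scores = np.clip(np.rint(scores), 0.0, 100.0)
        for p in range(n):
            for c, shape in enumerate(SHAPES):
                records.append(
                    (
                        pids[p],
                        position[(p, shape)],
                        shape,
                        params.taste_label,
                        float(scores[p, c]),
                    )
                )
    return pd.DataFrame.from_records(records, columns=RATINGS_COLUMNS)


def exchangeable_corr(rho: float, dim: int = N_CONDITIONS) -> np.ndarray:
    """Exchangeable (compound-symmetric) correlation matrix."""
    if not -1.0 / (dim - 1) < rho < 1.0:
        raise ValueError("rho outside the positive-definite range")
    return np.full((dim, dim), rho) + (1.0 - rho) * np.eye(dim)


def make_study_dataset(
    seed: int = 0,
    sigma: float = 20.0,
    rho: float = 0.5,
    n_participants: int = 24,
) -> pd.DataFrame:
    """Study-like dataset: published condition-mean estimates as truth.

    Generator means per taste are the study's reported EAP point estimates,
    with a common scale ``sigma`` (default 20 VAS units) and exchangeable
    correlation ``rho`` (default 0.5) across the four conditions; 24
    participants, clipped to [0, 100].
    """
    corr = exchangeable_corr(rho)
    params = [
        TrueParams(
            mu=np.array(REFERENCE_EAP[taste]),
            sigma=np.full(N_CONDITIONS, sigma),
            corr=corr,
            taste_label=taste,
        )
        for taste in TASTES
    ]
    config = SimulationConfig(
        n_participants=n_participants, seed=seed, bounds_mode="clipped"
    )
    return simulate_ratings(params, config)


def write_ratings(table: pd.DataFrame, path) -> None:
    """Write a ratings table as UTF-8 CSV with the canonical header."""
    table.loc[:, list(RATINGS_COLUMNS)].to_csv(path, index=False, encoding="utf-8")
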