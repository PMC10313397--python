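"""End-to-end analysis pipeline: validate ratings, fit, report.

Reads a long-format ratings table, fits the multivariate-normal model to
each taste's 24x4 score matrix by MCMC, checks convergence, evaluates the
six directional hypotheses H1–H6, computes the compound shape-family
comparisons, and renders machine- and human-readable reports that mirror
the study's "EAP (SD) [HDI lower, HDI upper]" convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .conditions import (
    COMPOUND_DIRECTION,
    HYPOTHESES,
    N_CONDITIONS,
    SHAPES,
    TASTES,
)
from .inference import (
    CompoundSpec,
    SummaryRow,
    directional_probability,
    joint_probability,
    marginal_product,
    probability_matrix,
    summarize,
)
from .model import PriorSpec, make_taste_target
from .sampling import ChainConfig, ConvergenceReport, PosteriorDraws, check_convergence, run_mcmc
from .synthetic import RATINGS_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "read_ratings",
    "validate_ratings",
    "pivot_scores",
    "fit_taste",
    "fit_all_tastes",
    "evaluate_hypotheses",
    "compound_report",
    "build_report",
    "HypothesisResult",
    "CompoundResult",
    "ReportBundle",
    "format_estimate",
]


def validate_ratings(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format ratings table against the study schema.

    Requires the canonical columns, known shape/taste labels, scores within
    [0, 100], no duplicate (participant, shape, taste) cells and a complete
    crossed design.  Returns the table with scores as floats.
    """
    missing_cols = [c for c in RATINGS_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"ratings table is missing columns: {missing_cols}")
    table = table.copy()
    table["score"] = pd.to_numeric(table["score"], errors="raise")

    bad_shape = sorted(set(table["shape"]) - set(SHAPES))
    if bad_shape:
        rows = table.index[table["shape"].isin(bad_shape)].tolist()[:5]
        raise ValueError(f"unknown shape label(s) {bad_shape} (rows {rows})")
    bad_taste = sorted(set(table["taste"]) - set(TASTES))
    if bad_taste:
        rows = table.index[table["taste"].isin(bad_taste)].tolist()[:5]
        raise ValueError(f"unknown taste label(s) {bad_taste} (rows {rows})")

    out_of_range = table[(table["score"] < 0) | (table["score"] > 100)]
    if not out_of_range.empty:
        raise ValueError(
            f"{len(out_of_range)} score(s) outside [0, 100]; "
            f"first offending rows: {out_of_range.index.tolist()[:5]}"
        )

    keys = table[["participant_id", "shape", "taste"]]
    dup = keys[keys.duplicated()]
    if not dup.empty:
        first = dup.iloc[0]
        raise ValueError(
            "duplicate (participant, shape, taste) cell: "
            f"({first['participant_id']}, {first['shape']}, {first['taste']})"
        )

    participants = sorted(set(table["participant_id"]))
    expected = {
        (p, s, t) for p in participants for s in SHAPES for t in TASTES
    }
    present = set(map(tuple, keys.itertuples(index=False)))
    absent = sorted(expected - present)
    if absent:
        raise ValueError(
            f"incomplete design: {len(absent)} missing (participant, shape, "
            f"taste) cell(s), first: {absent[:5]}"
        )
    return table


def read_ratings(path, **read_csv_kwargs) -> pd.DataFrame:
    """Read and validate a ratings CSV (row order irrelevant)."""
    table = pd.read_csv(path, **read_csv_kwargs)
    return validate_ratings(table)


def pivot_scores(table: pd.DataFrame, taste: str) -> np.ndarray:
    """Pivot one taste's scores to an (n_participants, 4) matrix in
    canonical condition order, rows sorted by participant id."""
    if taste not in TASTES:
        raise ValueError(f"unknown taste: {taste!r}")
    sub = table[table["taste"] == taste]
    wide = sub.pivot(index="participant_id", columns="shape", values="score")
    return wide.sort_index()[list(SHAPES)].to_numpy(dtype=float)


def fit_taste(
    table: pd.DataFrame,
    taste: str,
    priors: PriorSpec | None = None,
    chains: ChainConfig | None = None,
    threshold: float = 0.01,
) -> tuple[PosteriorDraws, ConvergenceReport]:
    """Fit the rating model to one taste and check convergence.

    Convergence violations are logged as warnings and annotated in the
    report; they never abort the fit.
    """
    data = pivot_scores(table, taste)
    target = make_taste_target(data, priors)
    draws = run_mcmc(target, chains)
    report = check_convergence(draws, threshold=threshold)
    logger.info(
        "fit %s: n=%d, %d retained draws, max |R-hat - 1| = %.4f",
        taste,
        data.shape[0],
        draws.config.total_retained,
        report.max_abs_deviation,
    )
    return draws, report


def fit_all_tastes(
    table: pd.DataFrame,
    priors: PriorSpec | None = None,
    chains: ChainConfig | None = None,
    threshold: float = 0.01,
) -> dict[str, tuple[PosteriorDraws, ConvergenceReport]]:
    """Fit every taste independently with per-taste seed offsets."""
    if chains is None:
        chains = ChainConfig()
    out = {}
    for t_idx, taste in enumerate(TASTES):
        cfg = ChainConfig(
            n_chains=chains.n_chains,
            n_iterations=chains.n_iterations,
            burn_in=chains.burn_in,
            seed=chains.seed + 101 * t_idx,
            proposals_per_draw=chains.proposals_per_draw,
            target_accept=chains.target_accept,
            initial_scale=chains.initial_scale,
        )
        out[taste] = fit_taste(table, taste, priors, cfg, threshold)
    return out


def _mu_draws(draws: PosteriorDraws) -> np.ndarray:
    """(4, n_pooled) matrix of condition-mean draws in canonical order."""
    return np.stack([draws.get(f"mu[{s}]") for s in SHAPES])


@dataclass(frozen=True)
class HypothesisResult:
    """One directional hypothesis with its posterior probability."""

    id: str
    taste: str
    comparison: tuple[str, str]  # (greater, lesser)
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


def evaluate_hypotheses(
    draws_by_taste: dict[str, PosteriorDraws]
) -> list[HypothesisResult]:
    """Evaluate H1–H6 from per-taste posterior draws."""
    missing = [t for t in TASTES if t not in draws_by_taste]
    if missing:
        raise ValueError(f"missing draws for taste(s): {missing}")
    results = []
    for hid in sorted(HYPOTHESES):
        taste, greater, lesser = HYPOTHESES[hid]
        draws = draws_by_taste[taste]
        p = directional_probability(
            draws.get(f"mu[{greater}]"), draws.get(f"mu[{lesser}]")
        )
        results.append(
            HypothesisResult(
                id=hid, taste=taste, comparison=(greater, lesser), probability=p
            )
        )
    return results


@dataclass(frozen=True)
class CompoundResult:
    """Shape-family group comparison for one taste."""

    taste: str
    spec: CompoundSpec
    joint: float
    product_of_marginals: float

    @property
    def description(self) -> str:
        a = " & ".join(SHAPES[i] for i in self.spec.group_a)
        b = " & ".join(SHAPES[i] for i in self.spec.group_b)
        return f"({a}) > ({b})"


def compound_report(
    draws_by_taste: dict[str, PosteriorDraws]
) -> dict[str, CompoundResult]:
    """Compound Bouba-vs-Kiki comparison per taste.

    Sweetness tests rounded > angular; sourness and bitterness test
    angular > rounded.  Both the draw-wise joint probability and the product
    of the four marginal directional probabilities are reported.
    """
    out = {}
    for taste, (group_a, group_b) in COMPOUND_DIRECTION.items():
        if taste not in draws_by_taste:
            continue
        mu = _mu_draws(draws_by_taste[taste])
        spec = CompoundSpec(group_a=group_a, group_b=group_b, taste=taste)
        marginals = [
            directional_probability(mu[a], mu[b]) for a in group_a for b in group_b
        ]
        out[taste] = CompoundResult(
            taste=taste,
            spec=spec,
            joint=joint_probability(mu, spec),
            product_of_marginals=marginal_product(*marginals),
        )
    return out


def format_estimate(eap: float, sd: float, lower: float, upper: float) -> str:
    """Render the "EAP (SD) [lower, upper]" reporting string at 2 decimals."""
    return f"{eap:.2f} ({sd:.2f}) [{lower:.2f}, {upper:.2f}]"


@dataclass
class ReportBundle:
    """Complete analysis output for one dataset."""

    summaries: dict[str, list[SummaryRow]]
    matrices: dict[str, np.ndarray]
    convergence: dict[str, ConvergenceReport]
    hypotheses: list[HypothesisResult]
    compounds: dict[str, CompoundResult]
    seed: int
    chain_config: ChainConfig
    version: str = field(default=__version__)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "chain_config": {
                "n_chains": self.chain_config.n_chains,
                "n_iterations": self.chain_config.n_iterations,
                "burn_in": self.chain_config.burn_in,
                "proposals_per_draw": self.chain_config.proposals_per_draw,
            },
            "summaries": {
                taste: [
                    {
                        "parameter": r.parameter,
                        "eap": round(r.eap, 4),
                        "sd": round(r.sd, 4),
                        "hdi_lower": round(r.hdi_lower, 4),
                        "hdi_upper": round(r.hdi_upper, 4),
                        "mass": r.mass,
                        "formatted": format_estimate(
                            r.eap, r.sd, r.hdi_lower, r.hdi_upper
                        ),
                    }
                    for r in rows
                ]
                for taste, rows in self.summaries.items()
            },
            "probability_matrices": {
                taste: [[round(v, 3) for v in row] for row in mat.tolist()]
                for taste, mat in self.matrices.items()
            },
            "convergence": {t: r.to_dict() for t, r in self.convergence.items()},
            "hypotheses": [
                {
                    "id": h.id,
                    "taste": h.taste,
                    "comparison": list(h.comparison),
                    "probability": round(h.probability, 3),
                }
                for h in self.hypotheses
            ],
            "compound_comparisons": {
                taste: {
                    "comparison": c.description,
                    "joint": round(c.joint, 3),
                    "product_of_marginals": round(c.product_of_marginals, 3),
                }
                for taste, c in self.compounds.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def to_markdown(self) -> str:
        lines = [f"# Shape-taste rating analysis (v{self.version}, seed {self.seed})", ""]
        for taste in self.summaries:
            lines.append(f"## {taste.capitalize()}")
            lines.append("")
            lines.append("| parameter | EAP (SD) [95% HDI] |")
            lines.append("|---|---|")
            for r in self.summaries[taste]:
                lines.append(
                    f"| {r.parameter} | "
                    f"{format_estimate(r.eap, r.sd, r.hdi_lower, r.hdi_upper)} |"
                )
            lines.append("")
            if taste in self.matrices:
                lines.append(f"P(row rated higher than column), {taste}:")
                lines.append("")
                lines.append("| | " + " | ".join(SHAPES) + " |")
                lines.append("|---" * (N_CONDITIONS + 1) + "|")
                for i, row in enumerate(self.matrices[taste]):
                    cells = " | ".join(f"{v:.3f}" for v in row)
                    lines.append(f"| {SHAPES[i]} | {cells} |")
                lines.append("")
            if taste in self.convergence:
                rep = self.convergence[taste]
                status = "passed" if rep.passed else "FAILED"
                lines.append(
                    f"Convergence: {status} "
                    f"(max |R-hat - 1| = {rep.max_abs_deviation:.4f}, "
                    f"threshold {rep.threshold})"
                )
                lines.append("")
        if self.hypotheses:
            lines.append("## Hypotheses")
            lines.append("")
            lines.append("| id | taste | comparison | probability |")
            lines.append("|---|---|---|---|")
            for h in self.hypotheses:
                lines.append(
                    f"| {h.id} | {h.taste} | {h.comparison[0]} > {h.comparison[1]} "
                    f"| {h.probability:.3f} |"
                )
            lines.append("")
        if self.compounds:
            lines.append("## Compound shape-family comparisons")
            lines.append("")
            lines.append("| taste | comparison | joint | product of marginals |")
            lines.append("|---|---|---|---|")
            for taste, c in self.compounds.items():
                lines.append(
                    f"| {taste} | {c.description} | {c.joint:.3f} "
                    f"| {c.product_of_marginals:.3f} |"
                )
            lines.append("")
        return "\n".join(lines)


def build_report(
    fits: dict[str, tuple[PosteriorDraws, ConvergenceReport]],
    seed: int = 0,
    mass: float = 0.95,
) -> ReportBundle:
    """Assemble the full report from per-taste fits.

    Every number in the rendered report is recomputed from the stored
    posterior draws, so regeneration from saved draws is byte-identical.
    """
    draws_by_taste = {t: d for t, (d, _) in fits.items()}
    summaries: dict[str, list[SummaryRow]] = {}
    matrices: dict[str, np.ndarray] = {}
    convergence: dict[str, ConvergenceReport] = {}
    for taste, (draws, conv) in fits.items():
        summaries[taste] = [
            summarize(draws.get(name), name, mass) for name in draws.param_names
        ]
        matrices[taste] = probability_matrix(_mu_draws(draws))
        convergence[taste] = conv
    hypotheses = (
        evaluate_hypotheses(draws_by_taste)
        if all(t in draws_by_taste for t in TASTES)
        else []
    )
    compounds = compound_report(draws_by_taste)
    any_cfg = next(iter(fits.values()))[0].config
    return ReportBundle(
        summaries=summaries,
        matrices=matrices,
        convergence=convergence,
        hypotheses=hypotheses,
        compounds=compounds,
        seed=seed,
        chain_config=any_cfg,
    )
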