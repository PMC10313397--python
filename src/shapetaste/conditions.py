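"""Canonical condition vocabulary and published reference quantities.

The study design presents four ring-shaped chocolate pieces — two rounded
("Bouba") and two angular ("Kiki") variants — to every participant, who rates
each one for sweetness, sourness and bitterness on a 0–100 visual analogue
scale (VAS).  Everything downstream indexes the four shape conditions in one
fixed canonical order, mirroring the mean-parameter numbering
(mu1..mu4) used in the study's reporting.
"""

from __future__ import annotations

import numpy as np

#: Canonical shape-condition order: (mu1, mu2, mu3, mu4).
SHAPES: tuple[str, ...] = ("Bouba-A6", "Kiki-A6", "Bouba-S6", "Kiki-A10")

#: Canonical taste order.
TASTES: tuple[str, ...] = ("sweetness", "sourness", "bitterness")

N_CONDITIONS = len(SHAPES)

#: Condition indices of the rounded (Bouba) and angular (Kiki) shapes.
BOUBA_INDICES: tuple[int, int] = (0, 2)
KIKI_INDICES: tuple[int, int] = (1, 3)

#: Directional hypotheses H1–H6: id -> (taste, greater shape, lesser shape).
#: H1/H4 concern sweetness, H2/H5 sourness, H3/H6 bitterness; H4–H6 compare
#: the minor within-family shape variants.
HYPOTHESES: dict[str, tuple[str, str, str]] = {
    "H1": ("sweetness", "Bouba-A6", "Kiki-A6"),
    "H2": ("sourness", "Kiki-A6", "Bouba-A6"),
    "H3": ("bitterness", "Kiki-A6", "Bouba-A6"),
    "H4": ("sweetness", "Bouba-S6", "Bouba-A6"),
    "H5": ("sourness", "Kiki-A10", "Kiki-A6"),
    "H6": ("bitterness", "Kiki-A10", "Kiki-A6"),
}

#: Posterior-mean (EAP) point estimates of the condition means reported by
#: the original chocolate-shape tasting study, per taste, in canonical shape
#: order.  Used as generator truth for study-like synthetic data.
REFERENCE_EAP: dict[str, tuple[float, float, float, float]] = {
    "sweetness": (38.52, 28.90, 40.63, 30.67),
    "sourness": (28.49, 33.45, 25.75, 28.91),
    "bitterness": (54.29, 55.21, 49.14, 54.40),
}

#: Published 4x4 directional-probability matrices, entry (i, j) = posterior
#: probability that condition i was rated higher than condition j for the
#: given taste; diagonal fixed at 0 by convention.
REFERENCE_PROBABILITY_TABLES: dict[str, np.ndarray] = {
    "sweetness": np.array(
        [
            [0.0, 0.987, 0.345, 0.956],
            [0.013, 0.0, 0.013, 0.349],
            [0.655, 0.987, 0.0, 0.966],
            [0.044, 0.651, 0.034, 0.0],
        ]
    ),
    "sourness": np.array(
        [
            [0.0, 0.180, 0.705, 0.465],
            [0.820, 0.0, 0.917, 0.779],
            [0.295, 0.083, 0.0, 0.272],
            [0.535, 0.221, 0.728, 0.0],
        ]
    ),
    "bitterness": np.array(
        [
            [0.0, 0.427, 0.822, 0.494],
            [0.573, 0.0, 0.851, 0.563],
            [0.178, 0.149, 0.0, 0.206],
            [0.506, 0.437, 0.794, 0.0],
        ]
    ),
}

#: Compound shape-family comparison per taste: which family is hypothesised
#: to dominate.  Sweetness: rounded > angular; sourness/bitterness:
#: angular > rounded.
COMPOUND_DIRECTION: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "sweetness": (BOUBA_INDICES, KIKI_INDICES),
    "sourness": (KIKI_INDICES, BOUBA_INDICES),
    "bitterness": (KIKI_INDICES, BOUBA_INDICES),
}


def shape_index(shape: str) -> int:
    """Return the canonical index of a shape label."""
    try:
        return SHAPES.index(shape)
    except ValueError:
        raise ValueError(f"unknown shape label: {shape!r}") from None
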