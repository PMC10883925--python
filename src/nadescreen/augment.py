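"""Random-negative data augmentation for the imbalanced mixture database.

Random mixtures of 3-5 distinct library compounds at coefficients 1-10 are
labeled unstable and appended to the training set only; the rationale is that
a random mixture is overwhelmingly unlikely to be a stable solvent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemtext import CompoundRecord, MixtureSpec

__all__ = ["AugmentationPlan", "generate_negative_mixtures", "augment_training_set"]

AUGMENTATION_LEVELS = (1, 5, 10, 25, 50, 100, 500)


@dataclass
class AugmentationPlan:
    n_negatives: int
    library: Sequence[CompoundRecord]
    component_range: tuple[int, int] = (3, 5)
    coefficient_range: tuple[int, int] = (1, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negatives < 0:
            raise ValueError("n_negatives must be >= 0")
        k_lo, k_hi = self.component_range
        c_lo, c_hi = self.coefficient_range
        if not (1 <= k_lo <= k_hi):
            raise ValueError(f"invalid component range {self.component_range}")
        if not (1 <= c_lo <= c_hi <= 10):
            raise ValueError(f"invalid coefficient range {self.coefficient_range}")


def generate_negative_mixtures(
    plan: AugmentationPlan,
    known_db: Sequence[MixtureSpec] = (),
) -> list[MixtureSpec]:
    """Draw ``plan.n_negatives`` random label-0 mixtures.

    Component count is uniform on the plan's range, components are distinct,
    coefficients uniform on the coefficient range.  Draws colliding (multiset
    equality) with *known_db* or an earlier draw are rejected and redrawn; a
    bounded rejection loop raises once the candidate slice looks exhausted.
    """
    library = list(plan.library)
    k_lo, k_hi = plan.component_range
    if len(library) < k_hi:
        raise ValueError(
            f"library of {len(library)} compounds cannot supply {k_hi} "
            "distinct components")
    rng = np.random.default_rng(plan.seed)
    c_lo, c_hi = plan.coefficient_range
    seen = {m.key() for m in known_db}
    out: list[MixtureSpec] = []
    attempts = 0
    cap = max(1000, 200 * (plan.n_negatives + 1))
    while len(out) < plan.n_negatives:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"rejection cap {cap} exceeded after generating "
                f"{len(out)}/{plan.n_negatives} negatives; the requested slice "
                "of mixture space appears exhausted")
        k = int(rng.integers(k_lo, k_hi + 1))
        idx = rng.choice(len(library), size=k, replace=False)
        components = tuple(
            (library[i], int(rng.integers(c_lo, c_hi + 1))) for i in idx)
        m = MixtureSpec(components=components, label=0)
        if m.key() in seen:
            continue
        seen.add(m.key())
        out.append(m)
    return out


def augment_training_set(
    train: Sequence[MixtureSpec],
    negatives: Sequence[MixtureSpec],
    seed: int = 0,
) -> list[MixtureSpec]:
    """Concatenate and seed-shuffle; the test set is untouched by contract."""
    for m in negatives:
        if m.label != 0:
            raise ValueError(
                f"augmentation negative carries label {m.label!r}, expected 0")
    combined = list(train) + list(negatives)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combined))
    return [combined[i] for i in order]
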