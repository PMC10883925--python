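"""Synthetic stand-in data.

Real screening corpora of this kind (a curated labeled mixture database and a
large reaction corpus) are not redistributable, so this module builds a fully
synthetic world that is shaped like them: a 198-compound library of
valid-by-construction acyclic C/O/N SMILES, a deterministic latent stability
rule that is visible in the encoded token stream, a 1000-mixture labeled
database at an 800/200 stable/unstable composition, and a small reaction
corpus.

The latent rule labels a mixture stable iff the coefficient-weighted oxygen
count lies in a window and the coefficient-weighted nitrogen count meets a
minimum.  Both quantities are exact functions of the token sequence the
classifier sees, so the learning task is well-posed and auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chemtext import (
    Canonicalizer,
    CompoundRecord,
    MixtureSpec,
    canonicalize_smiles,
    tokenize_smiles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityRule", "SyntheticWorld",
    "make_compound_library", "latent_stability", "make_labeled_db",
    "make_reaction_corpus", "make_world", "heteroatom_counts",
    "MARKER_NAME",
]

MARKER_NAME = "marker"

# Grammar knobs for the compound library: backbone length, atom draw weights,
# branch probability.  Branches only hang off backbone carbons so every
# generated string is valence-valid.
_CHAIN_MIN, _CHAIN_MAX = 2, 8
_ATOMS = ("C", "O", "N")
_ATOM_WEIGHTS = (0.60, 0.24, 0.16)
_BRANCH_PROB = 0.30
# Every library compound carries at least one nitrogen so that, in the default
# world, the rule's nitrogen minimum of 1 is met by construction and labels
# hinge on the oxygen window alone - which keeps the labeled DB exactly
# separable in the rule's own features.
_REQUIRE_NITROGEN = True


@dataclass(frozen=True)
class StabilityRule:
    """Window on weighted oxygen count plus a weighted nitrogen minimum."""

    o_lo: int = 4
    o_hi: int = 16
    n_min: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.o_lo <= self.o_hi:
            raise ValueError(f"invalid oxygen window [{self.o_lo}, {self.o_hi}]")
        if self.n_min < 0:
            raise ValueError("n_min must be non-negative")


def heteroatom_counts(smiles: str) -> tuple[int, int]:
    """(#O, #N) atom tokens in a SMILES string."""
    tokens = tokenize_smiles(smiles)
    return tokens.count("O"), tokens.count("N")


def latent_stability(
    mixture: MixtureSpec,
    rule: StabilityRule,
    library: Optional[Sequence[CompoundRecord]] = None,
) -> int:
    """Deterministic stability label {0, 1} of a mixture under *rule*.

    Stable (1) iff ``o_lo <= sum_i c_i * #O_i <= o_hi`` and
    ``sum_i c_i * #N_i >= n_min``.  When *library* is given, every component
    must belong to it.
    """
    if library is not None:
        known = {rec.smiles for rec in library}
        for compound, _ in mixture.components:
            if compound.smiles not in known:
                raise ValueError(
                    f"unknown compound {compound.smiles!r}: not in the world library")
    o_total = n_total = 0
    for compound, coef in mixture.components:
        n_o, n_n = heteroatom_counts(compound.smiles)
        o_total += coef * n_o
        n_total += coef * n_n
    stable = (rule.o_lo <= o_total <= rule.o_hi) and (n_total >= rule.n_min)
    return int(stable)


@dataclass
class SyntheticWorld:
    """Library + latent rule + seed; the marker compound stands in for a
    query drug during screening."""

    library: list[CompoundRecord]
    rule: StabilityRule
    seed: int
    composition: dict = field(default_factory=dict)  # smiles -> (#O, #N)

    @property
    def marker(self) -> CompoundRecord:
        for rec in self.library:
            if rec.name == MARKER_NAME:
                return rec
        raise ValueError("world library has no marker compound")

    def latent_stability(self, mixture: MixtureSpec) -> int:
        return latent_stability(mixture, self.rule, library=self.library)


def _random_compound_smiles(rng: np.random.Generator) -> str:
    length = int(rng.integers(_CHAIN_MIN, _CHAIN_MAX + 1))
    backbone = rng.choice(len(_ATOMS), size=length, p=_ATOM_WEIGHTS)
    if _REQUIRE_NITROGEN and 2 not in backbone:
        backbone[rng.integers(length)] = 2  # nitrogen tolerates any slot
    parts = []
    for pos, atom_idx in enumerate(backbone):
        atom = _ATOMS[atom_idx]
        parts.append(atom)
        # a branch needs a spare valence: carbon always has one, a nitrogen
        # only in the chain interior; oxygen never does
        can_branch = atom == "C" or (atom == "N" and 0 < pos < length - 1)
        if can_branch and rng.random() < _BRANCH_PROB:
            branch_atom = _ATOMS[rng.choice(len(_ATOMS), p=_ATOM_WEIGHTS)]
            parts.append(f"({branch_atom})")
    return "".join(parts)


def make_compound_library(
    n: int = 198,
    seed: int = 0,
    canonicalizer: Optional[Canonicalizer] = None,
) -> list[CompoundRecord]:
    """*n* unique canonical SMILES from the acyclic C/O/N grammar.

    The first compound is named ``marker`` and plays the designated query
    compound's role in screening tests.
    """
    if n < 6:
        raise ValueError(f"library needs at least 6 compounds, got {n}")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    smiles_list: list[str] = []
    attempts = 0
    cap = 200 * n
    while len(smiles_list) < n:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"grammar capacity exhausted: {len(smiles_list)}/{n} unique "
                f"compounds after {attempts} draws")
        smiles = canonicalize_smiles(_random_compound_smiles(rng), canonicalizer)
        if smiles not in seen:
            seen.add(smiles)
            smiles_list.append(smiles)
    library = []
    for i, smiles in enumerate(smiles_list):
        name = MARKER_NAME if i == 0 else f"cmp-{i:03d}"
        library.append(CompoundRecord(name=name, smiles=smiles))
    return library


def make_world(
    n_compounds: int = 198,
    seed: int = 0,
    rule: Optional[StabilityRule] = None,
    canonicalizer: Optional[Canonicalizer] = None,
) -> SyntheticWorld:
    library = make_compound_library(n_compounds, seed, canonicalizer)
    world = SyntheticWorld(
        library=library,
        rule=rule if rule is not None else StabilityRule(),
        seed=seed,
        composition={rec.smiles: heteroatom_counts(rec.smiles) for rec in library},
    )
    return world


def make_labeled_db(
    world: SyntheticWorld,
    n: int = 1000,
    n_stable: int = 800,
    seed: int = 0,
    component_range: tuple[int, int] = (2, 3),
    coefficient_range: tuple[int, int] = (1, 10),
) -> list[MixtureSpec]:
    """Rejection-sample a labeled DB with exactly *n_stable* rule-positives.

    Labels come from the latent rule, so relabeling the output reproduces the
    stored labels exactly; mixtures are unique under the multiset rule.
    """
    if not 0 <= n_stable <= n:
        raise ValueError(f"n_stable {n_stable} outside [0, {n}]")
    rng = np.random.default_rng(seed)
    k_lo, k_hi = component_range
    c_lo, c_hi = coefficient_range

    def draw() -> MixtureSpec:
        k = int(rng.integers(k_lo, k_hi + 1))
        idx = rng.choice(len(world.library), size=k, replace=False)
        components = tuple(
            (world.library[i], int(rng.integers(c_lo, c_hi + 1))) for i in idx)
        return MixtureSpec(components=components)

    # pilot: both classes must be attainable under the generator ranges
    pilot = [world.latent_stability(draw()) for _ in range(200)]
    rate = sum(pilot) / len(pilot)
    if n_stable > 0 and rate == 0.0:
        raise RuntimeError(
            "latent rule unsatisfiable under generator ranges (pilot "
            "acceptance rate 0.0 for stable)")
    if n - n_stable > 0 and rate == 1.0:
        raise RuntimeError(
            "latent rule never rejects under generator ranges (pilot "
            "acceptance rate 1.0 for stable)")

    stable: list[MixtureSpec] = []
    unstable: list[MixtureSpec] = []
    seen: set = set()
    attempts = 0
    cap = max(10_000, 500 * n)
    while len(stable) < n_stable or len(unstable) < n - n_stable:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"rejection cap {cap} exceeded: collected {len(stable)} stable "
                f"/ {len(unstable)} unstable (pilot stable rate {rate:.2f})")
        m = draw()
        if m.key() in seen:
            continue
        label = world.latent_stability(m)
        bucket, want = (stable, n_stable) if label else (unstable, n - n_stable)
        if len(bucket) < want:
            seen.add(m.key())
            bucket.append(m.with_label(label))
    db = stable + unstable
    order = rng.permutation(len(db))
    return [db[i] for i in order]


def _product_of(reactant_smiles: str) -> str:
    """Deterministic token edit standing in for a chemical transformation."""
    tokens = tokenize_smiles(reactant_smiles)
    if "O" in tokens:
        tokens = ["N" if t == "O" else t for t in tokens]
    else:
        tokens = ["O" if t == "C" else t for t in tokens]
    return "".join(tokens)


def make_reaction_corpus(
    world: SyntheticWorld,
    n_lines: int,
    seed: int = 0,
) -> list[str]:
    """``A.B>C`` lines with C a deterministic edit of A; one ``>`` per line."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    lines = []
    for _ in range(n_lines):
        a, b = (world.library[i].smiles
                for i in rng.choice(len(world.library), size=2, replace=False))
        lines.append(f"{a}.{b}>{_product_of(a)}")
    return lines
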