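"""Virtual screening: candidate universe generation, batch classification,
compound filtering, score binning, CSV export, and mixture-space counting."""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from .chemtext import (
    Canonicalizer,
    CompoundRecord,
    EncodedMixture,
    MixtureSpec,
    canonicalize_smiles,
    encode_mixture,
    tokenize_smiles,
)
from .model import ScoredMixture, StabilityClassifier, predict_scores

__all__ = [
    "Universe", "ScoreHistogram",
    "generate_universe", "iter_universe", "write_universe", "read_universe",
    "screen_universe", "filter_by_compound", "bin_scores",
    "export_results_csv", "count_ternary_combinations",
]


@dataclass
class Universe:
    """Unlabeled candidate mixtures plus the generator's provenance."""

    mixtures: list[MixtureSpec]
    seed: int
    component_range: tuple[int, int] = (3, 5)
    coefficient_range: tuple[int, int] = (1, 10)
    library_size: int = 0

    def __len__(self) -> int:
        return len(self.mixtures)


@dataclass
class ScoreHistogram:
    """Counts of scores above 50% in left-open 5-point bins.

    Bin *i* covers the interval ``(50+5i, 50+5(i+1)]`` in percent, labeled
    ``"50.1-55"`` .. ``"95.1-100"``.
    """

    labels: tuple[str, ...]
    counts: list[int] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts)


_BIN_LABELS = tuple(f"{lo}.1–{lo + 5}" for lo in range(50, 100, 5))


def iter_universe(
    n: int,
    library: Sequence[CompoundRecord],
    seed: int,
    component_range: tuple[int, int] = (3, 5),
    coefficient_range: tuple[int, int] = (1, 10),
) -> Iterator[MixtureSpec]:
    """Stream *n* random unlabeled mixtures (distinct components, uniform
    component count and coefficients)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    k_lo, k_hi = component_range
    c_lo, c_hi = coefficient_range
    if len(library) < k_hi:
        raise ValueError(
            f"library of {len(library)} compounds cannot supply {k_hi} "
            "distinct components")
    rng = np.random.default_rng(seed)
    lib = list(library)
    for _ in range(n):
        k = int(rng.integers(k_lo, k_hi + 1))
        idx = rng.choice(len(lib), size=k, replace=False)
        coefs = rng.integers(c_lo, c_hi + 1, size=k)
        yield MixtureSpec(components=tuple(
            (lib[i], int(c)) for i, c in zip(idx, coefs)))


def generate_universe(
    n: int,
    library: Sequence[CompoundRecord],
    seed: int,
    component_range: tuple[int, int] = (3, 5),
    coefficient_range: tuple[int, int] = (1, 10),
) -> Universe:
    """Materialized universe; for very large *n* prefer :func:`iter_universe`."""
    mixtures = list(iter_universe(n, library, seed, component_range,
                                  coefficient_range))
    return Universe(mixtures=mixtures, seed=seed,
                    component_range=component_range,
                    coefficient_range=coefficient_range,
                    library_size=len(library))


def write_universe(
    universe: Union[Universe, Iterable[MixtureSpec]],
    path: Union[str, Path],
) -> int:
    """One encoded mixture per line; returns the number of lines written."""
    mixtures = universe.mixtures if isinstance(universe, Universe) else universe
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for m in mixtures:
            fh.write(encode_mixture(m).text + "\n")
            n += 1
    return n


def read_universe(path: Union[str, Path]) -> list[str]:
    try:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise IOError(f"cannot read universe file {path}: {exc}") from exc
    return [line for line in lines if line.strip()]


def screen_universe(
    classifier: StabilityClassifier,
    universe: Union[Universe, Sequence[MixtureSpec], Sequence[str], str, Path],
    batch_size: int = 64,
) -> list[ScoredMixture]:
    """Score every universe entry, order preserved, streaming over batches."""
    if isinstance(universe, (str, Path)):
        entries: Sequence = read_universe(universe)
    elif isinstance(universe, Universe):
        entries = universe.mixtures
    else:
        entries = list(universe)
    out: list[ScoredMixture] = []
    batch: list = []
    for i, entry in enumerate(entries):
        if isinstance(entry, str):
            try:
                tokens = tuple(tokenize_smiles(entry))
                entry = EncodedMixture(text=entry, tokens=tokens)
            except Exception as exc:  # pragma: no cover - tokenizer is total
                raise IOError(f"unreadable universe entry at line {i + 1}") from exc
        batch.append(entry)
        if len(batch) == batch_size:
            out.extend(predict_scores(classifier, batch, batch_size=batch_size))
            batch = []
    if batch:
        out.extend(predict_scores(classifier, batch, batch_size=batch_size))
    return out


def _component_smiles(encoded_text: str) -> list[tuple[int, str]]:
    """(coefficient, SMILES) units of an encoded mixture line."""
    from .chemtext import decode_mixture

    spec = decode_mixture(encoded_text)
    return [(coef, rec.smiles) for rec, coef in spec.components]


def filter_by_compound(
    scored: Sequence[ScoredMixture],
    query_smiles: str,
    canonicalizer: Optional[Canonicalizer] = None,
) -> list[ScoredMixture]:
    """Records whose component multiset contains the (canonicalized) query,
    sorted by descending score, ties broken by encoded-string order."""
    query = canonicalize_smiles(query_smiles, canonicalizer)
    hits = [s for s in scored
            if any(smiles == query
                   for _, smiles in _component_smiles(s.mixture.text))]
    return sorted(hits, key=lambda s: (-s.score, s.mixture.text))


def bin_scores(scored: Sequence[ScoredMixture]) -> ScoreHistogram:
    """Histogram of scores above 50% in left-open 5-percentage-point bins."""
    counts = [0] * len(_BIN_LABELS)
    for s in scored:
        pct = round(100.0 * s.score, 9)
        if pct <= 50.0:
            continue
        idx = int(math.ceil((pct - 50.0) / 5.0)) - 1
        idx = min(idx, len(counts) - 1)
        counts[idx] += 1
    return ScoreHistogram(labels=_BIN_LABELS, counts=counts)


def export_results_csv(
    scored: Sequence[ScoredMixture],
    path: Union[str, Path],
) -> None:
    """Deterministic CSV: ``components,ratios,encoded,score,label`` with the
    score printed to 4 decimals."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["components", "ratios", "encoded", "score", "label"])
        for s in scored:
            units = _component_smiles(s.mixture.text)
            writer.writerow([
                ";".join(smiles for _, smiles in units),
                ":".join(str(coef) for coef, _ in units),
                s.mixture.text,
                f"{s.score:.4f}",
                s.label,
            ])


def count_ternary_combinations(pool_size: int) -> int:
    """Exact number of 3-subsets of a pool, as an arbitrary-precision int."""
    if pool_size < 3:
        raise ValueError(f"pool_size must be >= 3, got {pool_size}")
    return math.comb(pool_size, 3)
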