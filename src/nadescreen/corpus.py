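"""Reaction-corpus preparation and dataset splitting / deduplication."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .chemtext import MixtureSpec

__all__ = [
    "ReactionRecord", "DatasetSplit", "DedupReport",
    "merge_reaction_files", "merge_reaction_paths", "read_lines", "write_lines",
    "split_dataset", "dedup_across",
]


@dataclass(frozen=True)
class ReactionRecord:
    """Dot-joined reactant SMILES and product SMILES, rendered ``reactants>products``."""

    reactants: str
    products: str

    def render(self) -> str:
        return f"{self.reactants}>{self.products}"

    @classmethod
    def parse(cls, line: str) -> "ReactionRecord":
        parts = line.split(">")
        if len(parts) != 2:
            raise ValueError(
                f"reaction line must contain exactly one '>': {line!r}")
        return cls(reactants=parts[0], products=parts[1])


@dataclass
class DatasetSplit:
    train: list[MixtureSpec]
    test: list[MixtureSpec]
    test_fraction: float
    seed: int


@dataclass
class DedupReport:
    removed: list[MixtureSpec] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def read_lines(path: Union[str, Path]) -> list[str]:
    return Path(path).read_text(encoding="utf-8").splitlines()


def write_lines(path: Union[str, Path], lines: Sequence[str]) -> None:
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def merge_reaction_files(src_lines: Sequence[str], tgt_lines: Sequence[str]) -> list[str]:
    """Pair source line *i* with target line *i* as ``src>tgt``.

    The two files must have equal line counts; the merged corpus preserves
    the count and is invertible by splitting on the single ``>``.
    """
    if len(src_lines) != len(tgt_lines):
        raise ValueError(
            f"source and target line counts differ: {len(src_lines)} vs "
            f"{len(tgt_lines)}")
    return [f"{src}>{tgt}" for src, tgt in zip(src_lines, tgt_lines)]


def merge_reaction_paths(
    src_path: Union[str, Path],
    tgt_path: Union[str, Path],
    out_path: Union[str, Path],
) -> int:
    """Merge paired source/target reaction files (the ``src-train.txt`` /
    ``tgt-train.txt`` layout) into a one-line-per-reaction corpus file.

    Returns the number of reactions written.
    """
    merged = merge_reaction_files(read_lines(src_path), read_lines(tgt_path))
    write_lines(out_path, merged)
    return len(merged)


def split_dataset(
    db: Sequence[MixtureSpec],
    test_fraction: float,
    seed: int,
    stratify: bool = False,
) -> DatasetSplit:
    """Seeded uniform random split without replacement.

    ``|test| = round(test_fraction * N)``; unstratified by default.  With
    ``stratify=True`` the rounding rule is applied per label class.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    if stratify:
        train: list[MixtureSpec] = []
        test: list[MixtureSpec] = []
        labels = sorted({m.label for m in db}, key=lambda x: (x is None, x))
        for lab in labels:
            idx = [i for i, m in enumerate(db) if m.label == lab]
            n_test = int(round(test_fraction * len(idx)))
            chosen = set(rng.choice(len(idx), size=n_test, replace=False).tolist())
            for j, i in enumerate(idx):
                (test if j in chosen else train).append(db[i])
    else:
        n_test = int(round(test_fraction * len(db)))
        chosen = set(rng.choice(len(db), size=n_test, replace=False).tolist())
        test = [db[i] for i in range(len(db)) if i in chosen]
        train = [db[i] for i in range(len(db)) if i not in chosen]
    return DatasetSplit(train=train, test=test, test_fraction=test_fraction, seed=seed)


def dedup_across(
    train: Sequence[MixtureSpec],
    test: Sequence[MixtureSpec],
) -> tuple[list[MixtureSpec], DedupReport]:
    """Drop training mixtures that duplicate a test mixture.

    Equality is the exact multiset of (canonical SMILES, coefficient); ratios
    are deliberately not rescaled, so 1:1:1 and 4:1:1 of the same compounds
    are distinct entries.
    """
    test_keys = {m.key() for m in test}
    kept: list[MixtureSpec] = []
    report = DedupReport()
    for m in train:
        if m.key() in test_keys:
            report.removed.append(m)
        else:
            kept.append(m)
    return kept, report
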