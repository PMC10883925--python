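"""SMILES text handling.

Tokenization, the mixture string-encoding format with stoichiometric-ratio
special tokens, vocabulary construction, and the plain-text dialects used to
exchange compound libraries and labeled mixture datasets.

A mixture of ethanol (2 parts) and water (1 part) is rendered as the single
line ``[R2]CCO.[R1]O``: each component is prefixed by a ratio token ``[Rc]``
(``c`` in 1..10) and components are joined by ``.``, sorted lexicographically
by canonical SMILES so the encoding is independent of input order.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "PAD", "UNK", "CLS", "SEP", "MASK", "GT",
    "RATIO_TOKENS", "SPECIAL_TOKENS", "RATIO_MIN", "RATIO_MAX",
    "SmilesParseError", "MixtureFormatError",
    "CompoundRecord", "MixtureSpec", "EncodedMixture", "Vocabulary",
    "canonicalize_smiles", "rdkit_canonicalizer", "identity_canonicalizer",
    "tokenize_smiles", "encode_mixture", "decode_mixture", "build_vocabulary",
    "read_compound_library", "write_compound_library",
    "read_labeled_mixtures", "write_labeled_mixtures",
]

# ---------------------------------------------------------------------------
# Special tokens

PAD = "[PAD]"
UNK = "[UNK]"
CLS = "[CLS]"
SEP = "[SEP]"
MASK = "[MASK]"
GT = ">"  # reaction separator between reactants and products

RATIO_MIN = 1
RATIO_MAX = 10
RATIO_TOKENS = tuple(f"[R{c}]" for c in range(RATIO_MIN, RATIO_MAX + 1))
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP, MASK, GT) + RATIO_TOKENS

_RATIO_RE = re.compile(r"^\[R(10|[1-9])\]$")


class SmilesParseError(ValueError):
    """Raised when a string cannot be parsed as SMILES."""


class MixtureFormatError(ValueError):
    """Raised when an encoded mixture line does not follow the format."""


# ---------------------------------------------------------------------------
# Canonicalization (pluggable contract)

Canonicalizer = Callable[[str], str]

_rdkit_ready = False


def rdkit_canonicalizer(smiles: str) -> str:
    """Canonicalize with RDKit; raises :class:`SmilesParseError` on failure."""
    global _rdkit_ready
    from rdkit import Chem

    if not _rdkit_ready:
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
        _rdkit_ready = True
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"not a valid SMILES string: {smiles!r}")
    return Chem.MolToSmiles(mol)


def identity_canonicalizer(smiles: str) -> str:
    """Fallback used when no chemistry engine is available."""
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    return smiles


def default_canonicalizer() -> Canonicalizer:
    try:
        import rdkit  # noqa: F401

        return rdkit_canonicalizer
    except ImportError:  # pragma: no cover - rdkit is a declared dependency
        logger.warning("no chemistry engine available; using identity canonicalizer")
        return identity_canonicalizer


def canonicalize_smiles(smiles: str, canonicalizer: Optional[Canonicalizer] = None) -> str:
    """Return the canonical form of *smiles* under the plugged canonicalizer.

    Deterministic and idempotent: ``f(f(x)) == f(x)``.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    if canonicalizer is None:
        canonicalizer = default_canonicalizer()
    return canonicalizer(smiles)


# ---------------------------------------------------------------------------
# Tokenization

# Bracket expressions (which cover the [Rc] ratio tokens and bracket atoms)
# first, then the two-letter organic-subset halogens, then any single
# character.  The fallback makes the tokenizer total and lossless.
_TOKEN_RE = re.compile(r"\[[^\]]*\]|Cl|Br|.")


def tokenize_smiles(text: str) -> list[str]:
    """Atom-level SMILES tokenization.

    Two-letter atoms (``Cl``, ``Br``) and bracket expressions ``[...]`` are
    single tokens; every other character is its own token.  Concatenating the
    tokens reproduces the input exactly; unknown characters survive as
    single-character tokens and are mapped to ``[UNK]`` by the vocabulary.
    """
    return _TOKEN_RE.findall(text)


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class CompoundRecord:
    """A named compound with a canonical SMILES string."""

    name: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("CompoundRecord.smiles must be non-empty")


@dataclass(frozen=True)
class MixtureSpec:
    """A multiset of (compound, integer coefficient) with an optional label."""

    components: tuple[tuple[CompoundRecord, int], ...]
    label: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(
            (c, int(k)) for c, k in self.components))
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    def key(self) -> tuple[tuple[str, int], ...]:
        """Order-insensitive multiset identity of (canonical SMILES, coefficient)."""
        return tuple(sorted((c.smiles, k) for c, k in self.components))

    def sorted_components(self) -> tuple[tuple[CompoundRecord, int], ...]:
        return tuple(sorted(self.components, key=lambda ck: (ck[0].smiles, ck[1])))

    def with_label(self, label: Optional[int]) -> "MixtureSpec":
        return MixtureSpec(self.components, label)

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class EncodedMixture:
    """A mixture rendered as a single tokenizable line."""

    text: str
    tokens: tuple[str, ...]


# ---------------------------------------------------------------------------
# Mixture encoding / decoding

def encode_mixture(m: MixtureSpec) -> EncodedMixture:
    """Render a mixture as ``[Rc]SMILES`` units joined by ``.``.

    Components are sorted lexicographically by canonical SMILES, so any
    permutation of the same mixture encodes identically.
    """
    if not m.components:
        raise MixtureFormatError("cannot encode a mixture with no components")
    for compound, coef in m.components:
        if not RATIO_MIN <= coef <= RATIO_MAX:
            raise ValueError(
                f"stoichiometric coefficient {coef} for {compound.smiles!r} "
                f"outside [{RATIO_MIN}, {RATIO_MAX}]")
    parts = [f"[R{coef}]{compound.smiles}"
             for compound, coef in m.sorted_components()]
    text = ".".join(parts)
    return EncodedMixture(text=text, tokens=tuple(tokenize_smiles(text)))


# Split only on dots that start the next ratio-token unit, so dots inside a
# multi-fragment component SMILES are preserved.
_UNIT_SPLIT_RE = re.compile(r"\.(?=\[R(?:10|[1-9])\])")
_UNIT_RE = re.compile(r"^\[R(10|[1-9])\](.+)$")


def decode_mixture(
    e: Union[EncodedMixture, str],
    library: Sequence[CompoundRecord] = (),
    label: Optional[int] = None,
) -> MixtureSpec:
    """Inverse of :func:`encode_mixture` up to component reordering.

    SMILES not found in *library* yield anonymous records named after the
    SMILES itself.
    """
    text = e.text if isinstance(e, EncodedMixture) else e
    if not text:
        raise MixtureFormatError("empty encoded mixture")
    lookup = {rec.smiles: rec for rec in library}
    components = []
    for part in _UNIT_SPLIT_RE.split(text):
        match = _UNIT_RE.match(part)
        if match is None:
            raise MixtureFormatError(
                f"malformed mixture unit {part!r} in line {text!r}: expected "
                "'[Rc]SMILES'")
        coef = int(match.group(1))
        smiles = match.group(2)
        record = lookup.get(smiles, CompoundRecord(name=smiles, smiles=smiles))
        components.append((record, coef))
    return MixtureSpec(components=tuple(components), label=label)


# ---------------------------------------------------------------------------
# Vocabulary

@dataclass(frozen=True)
class Vocabulary:
    """Bijective token<->id map; special tokens occupy the lowest ids."""

    tokens: tuple[str, ...]
    token_to_id: dict = field(repr=False)

    @classmethod
    def from_tokens(cls, tokens: Sequence[str]) -> "Vocabulary":
        tokens = tuple(tokens)
        t2i = {t: i for i, t in enumerate(tokens)}
        if len(t2i) != len(tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for special in SPECIAL_TOKENS:
            if special not in t2i:
                raise ValueError(f"special token {special!r} missing")
        return cls(tokens=tokens, token_to_id=t2i)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(self.token_to_id[t] for t in SPECIAL_TOKENS)

    def id(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def encode_tokens(self, tokens: Iterable[str]) -> list[int]:
        unk = self.unk_id
        return [self.token_to_id.get(t, unk) for t in tokens]

    def decode_ids(self, ids: Iterable[int]) -> list[str]:
        return [self.tokens[i] for i in ids]

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Vocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls.from_tokens(lines)


def build_vocabulary(corpus: Iterable[str], vocab_size: int) -> Vocabulary:
    """Frequency-ranked vocabulary over tokenized corpus lines.

    Special tokens come first; remaining slots are filled by corpus tokens in
    descending frequency (ties broken lexicographically) up to *vocab_size*.
    """
    if vocab_size < len(SPECIAL_TOKENS) + 1:
        raise ValueError(
            f"vocab_size {vocab_size} leaves no room beyond the "
            f"{len(SPECIAL_TOKENS)} special tokens")
    counts: Counter[str] = Counter()
    n_lines = 0
    for line in corpus:
        n_lines += 1
        counts.update(tokenize_smiles(line.rstrip("\n")))
    if n_lines == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    specials = set(SPECIAL_TOKENS)
    ranked = sorted(
        (t for t in counts if t not in specials),
        key=lambda t: (-counts[t], t))
    tokens = list(SPECIAL_TOKENS) + ranked[: vocab_size - len(SPECIAL_TOKENS)]
    return Vocabulary.from_tokens(tokens)


# ---------------------------------------------------------------------------
# File dialects

def write_compound_library(path: Union[str, Path], library: Sequence[CompoundRecord]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "smiles"])
        for rec in library:
            writer.writerow([rec.name, rec.smiles])


def read_compound_library(path: Union[str, Path]) -> list[CompoundRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["name", "smiles"]:
            raise ValueError(f"{path}: expected header 'name,smiles', got {header!r}")
        return [CompoundRecord(name=row[0], smiles=row[1]) for row in reader if row]


def write_labeled_mixtures(
    path: Union[str, Path],
    mixtures: Sequence[MixtureSpec],
    dialect: str = "ragged",
) -> None:
    """Write mixtures in one of the two labeled-CSV dialects.

    ``ragged``: ``smiles_1,coef_1,...,smiles_n,coef_n,label`` with rows of
    varying width.  ``encoded``: two columns ``encoded,label``.
    """
    if dialect not in ("ragged", "encoded"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if dialect == "encoded":
            writer.writerow(["encoded", "label"])
            for m in mixtures:
                writer.writerow([encode_mixture(m).text, _label_str(m)])
        else:
            k_max = max((m.n_components for m in mixtures), default=1)
            header = []
            for i in range(1, k_max + 1):
                header += [f"smiles_{i}", f"coef_{i}"]
            writer.writerow(header + ["label"])
            for m in mixtures:
                row = []
                for compound, coef in m.sorted_components():
                    row += [compound.smiles, str(coef)]
                writer.writerow(row + [_label_str(m)])


def _label_str(m: MixtureSpec) -> str:
    return "" if m.label is None else str(m.label)


def read_labeled_mixtures(
    path: Union[str, Path],
    library: Sequence[CompoundRecord] = (),
) -> list[MixtureSpec]:
    """Read either labeled-CSV dialect, auto-detected from the header."""
    lookup = {rec.smiles: rec for rec in library}
    mixtures: list[MixtureSpec] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty labeled-mixture file")
        if [h.strip() for h in header[:1]] == ["encoded"]:
            for row in reader:
                if not row:
                    continue
                label = int(row[1]) if len(row) > 1 and row[1] != "" else None
                mixtures.append(decode_mixture(row[0], library, label=label))
            return mixtures
        if not header[0].startswith("smiles_"):
            raise ValueError(
                f"{path}: unrecognized header {header!r}; expected the "
                "'smiles_1,coef_1,...' or 'encoded,label' dialect")
        for row in reader:
            row = [cell for cell in row if cell != ""]
            if not row:
                continue
            if len(row) % 2 == 0:
                raise ValueError(
                    f"{path}: malformed row {row!r}; expected SMILES/coefficient "
                    "pairs followed by a label")
            label_cell, pairs = row[-1], row[:-1]
            components = []
            for i in range(0, len(pairs), 2):
                smiles = pairs[i]
                coef = int(pairs[i + 1])
                record = lookup.get(smiles, CompoundRecord(name=smiles, smiles=smiles))
                components.append((record, coef))
            mixtures.append(MixtureSpec(tuple(components), label=int(label_cell)))
    return mixtures
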