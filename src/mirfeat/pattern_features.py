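"""Sequence-structure pattern features: triplets, stacking triplets, motifs.

The triplet encoding collapses both bracket characters of the dot-bracket
string to a single "paired" state '(' and records, for every interior
position, the middle nucleotide together with the paired/unpaired pattern of
the three contiguous positions — 4 nucleotides × 8 patterns = 32 relative
frequencies.  Terminal bases have no complete window and are excluded.
Structures with multiple loops are handled like any other (no single-loop
restriction).

The motif features count overlapping occurrences of sequence-structure
motifs in the padded sequence-structure string, whose tokens are
(nucleotide, state) with state in {left-paired '(', right-paired ')',
unpaired '.'} — a 12-token alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .rna_structures import SecondaryStructure

__all__ = [
    "TRIPLET_PATTERNS",
    "TRIPLET_NAMES",
    "STATES",
    "triplet_profile",
    "stacking_triplets",
    "ss_string",
    "ss_tokens_to_text",
    "MotifVocabulary",
    "default_vocabulary",
    "motif_counts",
]

NUCLEOTIDES = "ACGU"
#: the 8 paired/unpaired patterns, '(' = paired, '.' = unpaired
TRIPLET_PATTERNS = tuple(
    a + b + c for a in "(." for b in "(." for c in "(."
)
#: fixed ordering of the 32 triplet features: A(((, A((., ..., U...
TRIPLET_NAMES = tuple(
    f"{x}_{p}" for x in NUCLEOTIDES for p in TRIPLET_PATTERNS
)

#: sequence-structure string states
STATES = "()."


def triplet_profile(seq: str, structure: SecondaryStructure) -> dict[str, float]:
    """The 32 triplet relative frequencies ``X_sss``.

    Windows slide over all L−2 interior positions; counts are normalized by
    L−2.  Both '(' and ')' map to the paired state.
    """
    L = len(seq)
    if L < 3 or structure.L != L:
        raise ValueError("triplet profile requires L >= 3 and matching structure")
    collapsed = structure.db.replace(")", "(")
    counts = dict.fromkeys(TRIPLET_NAMES, 0)
    for i in range(1, L - 1):
        key = f"{seq[i]}_{collapsed[i - 1 : i + 2]}"
        counts[key] += 1
    denom = L - 2
    return {k: counts[k] / denom for k in TRIPLET_NAMES}


def stacking_triplets(profile: dict[str, float]) -> dict[str, float]:
    """Projection of the four fully stacked entries X_(((."""
    return {f"stack_{x}": profile[f"{x}_((("] for x in NUCLEOTIDES}


def ss_string(seq: str, structure: SecondaryStructure) -> tuple[tuple[str, str], ...]:
    """The padded sequence-structure string as (nucleotide, state) tokens.

    State is '(' when the base pairs with a downstream partner, ')' with an
    upstream partner, '.' when unpaired.
    """
    if structure.L != len(seq):
        raise ValueError("sequence and structure lengths differ")
    tokens = []
    for i in range(1, len(seq) + 1):
        j = structure.pairs[i]
        state = "." if j == 0 else ("(" if j > i else ")")
        tokens.append((seq[i - 1], state))
    return tuple(tokens)


#: one private character per (nucleotide, state) token, for fast scanning
_TOKEN_CHARS = {
    (n, s): chr(65 + i)
    for i, (n, s) in enumerate(
        (n, s) for n in NUCLEOTIDES for s in STATES
    )
}


def ss_tokens_to_text(tokens: Iterable[tuple[str, str]]) -> str:
    """Render tokens in the motif-file grammar (nucleotide+state pairs)."""
    return "".join(n + s for n, s in tokens)


def _parse_token_text(text: str) -> tuple[tuple[str, str], ...]:
    if len(text) % 2 != 0:
        raise ValueError(f"odd-length motif string {text!r}")
    tokens = []
    for i in range(0, len(text), 2):
        n, s = text[i], text[i + 1]
        if n not in NUCLEOTIDES or s not in STATES:
            raise ValueError(f"illegal token {text[i:i + 2]!r} in motif {text!r}")
        tokens.append((n, s))
    return tuple(tokens)


@dataclass(frozen=True)
class MotifVocabulary:
    """An ordered collection of unique sequence-structure motifs.

    The on-disk grammar is one motif per line, each motif a concatenation of
    nucleotide+state character pairs, e.g. ``A(G(C)`` for the three-token
    motif (A,left)(G,left)(C,right).  Lines starting with '#' are comments.
    """

    id: str
    motifs: tuple[tuple[tuple[str, str], ...], ...]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("empty motif vocabulary")
        if len(set(self.motifs)) != len(self.motifs):
            raise ValueError("duplicate motifs in vocabulary")

    def __len__(self) -> int:
        return len(self.motifs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f"motif_{ss_tokens_to_text(m)}" for m in self.motifs)

    @classmethod
    def from_file(cls, path: str | Path, id: str | None = None) -> "MotifVocabulary":
        motifs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                motifs.append(_parse_token_text(line))
        return cls(id=id or Path(path).stem, motifs=tuple(motifs))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self.motifs:
                fh.write(ss_tokens_to_text(m) + "\n")


def default_vocabulary(size: int = 1300) -> MotifVocabulary:
    """Deterministic stand-in vocabulary of ``size`` motifs.

    The published 1,300-motif list is not part of the public record, so the
    default enumerates all 1- and 2-token motifs over the 12-token alphabet
    (12 + 144) followed by the lexicographically first 3-token motifs,
    truncated to ``size``.  A user-supplied motif file reproduces any other
    vocabulary faithfully.
    """
    alphabet = [(n, s) for n in NUCLEOTIDES for s in STATES]
    motifs: list[tuple[tuple[str, str], ...]] = []
    motifs.extend((t,) for t in alphabet)
    motifs.extend((a, b) for a in alphabet for b in alphabet)
    for a in alphabet:
        for b in alphabet:
            for c in alphabet:
                if len(motifs) >= size:
                    break
                motifs.append((a, b, c))
            if len(motifs) >= size:
                break
        if len(motifs) >= size:
            break
    if len(motifs) < size:
        raise ValueError(f"cannot build {size} motifs from up to 3 tokens")
    return MotifVocabulary(id=f"default-{size}", motifs=tuple(motifs[:size]))


def motif_counts(
    tokens: Iterable[tuple[str, str]], vocab: MotifVocabulary
) -> dict[str, int]:
    """Overlapping occurrence counts of every vocabulary motif."""
    text = "".join(_TOKEN_CHARS[t] for t in tokens)
    out: dict[str, int] = {}
    for name, motif in zip(vocab.names, vocab.motifs):
        pat = "".join(_TOKEN_CHARS[t] for t in motif)
        n = 0
        start = text.find(pat)
        while start != -1:
            n += 1
            start = text.find(pat, start + 1)
        out[name] = n
    return out
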