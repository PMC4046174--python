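"""Features computed from the primary sequence alone.

Covers the sequence-only rows of the feature catalog: the 16 overlapping
dinucleotide frequencies, G+C content, the longest open reading stretch
(maximal run of non-stop codons over the forward frames, in amino acids) and
the percentage of the sequence falling in DUST-style low-complexity regions.
"""

from __future__ import annotations

from typing import Sequence

NUCLEOTIDES = "ACGU"

#: fixed AA..UU ordering of the 16 dinucleotides
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})


class UndefinedFeatureError(ValueError):
    """Raised when a feature is undefined for the given sequence length."""


def dinucleotide_frequencies(seq: str) -> dict[str, float]:
    """Relative frequencies of the 16 dinucleotides over the L−1 overlapping
    windows, in fixed AA..UU order."""
    if len(seq) < 2:
        raise UndefinedFeatureError(
            "dinucleotide frequencies undefined for sequences shorter than 2"
        )
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(len(seq) - 1):
        counts[seq[i : i + 2]] += 1
    denom = len(seq) - 1
    return {d: counts[d] / denom for d in DINUCLEOTIDES}


def gc_content(seq: str) -> float:
    """G+C content as a percentage of sequence length."""
    if not seq:
        raise UndefinedFeatureError("G+C content undefined for empty sequence")
    return 100.0 * sum(1 for c in seq if c in "GC") / len(seq)


def max_aa_run(seq: str, frames: Sequence[int] = (0, 1, 2)) -> int:
    """Longest run of consecutive non-stop codons across reading frames.

    Returned in amino acids.  Only the forward frames are scanned by default;
    pass ``frames=range(6)`` to include the reverse complement frames 3–5.
    Sequences shorter than one codon score 0.
    """
    if len(seq) < 3:
        return 0
    best = 0
    for frame in frames:
        if frame >= 3:
            s = _revcomp(seq)
            f = frame - 3
        else:
            s, f = seq, frame
        run = 0
        for i in range(f, len(s) - 2, 3):
            if s[i : i + 3] in STOP_CODONS:
                run = 0
            else:
                run += 1
                best = max(best, run)
    return best


def _revcomp(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in reversed(seq))


def dust_window_score(window: str) -> float:
    """DUST statistic for one window: sum over trinucleotide types of
    c(c−1)/2, divided by (k−1) where k is the number of trinucleotide
    positions in the window."""
    k = len(window) - 2
    if k < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(k):
        tri = window[i : i + 3]
        counts[tri] = counts.get(tri, 0) + 1
    score = sum(c * (c - 1) / 2 for c in counts.values())
    return score / (k - 1)


def low_complexity_pct(
    seq: str, window: int = 64, threshold: float = 2.0
) -> float:
    """Percentage of the sequence covered by low-complexity regions.

    A DUST-style detector: every sliding window of ``window`` bases (or the
    whole sequence when shorter) is scored by the trinucleotide statistic
    :func:`dust_window_score`; windows scoring above ``threshold`` are masked
    in full and the masked fraction is returned as a percentage.
    """
    if not seq:
        raise UndefinedFeatureError("low-complexity undefined for empty sequence")
    L = len(seq)
    w = min(window, L)
    if w < 5:
        return 0.0
    masked = [False] * L
    for start in range(0, L - w + 1):
        if dust_window_score(seq[start : start + w]) > threshold:
            for i in range(start, start + w):
                masked[i] = True
    return 100.0 * sum(masked) / L
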