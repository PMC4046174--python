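"""Shuffling-based features: z-scores and the folding-stability p-value.

The null model is the Altschul–Erikson dinucleotide-preserving shuffle: the
sequence is viewed as an Eulerian walk on the directed multigraph whose
edges are its dinucleotides, and a uniformly random alternative walk with
the same edge multiset (hence identical mono- and di-nucleotide counts and
the same first and last base) is drawn by the last-edge/arborescence method.

z-score features standardize a structure feature of the original sequence
against its distribution over shuffled copies; the randfold-style p-value is
the permutation-test estimate of how often a shuffle folds at least as
stably as the original, with the usual +1 correction so p is never 0.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .rna_structures import HairpinRecord, StructureBackend, decompose
from .struct_features import (
    FeatureBlock,
    ensemble_features,
    pairing_features,
    topological_dF,
)

__all__ = [
    "ShuffleConfig",
    "dinucleotide_shuffle",
    "is_forced_identity",
    "base_profile",
    "zscore_features",
    "randfold_p",
    "ZSCORE_BASES",
]

#: base features standardized into zG, zP, zQ, zD, zF
ZSCORE_BASES = ("dG", "dP", "dQ", "dD", "dF")


@dataclass(frozen=True)
class ShuffleConfig:
    """Shuffle-ensemble sizes and seeding.

    ``n_shuffles`` controls the z-score ensembles (needs >= 2 for a sample
    SD); ``n_shuffles_p`` the stability p-value (>= 1).  Each record draws
    its own RNG stream from ``seed`` and the record id, so results do not
    depend on extraction order.
    """

    n_shuffles: int = 100
    n_shuffles_p: int = 999
    seed: int = 0
    method: str = "dinucleotide"

    def __post_init__(self) -> None:
        if self.n_shuffles < 2:
            raise ValueError("n_shuffles must be >= 2 for z-scores")
        if self.n_shuffles_p < 1:
            raise ValueError("n_shuffles_p must be >= 1")
        if self.method != "dinucleotide":
            raise ValueError("only dinucleotide-preserving shuffling is supported")

    def record_rng(self, record_id: str) -> np.random.Generator:
        mix = zlib.crc32(record_id.encode()) & 0x7FFFFFFF
        return np.random.default_rng((self.seed, mix))


def is_forced_identity(seq: str) -> bool:
    """Cheap sufficient test that the dinucleotide graph admits only the
    input arrangement (every vertex has at most one distinct successor)."""
    if len(seq) < 3:
        return True
    succ: dict[str, set[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succ.setdefault(a, set()).add(b)
    return all(len(s) <= 1 for s in succ.values())


def dinucleotide_shuffle(seq: str, rng: np.random.Generator | int) -> str:
    """Dinucleotide-preserving (Altschul–Erikson) shuffle of ``seq``.

    Preserves all 16 dinucleotide counts exactly, along with the first and
    last nucleotide.  Sequences whose dinucleotide graph admits no
    alternative arrangement are returned unchanged.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if is_forced_identity(seq):
        return seq

    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    verts = list(edges.keys())

    # choose a random last-edge per vertex (except the terminal vertex) such
    # that following last-edges from every vertex reaches the terminal one
    non_terminal = [v for v in verts if v != last]
    while True:
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal
        }
        if all(_reaches(v, last, last_edge) for v in non_terminal):
            break

    arranged: dict[str, list[str]] = {}
    for v in verts:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        arranged[v] = rest

    out = [first]
    idx = dict.fromkeys(verts, 0)
    v = first
    for _ in range(len(seq) - 1):
        nxt = arranged[v][idx[v]]
        idx[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _reaches(v: str, target: str, last_edge: dict[str, str]) -> bool:
    seen = set()
    while v != target:
        if v in seen or v not in last_edge:
            return False
        seen.add(v)
        v = last_edge[v]
    return True


def base_profile(
    seq: str, backend: StructureBackend, record_id: str | None = None
) -> dict[str, float]:
    """The five shuffle-standardized base features for one sequence:
    dG (MFE/L), dP (pairs/L), dQ, dD (ensemble) and dF (topology)."""
    structure = backend.fold(seq, record_id)
    elements = decompose(seq, structure)
    ens = backend.ensemble(seq, record_id)
    L = len(seq)
    vals = {
        "dG": structure.mfe / L,
        "dP": pairing_features(seq, elements).values["dP"],
        "dF": topological_dF(elements),
    }
    ens_block = ensemble_features(structure, ens)
    vals["dQ"] = ens_block.values["dQ"]
    vals["dD"] = ens_block.values["dD"]
    return vals


def zscore_features(
    record: HairpinRecord,
    backend: StructureBackend,
    cfg: ShuffleConfig,
) -> FeatureBlock:
    """zG, zP, zQ, zD, zF: (original − shuffle mean) / shuffle sample SD.

    A zero shuffle SD flags the z-score degenerate with value 0.
    """
    rng = cfg.record_rng(record.id)
    original = base_profile(record.seq, backend, record.id)
    shuffled = []
    for _ in range(cfg.n_shuffles):
        s = dinucleotide_shuffle(record.seq, rng)
        shuffled.append(base_profile(s, backend))
    block = FeatureBlock()
    for base, zname in zip(ZSCORE_BASES, ("zG", "zP", "zQ", "zD", "zF")):
        vals = np.array([p[base] for p in shuffled])
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            block.set(zname, 0.0)
            block.degenerate.add(zname)
        else:
            block.set(zname, (original[base] - float(vals.mean())) / sd)
    return block


def randfold_p(
    record: HairpinRecord,
    backend: StructureBackend,
    cfg: ShuffleConfig,
) -> float:
    """Empirical folding-stability p-value.

    p = (1 + #{shuffles with MFE <= original MFE}) / (n + 1), in (0, 1].
    """
    rng = cfg.record_rng(record.id)
    mfe0 = backend.fold(record.seq, record.id).mfe
    hits = 0
    for _ in range(cfg.n_shuffles_p):
        s = dinucleotide_shuffle(record.seq, rng)
        if backend.fold(s).mfe <= mfe0:
            hits += 1
    return (1 + hits) / (cfg.n_shuffles_p + 1)
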