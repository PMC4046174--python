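"""Synthetic hairpins and pseudo-hairpins with designed structures.

The generator emulates the two classes of the pre-miRNA recognition task at
desk scale, with no downloads and no folding engine:

* positives are designed stem-loops (~60–120 nt): a long complementary stem
  (>= 15 pairs) with planted G·U wobbles and small bulges, a hairpin loop,
  and short unpaired tails;
* negatives are codon-structured pseudo-hairpins of matching length: random
  non-stop codons with one planted weak inverted repeat (5–10 pairs), i.e.
  sequences that fold back weakly but lack the long clean stem.

Every record carries a *designed* secondary structure and a designed-MFE
proxy (a weighted pair-count energy with noise), plus a consistent sidecar
of ensemble/thermodynamic values, so the whole feature pipeline runs
engine-free through :class:`~mirfeat.rna_structures.FixtureBackend`.  The
two length distributions coincide and the energy distributions overlap,
mimicking the deliberate length/MFE matching of the published negative set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .ml_eval import protocol_splits
from .rna_structures import (
    FixtureBackend,
    HairpinRecord,
    SecondaryStructure,
    parse_dotbracket,
    write_fasta,
    write_sidecar,
    write_vienna,
)

__all__ = [
    "GeneratorParams",
    "SyntheticRecord",
    "generate_hairpins",
    "generate_pseudohairpins",
    "generate_dataset",
    "designed_backend",
    "sequence_identity",
    "cluster_reduce",
    "assemble_protocol_sets",
    "write_dataset",
]

_KT37 = 0.6163  # kcal/mol at 37 °C, used to keep efe/freq_mfe consistent

#: designed-energy weights per pair class (kcal/mol, coarse)
_PAIR_ENERGY = {"GC": 3.0, "AU": 2.0, "GU": 1.0}

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGU" for b in "ACGU" for c in "ACGU"
    if a + b + c not in ("UAA", "UAG", "UGA")
)

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions of the synthetic data.

    Lengths span the pre-miRNA range (60–120 nt).  Positives plant stems of
    at least ``min_stem_pairs``; negatives plant inverted repeats drawn from
    ``neg_stem_range`` (strictly below the positive minimum).  ``gc_range``
    is the per-record G+C bias of stem arms.
    """

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (60, 120)
    loop_range: tuple[int, int] = (4, 8)
    tail_range: tuple[int, int] = (2, 6)
    max_bulges: int = 2
    wobble_prob: float = 0.1
    min_stem_pairs: int = 15
    neg_stem_range: tuple[int, int] = (5, 10)
    gc_range: tuple[float, float] = (0.4, 0.65)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        worst = (
            lo
            - self.loop_range[1]
            - 2 * self.tail_range[1]
            - 2 * self.max_bulges
        )
        if worst // 2 < self.min_stem_pairs:
            raise ValueError(
                "infeasible params: shortest sequence cannot hold "
                f"{self.min_stem_pairs} stem pairs"
            )
        if self.neg_stem_range[1] >= self.min_stem_pairs:
            raise ValueError(
                "negative stems must stay below the positive minimum"
            )


@dataclass(frozen=True)
class SyntheticRecord:
    """A generated sequence with its designed structure, sidecar profile
    row and class label (+1 hairpin, −1 pseudo-hairpin)."""

    record: HairpinRecord
    structure: SecondaryStructure
    sidecar: dict[str, float]
    label: int


def _sample_base(rng: np.random.Generator, p_gc: float) -> str:
    if rng.random() < p_gc:
        return "G" if rng.random() < 0.5 else "C"
    return "A" if rng.random() < 0.5 else "U"


def _designed_energy(
    seq: str, pairs: Sequence[tuple[int, int]], loop: int, n_bulges: int,
    rng: np.random.Generator,
) -> float:
    e = 0.0
    for i, j in pairs:
        cls = "".join(sorted((seq[i - 1], seq[j - 1])))
        cls = {"CG": "GC", "AU": "AU", "GU": "GU"}[cls]
        e -= _PAIR_ENERGY[cls]
    e += 0.3 * loop + 1.5 * n_bulges + rng.normal(0.0, 2.0)
    return min(e, -1.0)


def _sidecar_row(
    mfe: float, rng: np.random.Generator, positive: bool
) -> dict[str, float]:
    # freq/efe tied through freq = exp((efe - mfe)/kT); dH from the
    # identity mfe = dH - T*dS/1000 at T = 310.15 K
    freq = rng.uniform(0.4, 0.9) if positive else rng.uniform(0.02, 0.4)
    efe = mfe + _KT37 * float(np.log(freq))
    diversity = rng.uniform(0.5, 3.0) if positive else rng.uniform(3.0, 12.0)
    dS = rng.uniform(-260.0, -120.0)
    dH = mfe + 310.15 * dS / 1000.0
    tm = 1000.0 * dH / dS
    return {
        "efe": efe,
        "freq_mfe": freq,
        "diversity": diversity,
        "dH": dH,
        "dS": dS,
        "tm": tm,
    }


def _build_hairpin(
    rng: np.random.Generator, params: GeneratorParams
) -> tuple[str, str, int, int]:
    """One designed stem-loop; returns (seq, db, loop_len, n_bulges)."""
    L = int(rng.integers(params.length_range[0], params.length_range[1] + 1))
    loop = int(rng.integers(params.loop_range[0], params.loop_range[1] + 1))
    t5 = int(rng.integers(params.tail_range[0], params.tail_range[1] + 1))
    t3 = int(rng.integers(params.tail_range[0], params.tail_range[1] + 1))
    n_bulges = int(rng.integers(0, params.max_bulges + 1))
    bulge_sizes = [int(rng.integers(1, 3)) for _ in range(n_bulges)]
    budget = L - loop - t5 - t3 - sum(bulge_sizes)
    n_bp = budget // 2
    if n_bp < params.min_stem_pairs:  # shrink tails to recover pairs
        deficit = 2 * (params.min_stem_pairs - n_bp)
        t3 = max(params.tail_range[0], t3 - deficit)
        n_bp = (L - loop - t5 - t3 - sum(bulge_sizes)) // 2
    # the 3' tail absorbs the remainder so the total length is exactly L
    t3 = L - t5 - loop - 2 * n_bp - sum(bulge_sizes)
    p_gc = rng.uniform(*params.gc_range)

    arm5 = [_sample_base(rng, p_gc) for _ in range(n_bp)]
    arm3 = []
    for b in arm5:
        partner = _COMP[b]
        if b in "GU" and rng.random() < params.wobble_prob:
            partner = "U" if b == "G" else "G"
        arm3.append(partner)

    gaps = (
        rng.choice(np.arange(1, n_bp), size=n_bulges, replace=False)
        if n_bulges
        else []
    )
    bulges = {
        int(g): (("5" if rng.random() < 0.5 else "3"), s)
        for g, s in zip(gaps, bulge_sizes)
    }

    seq5, db5, seq3r, db3r = [], [], [], []
    for i in range(n_bp):
        seq5.append(arm5[i])
        db5.append("(")
        seq3r.append(arm3[i])
        db3r.append(")")
        if i + 1 in bulges:
            side, size = bulges[i + 1]
            filler = [_sample_base(rng, 0.3) for _ in range(size)]
            if side == "5":
                seq5.extend(filler)
                db5.extend("." * size)
            else:
                seq3r.extend(filler)
                db3r.extend("." * size)
    tail5 = [_sample_base(rng, 0.3) for _ in range(t5)]
    tail3 = [_sample_base(rng, 0.3) for _ in range(t3)]
    loop_seq = [_sample_base(rng, 0.3) for _ in range(loop)]
    seq = (
        "".join(tail5) + "".join(seq5) + "".join(loop_seq)
        + "".join(reversed(seq3r)) + "".join(tail3)
    )
    db = (
        "." * t5 + "".join(db5) + "." * loop
        + "".join(reversed(db3r)) + "." * t3
    )
    return seq, db, loop, n_bulges


def generate_hairpins(params: GeneratorParams) -> list[SyntheticRecord]:
    """Designed stem-loop positives (label +1), bit-reproducible per seed."""
    rng = np.random.default_rng((params.seed, 1))
    out = []
    for k in range(params.n_pos):
        seq, db, loop, n_bulges = _build_hairpin(rng, params)
        pairs_tbl = parse_dotbracket(db)
        pairs = [
            (i, pairs_tbl[i])
            for i in range(1, len(db) + 1)
            if pairs_tbl[i] > i
        ]
        mfe = _designed_energy(seq, pairs, loop, n_bulges, rng)
        struct = SecondaryStructure.from_db(db, mfe=round(mfe, 2))
        rec = HairpinRecord(id=f"pos{k:05d}", seq=seq)
        out.append(
            SyntheticRecord(
                record=rec,
                structure=struct,
                sidecar=_sidecar_row(struct.mfe, rng, positive=True),
                label=1,
            )
        )
    return out


def generate_pseudohairpins(params: GeneratorParams) -> list[SyntheticRecord]:
    """Codon-structured pseudo-hairpin negatives (label −1)."""
    rng = np.random.default_rng((params.seed, 2))
    out = []
    for k in range(params.n_neg):
        L = int(
            rng.integers(params.length_range[0], params.length_range[1] + 1)
        )
        n_codons = L // 3
        seq = list(
            "".join(
                _NON_STOP_CODONS[int(rng.integers(len(_NON_STOP_CODONS)))]
                for _ in range(n_codons)
            )
        )
        seq.extend(_sample_base(rng, 0.5) for _ in range(L - 3 * n_codons))

        s = int(
            rng.integers(params.neg_stem_range[0], params.neg_stem_range[1] + 1)
        )
        gap = int(rng.integers(3, 10))
        start1 = int(rng.integers(0, L - (2 * s + gap)))
        start2 = start1 + s + gap
        for i in range(s):
            b = seq[start1 + i]
            partner = _COMP[b]
            if b in "GU" and rng.random() < params.wobble_prob:
                partner = "U" if b == "G" else "G"
            seq[start2 + (s - 1 - i)] = partner
        db = ["."] * L
        pairs = []
        for i in range(s):
            a = start1 + i + 1
            b2 = start2 + (s - 1 - i) + 1
            db[a - 1] = "("
            db[b2 - 1] = ")"
            pairs.append((a, b2))
        mfe = _designed_energy("".join(seq), pairs, gap, 0, rng) + rng.normal(
            0.0, 3.0
        )
        struct = SecondaryStructure.from_db("".join(db), mfe=round(min(mfe, -0.5), 2))
        rec = HairpinRecord(id=f"neg{k:05d}", seq="".join(seq))
        out.append(
            SyntheticRecord(
                record=rec,
                structure=struct,
                sidecar=_sidecar_row(struct.mfe, rng, positive=False),
                label=-1,
            )
        )
    return out


def generate_dataset(
    params: GeneratorParams,
) -> tuple[list[SyntheticRecord], list[SyntheticRecord]]:
    return generate_hairpins(params), generate_pseudohairpins(params)


def designed_backend(synrecs: Sequence[SyntheticRecord]) -> FixtureBackend:
    """A fixture backend pre-loaded with the designed structures/profiles."""
    fb = FixtureBackend()
    for sr in synrecs:
        fb.add_structure(sr.record.id, sr.record.seq, sr.structure)
        fb.add_profile(sr.record.id, **sr.sidecar)
    return fb


# ---------------------------------------------------------------------------
# Redundancy reduction


def sequence_identity(a: str, b: str, k: int = 8) -> float:
    """Fraction of identical positions under the best ungapped offset.

    Candidate offsets are seeded by shared k-mers; with no shared k-mer the
    identity is 0.  The denominator is the shorter sequence length.
    """
    if len(a) < k or len(b) < k:
        return 0.0
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i : i + k], []).append(i)
    offsets = set()
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            offsets.add(i - j)
    best = 0
    for off in offsets:
        lo = max(0, off)
        hi = min(len(a), len(b) + off)
        matches = sum(
            1 for i in range(lo, hi) if a[i] == b[i - off]
        )
        best = max(best, matches)
    return best / min(len(a), len(b))


def cluster_reduce(
    records: Sequence[HairpinRecord],
    similarity: float = 0.8,
    seed: int = 0,
) -> list[HairpinRecord]:
    """Greedy centroid clustering at the given identity threshold; one
    randomly picked representative per cluster.

    Records are considered longest-first; a record joins the first centroid
    with :func:`sequence_identity` >= threshold, else founds a new cluster.
    """
    if not records:
        raise ValueError("no records to cluster")
    order = sorted(records, key=lambda r: (-r.L, r.id))
    centroids: list[HairpinRecord] = []
    clusters: list[list[HairpinRecord]] = []
    for rec in order:
        for ci, cent in enumerate(centroids):
            if sequence_identity(cent.seq, rec.seq) >= similarity:
                clusters[ci].append(rec)
                break
        else:
            centroids.append(rec)
            clusters.append([rec])
    rng = np.random.default_rng(seed)
    return [cl[int(rng.integers(len(cl)))] for cl in clusters]


def assemble_protocol_sets(
    pos: Sequence[HairpinRecord],
    neg: Sequence[HairpinRecord],
    seed: int = 0,
    reps: int = 10,
    increment: int = 67,
):
    """Record-level GEN/training splits of the repeated-holdout protocol.

    Yields per repetition a dict with record lists ``gen_pos``, ``gen_neg``,
    ``train_pos``, ``train_neg``; the train lists are the full remainders in
    sampling order (use the first 67·k of each for k increments).
    """
    pos = list(pos)
    neg = list(neg)
    for gp, gn, tp, tn in protocol_splits(
        len(pos), len(neg), seed=seed, reps=reps, increment=increment
    ):
        yield {
            "gen_pos": [pos[i] for i in gp],
            "gen_neg": [neg[i] for i in gn],
            "train_pos": [pos[i] for i in tp],
            "train_neg": [neg[i] for i in tn],
        }


def write_dataset(
    out_prefix: str | Path,
    pos: Sequence[SyntheticRecord],
    neg: Sequence[SyntheticRecord],
) -> dict[str, Path]:
    """Write FASTA + Vienna structures + sidecar TSV + labels TSV."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    allrecs = list(pos) + list(neg)
    paths = {
        "fasta": prefix.with_suffix(".fasta"),
        "vienna": prefix.with_suffix(".vienna"),
        "sidecar": prefix.with_suffix(".sidecar.tsv"),
        "labels": prefix.with_suffix(".labels.tsv"),
    }
    write_fasta([sr.record for sr in allrecs], paths["fasta"])
    write_vienna(
        [(sr.record.id, sr.record.seq, sr.structure) for sr in allrecs],
        paths["vienna"],
    )
    write_sidecar({sr.record.id: sr.sidecar for sr in allrecs}, paths["sidecar"])
    with open(paths["labels"], "w") as fh:
        fh.write("id\tlabel\n")
        for sr in allrecs:
            fh.write(f"{sr.record.id}\t{sr.label}\n")
    return paths
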