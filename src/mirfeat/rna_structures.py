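"""Sequence/structure data model, dot-bracket parsing and folding backends.

Coordinates are 1-based throughout, matching the pair-table convention of
Vienna-format files: a pair table is a tuple of length ``L + 1`` whose slot 0
is unused and whose slot ``i`` holds the partner of base ``i`` (0 when
unpaired).

Folding, partition-function and thermodynamic quantities are obtained from a
pluggable backend.  Any object satisfying :class:`StructureBackend` may be
used; the package ships

* :class:`FixtureBackend` — replays precomputed Vienna dot-bracket files and a
  tabular sidecar, so every downstream stage runs with no folding engine;
* :class:`ViennaRNABackend` — live RNAfold-equivalent folding through the
  ViennaRNA Python bindings, when they are importable;
* :class:`CountingBackend` — a transparent wrapper that counts calls, used to
  verify which feature sets touch which backend capabilities.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "HairpinRecord",
    "SecondaryStructure",
    "StructureElements",
    "EnsembleProfile",
    "ThermoProfile",
    "DotBracketError",
    "NonCanonicalPairError",
    "NoStructureSourceError",
    "normalize_sequence",
    "parse_dotbracket",
    "render_dotbracket",
    "validate_min_loop",
    "decompose",
    "StructureBackend",
    "FixtureBackend",
    "ViennaRNABackend",
    "CountingBackend",
    "read_fasta",
    "write_fasta",
    "read_vienna",
    "write_vienna",
    "read_sidecar",
    "write_sidecar",
]

RNA_ALPHABET = frozenset("ACGU")
#: Canonical pair classes; Watson–Crick plus the G·U wobble.
_PAIR_CLASS = {
    frozenset("AU"): "AU",
    frozenset("GC"): "GC",
    frozenset("GU"): "GU",
}

EXTERIOR = 0  # vertex id of the exterior region in the structure tree


class DotBracketError(ValueError):
    """Malformed dot-bracket string (unbalanced or illegal characters)."""


class NonCanonicalPairError(ValueError):
    """A paired position does not form an A-U, G-C or G-U pair."""


class NoStructureSourceError(RuntimeError):
    """No backend can supply the requested structure/ensemble/thermo profile."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, map T to U and reject ambiguity codes."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"sequence contains non-ACGU symbols after normalization: {sorted(bad)}"
        )
    return s


@dataclass(frozen=True)
class HairpinRecord:
    """A single RNA sequence with identifier, normalized to the ACGU alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_sequence(self.seq))
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")

    @property
    def L(self) -> int:
        return len(self.seq)


def parse_dotbracket(db: str) -> tuple[int, ...]:
    """Parse a dot-bracket string into a 1-based pair table.

    Returns a tuple of length ``len(db) + 1``; slot 0 is unused, slot *i*
    holds the 1-based partner of position *i* (0 when unpaired).
    """
    n = len(db)
    pairs = [0] * (n + 1)
    stack: list[int] = []
    for i, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unmatched ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise DotBracketError(f"illegal character {ch!r} at position {i}")
    if stack:
        raise DotBracketError(f"unmatched '(' at position {stack[0]}")
    return tuple(pairs)


def render_dotbracket(pairs: Sequence[int]) -> str:
    """Inverse of :func:`parse_dotbracket` for pseudoknot-free pair tables."""
    n = len(pairs) - 1
    out = []
    for i in range(1, n + 1):
        j = pairs[i]
        if j == 0:
            out.append(".")
        elif j > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def validate_min_loop(pairs: Sequence[int], min_loop: int = 3) -> None:
    """Reject structures whose hairpin loops span fewer than ``min_loop`` bases."""
    for i in range(1, len(pairs)):
        j = pairs[i]
        if j > i and j - i - 1 < min_loop and all(
            pairs[k] == 0 for k in range(i + 1, j)
        ):
            raise ValueError(
                f"hairpin loop closed by pair ({i},{j}) has fewer than "
                f"{min_loop} unpaired bases"
            )


@dataclass(frozen=True)
class SecondaryStructure:
    """A secondary structure: dot-bracket string, pair table and MFE (kcal/mol)."""

    db: str
    pairs: tuple[int, ...]
    mfe: float

    @classmethod
    def from_db(cls, db: str, mfe: float = 0.0) -> "SecondaryStructure":
        return cls(db=db, pairs=parse_dotbracket(db), mfe=mfe)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.db) + 1:
            raise ValueError("pair table length inconsistent with dot-bracket")

    @property
    def L(self) -> int:
        return len(self.db)

    def pair_set(self) -> frozenset[tuple[int, int]]:
        """The set of pairs (i, j) with i < j."""
        return frozenset(
            (i, self.pairs[i])
            for i in range(1, self.L + 1)
            if self.pairs[i] > i
        )


@dataclass(frozen=True)
class StructureElements:
    """Decomposition of a structure into stems and loops.

    ``loops`` holds ``(kind, unpaired_count)`` entries with kind in
    {hairpin, bulge, internal, multi, exterior}; ``tree_edges`` are the edges
    of the tree-graph representation (vertex 0 = exterior region, vertices
    1..n_loops = non-exterior loops in 5'→3' order of their closing pairs,
    one edge per stem).
    """

    stems: tuple[tuple[tuple[int, int], ...], ...]
    loops: tuple[tuple[str, int], ...]
    bp_total: int
    bp_AU: int
    bp_GC: int
    bp_GU: int
    internal_loop_total: int
    tree_edges: tuple[tuple[int, int], ...]

    @property
    def n_stems(self) -> int:
        return len(self.stems)

    @property
    def n_loops(self) -> int:
        return sum(1 for kind, _ in self.loops if kind != "exterior")

    @property
    def n_tree_vertices(self) -> int:
        return self.n_loops + 1


def _classify_pair(seq: str, i: int, j: int) -> str:
    cls = _PAIR_CLASS.get(frozenset((seq[i - 1], seq[j - 1])))
    if cls is None:
        raise NonCanonicalPairError(
            f"non-canonical pair {seq[i - 1]}-{seq[j - 1]} at ({i},{j})"
        )
    return cls


def decompose(seq: str, structure: SecondaryStructure) -> StructureElements:
    """Decompose a structure into maximal stems, loop taxonomy and pair counts.

    A stem is a maximal run of stacked pairs with no intervening unpaired
    base (minimum one pair).  A region closed by a pair is classified as
    hairpin (no inner helix), bulge (one inner helix, unpaired bases on
    exactly one side), internal (one inner helix, both sides), or multi
    (two or more inner helices); regions with one inner helix and no
    unpaired base are stacking steps inside a stem, not loops.
    ``internal_loop_total`` accumulates the unpaired bases of internal and
    bulge loops.
    """
    if len(seq) != structure.L:
        raise ValueError("sequence and structure lengths differ")
    pairs = structure.pairs
    L = structure.L

    bp = {"AU": 0, "GC": 0, "GU": 0}
    for i in range(1, L + 1):
        j = pairs[i]
        if j > i:
            bp[_classify_pair(seq, i, j)] += 1
    bp_total = bp["AU"] + bp["GC"] + bp["GU"]

    # Maximal stems: start at a pair (i,j) not stacked on an enclosing pair.
    stems: list[tuple[tuple[int, int], ...]] = []
    stem_of_inner: dict[tuple[int, int], int] = {}
    stem_outer: list[tuple[int, int]] = []
    for i in range(1, L + 1):
        j = pairs[i]
        if j <= i:
            continue
        if i > 1 and pairs[i - 1] == j + 1:
            continue  # stacked on the previous pair: same stem
        run = [(i, j)]
        while pairs[run[-1][0] + 1] == run[-1][1] - 1:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        stems.append(tuple(run))
        stem_of_inner[run[-1]] = len(stems) - 1
        stem_outer.append(run[0])

    # Regions closed by the innermost pair of each stem are loops; classify
    # by walking the interior of each closing pair.
    loops: list[tuple[str, int]] = []
    loop_id_by_pair: dict[tuple[int, int], int] = {}
    internal_loop_total = 0
    closing = sorted(stem_of_inner)  # 5'→3' order of closing pairs
    for (i, j) in closing:
        k = i + 1
        unpaired = 0
        left = 0
        children: list[tuple[int, int]] = []
        while k < j:
            if pairs[k] == 0:
                unpaired += 1
                if not children:
                    left += 1
                k += 1
            else:
                children.append((k, pairs[k]))
                k = pairs[k] + 1
        right = unpaired - left if children else 0
        if not children:
            kind = "hairpin"
        elif len(children) == 1:
            if unpaired == 0:
                raise AssertionError("stacking region reported as closing pair")
            kind = "internal" if (left > 0 and right > 0) else "bulge"
        else:
            kind = "multi"
        if kind in ("internal", "bulge"):
            internal_loop_total += unpaired
        loop_id_by_pair[(i, j)] = len(loops) + 1  # vertex ids start at 1
        loops.append((kind, unpaired))

    # Exterior region: unpaired top-level bases.
    ext_unpaired = 0
    k = 1
    while k <= L:
        if pairs[k] == 0:
            ext_unpaired += 1
            k += 1
        else:
            k = pairs[k] + 1
    loop_entries = tuple(loops) + (("exterior", ext_unpaired),)

    # Tree edges: one per stem, from the region containing its outer pair to
    # the loop closed by its inner pair.
    enclosing = _enclosing_pairs(pairs)
    edges: list[tuple[int, int]] = []
    for s_idx, outer in enumerate(stem_outer):
        inner = stems[s_idx][-1]
        below = loop_id_by_pair[inner]
        enc = enclosing[outer[0]]
        above = EXTERIOR if enc is None else loop_id_by_pair[enc]
        edges.append((above, below))

    return StructureElements(
        stems=tuple(stems),
        loops=loop_entries,
        bp_total=bp_total,
        bp_AU=bp["AU"],
        bp_GC=bp["GC"],
        bp_GU=bp["GU"],
        internal_loop_total=internal_loop_total,
        tree_edges=tuple(edges),
    )


def _enclosing_pairs(
    pairs: Sequence[int],
) -> dict[int, tuple[int, int] | None]:
    """For each pair-opening position, the innermost *loop-closing* pair
    strictly enclosing it (None when at top level).

    A pair (p, q) immediately stacked on (p+1, q-1) is not loop-closing for
    its inner neighbour; the innermost loop-closing enclosure is found by
    skipping through stacked runs.
    """
    out: dict[int, tuple[int, int] | None] = {}
    stack: list[tuple[int, int]] = []
    n = len(pairs) - 1
    for i in range(1, n + 1):
        j = pairs[i]
        if j > i:
            # walk outward through any directly stacked run: the enclosing
            # loop-closing pair is the nearest stack entry that does not
            # stack onto the run containing (i, j)
            enc: tuple[int, int] | None = None
            cur = (i, j)
            for (p, q) in reversed(stack):
                if p == cur[0] - 1 and q == cur[1] + 1:
                    cur = (p, q)
                else:
                    enc = (p, q)
                    break
            out[i] = enc
            stack.append((i, j))
        elif 0 < j < i:
            stack.pop()
    return out


@dataclass(frozen=True)
class EnsembleProfile:
    """Partition-function quantities for one sequence.

    bpp maps 1-based pairs (i, j), i < j, to base-pair probabilities.
    """

    efe: float
    freq_mfe: float
    bpp: dict[tuple[int, int], float] = field(default_factory=dict)
    diversity: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.freq_mfe <= 1.0 + 1e-9):
            raise ValueError(f"freq_mfe {self.freq_mfe} outside [0,1]")
        if self.diversity < 0:
            raise ValueError("diversity must be non-negative")
        for (i, j), p in self.bpp.items():
            if not (i < j and -1e-9 <= p <= 1 + 1e-9):
                raise ValueError(f"invalid bpp entry ({i},{j}) -> {p}")


@dataclass(frozen=True)
class ThermoProfile:
    """Structure enthalpy dH (kcal/mol), entropy dS (cal/(mol·K)) and melting
    energy/temperature tm (None when the backend does not provide it)."""

    dH: float
    dS: float
    tm: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dH) and math.isfinite(self.dS)):
            raise ValueError("dH and dS must be finite")


# ---------------------------------------------------------------------------
# Backends


class StructureBackend:
    """Contract for structure/ensemble/thermo providers.

    Implementations may raise :class:`NoStructureSourceError` for sequences
    they cannot serve; they must never return silent placeholder zeros.
    """

    #: capabilities this backend provides, subset of {fold, ensemble, thermo}
    capabilities: frozenset[str] = frozenset()

    def fold(self, seq: str, record_id: str | None = None) -> SecondaryStructure:
        raise NoStructureSourceError("backend does not fold")

    def ensemble(self, seq: str, record_id: str | None = None) -> EnsembleProfile:
        raise NoStructureSourceError("backend does not provide ensembles")

    def thermo(self, seq: str, record_id: str | None = None) -> ThermoProfile:
        raise NoStructureSourceError("backend does not provide thermodynamics")


class FixtureBackend(StructureBackend):
    """Replays precomputed structures and profiles from files.

    Structures come from a Vienna dot-bracket file; ensemble and thermo
    profiles from a TSV sidecar with columns
    ``id  efe  freq_mfe  diversity  dH  dS  tm``.  Base-pair probabilities
    are reconstructed by assigning ``freq_mfe`` to every pair of the stored
    MFE structure (a sharp-ensemble approximation adequate for fixtures).
    Lookups are by record id, with a fallback on the exact sequence.
    """

    capabilities = frozenset({"fold", "ensemble", "thermo"})

    def __init__(
        self,
        vienna_path: str | Path | None = None,
        sidecar_path: str | Path | None = None,
    ) -> None:
        self._structures: dict[str, tuple[str, SecondaryStructure]] = {}
        self._by_seq: dict[str, SecondaryStructure] = {}
        self._sidecar: dict[str, dict[str, float]] = {}
        if vienna_path is not None:
            for rid, seq, struct in read_vienna(vienna_path):
                self.add_structure(rid, seq, struct)
        if sidecar_path is not None:
            for rid, row in read_sidecar(sidecar_path).items():
                self._sidecar[rid] = row

    def add_structure(
        self, record_id: str, seq: str, struct: SecondaryStructure
    ) -> None:
        self._structures[record_id] = (normalize_sequence(seq), struct)
        self._by_seq[normalize_sequence(seq)] = struct

    def add_profile(self, record_id: str, **row: float) -> None:
        self._sidecar[record_id] = dict(row)

    def _lookup_structure(
        self, seq: str, record_id: str | None
    ) -> SecondaryStructure:
        if record_id is not None and record_id in self._structures:
            return self._structures[record_id][1]
        if seq in self._by_seq:
            return self._by_seq[seq]
        raise NoStructureSourceError(
            f"no fixture structure for record {record_id!r}"
        )

    def fold(self, seq: str, record_id: str | None = None) -> SecondaryStructure:
        return self._lookup_structure(seq, record_id)

    def ensemble(self, seq: str, record_id: str | None = None) -> EnsembleProfile:
        struct = self._lookup_structure(seq, record_id)
        if record_id is None or record_id not in self._sidecar:
            raise NoStructureSourceError(
                f"no fixture ensemble profile for record {record_id!r}"
            )
        row = self._sidecar[record_id]
        freq = float(row["freq_mfe"])
        bpp = {pair: freq for pair in sorted(struct.pair_set())}
        return EnsembleProfile(
            efe=float(row["efe"]),
            freq_mfe=freq,
            bpp=bpp,
            diversity=float(row["diversity"]),
        )

    def thermo(self, seq: str, record_id: str | None = None) -> ThermoProfile:
        if record_id is None or record_id not in self._sidecar:
            raise NoStructureSourceError(
                f"no fixture thermo profile for record {record_id!r}"
            )
        row = self._sidecar[record_id]
        tm = row.get("tm")
        tm_val = None if tm is None or not math.isfinite(float(tm)) else float(tm)
        return ThermoProfile(dH=float(row["dH"]), dS=float(row["dS"]), tm=tm_val)


class ViennaRNABackend(StructureBackend):
    """Live folding through the ViennaRNA Python bindings.

    Thermodynamic quantities are derived from the temperature dependence of
    the MFE: folding at two temperatures T1 < T2 gives
    dS = −(ΔG(T2) − ΔG(T1)) / (T2 − T1) and dH = ΔG(T1) + T1·dS, with the
    melting temperature tm = dH / dS (in K) when dS < 0.
    """

    capabilities = frozenset({"fold", "ensemble", "thermo"})

    GAS_CONSTANT = 0.00198717  # kcal/(mol·K)

    def __init__(self, temperature: float = 37.0, thermo_delta: float = 20.0):
        try:
            import RNA  # type: ignore
        except ImportError as exc:  # pragma: no cover - env without bindings
            raise NoStructureSourceError(
                "ViennaRNA Python bindings are not importable"
            ) from exc
        self._RNA = RNA
        self.temperature = temperature
        self.thermo_delta = thermo_delta

    def _mfe_at(self, seq: str, temperature: float) -> tuple[str, float]:
        md = self._RNA.md()
        md.temperature = temperature
        fc = self._RNA.fold_compound(seq, md)
        return fc.mfe()

    def fold(self, seq: str, record_id: str | None = None) -> SecondaryStructure:
        db, mfe = self._mfe_at(seq, self.temperature)
        return SecondaryStructure.from_db(db, mfe=float(mfe))

    def ensemble(self, seq: str, record_id: str | None = None) -> EnsembleProfile:
        RNA = self._RNA
        md = RNA.md()
        md.temperature = self.temperature
        fc = RNA.fold_compound(seq, md)
        db, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        _, efe = fc.pf()
        kT = self.GAS_CONSTANT * (273.15 + self.temperature)
        freq = min(1.0, math.exp((efe - mfe) / kT))
        raw = fc.bpp()
        bpp: dict[tuple[int, int], float] = {}
        n = len(seq)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                p = raw[i][j]
                if p > 1e-8:
                    bpp[(i, j)] = min(1.0, float(p))
        diversity = float(fc.mean_bp_distance())
        return EnsembleProfile(efe=float(efe), freq_mfe=freq, bpp=bpp,
                               diversity=diversity)

    def thermo(self, seq: str, record_id: str | None = None) -> ThermoProfile:
        t1 = self.temperature
        t2 = self.temperature + self.thermo_delta
        _, g1 = self._mfe_at(seq, t1)
        _, g2 = self._mfe_at(seq, t2)
        dS = -1000.0 * (g2 - g1) / (t2 - t1)  # cal/(mol·K)
        dH = g1 + (273.15 + t1) * dS / 1000.0
        tm = 1000.0 * dH / dS if abs(dS) > 1e-9 else None
        return ThermoProfile(dH=float(dH), dS=float(dS), tm=tm)


class CountingBackend(StructureBackend):
    """Wraps a backend and counts fold/ensemble/thermo calls."""

    def __init__(self, inner: StructureBackend) -> None:
        self.inner = inner
        self.capabilities = inner.capabilities
        self.n_fold = 0
        self.n_ensemble = 0
        self.n_thermo = 0

    def fold(self, seq: str, record_id: str | None = None) -> SecondaryStructure:
        self.n_fold += 1
        return self.inner.fold(seq, record_id)

    def ensemble(self, seq: str, record_id: str | None = None) -> EnsembleProfile:
        self.n_ensemble += 1
        return self.inner.ensemble(seq, record_id)

    def thermo(self, seq: str, record_id: str | None = None) -> ThermoProfile:
        self.n_thermo += 1
        return self.inner.thermo(seq, record_id)


# ---------------------------------------------------------------------------
# File I/O


def read_fasta(path: str | Path) -> list[HairpinRecord]:
    from Bio import SeqIO

    return [
        HairpinRecord(id=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[HairpinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


_ENERGY_RE = re.compile(r"^([().]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def read_vienna(
    path: str | Path,
) -> Iterator[tuple[str, str, SecondaryStructure]]:
    """Read Vienna dot-bracket records: header, sequence line, structure line
    with a trailing energy in parentheses."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"expected FASTA-style header, got {header!r}")
        rid = header[1:].split()[0]
        seq = normalize_sequence(lines[i + 1])
        m = _ENERGY_RE.match(lines[i + 2].strip())
        if not m:
            raise ValueError(f"malformed structure line for record {rid!r}")
        db, mfe = m.group(1), float(m.group(2))
        if len(db) != len(seq):
            raise ValueError(f"structure/sequence length mismatch for {rid!r}")
        yield rid, seq, SecondaryStructure.from_db(db, mfe=mfe)
        i += 3


def write_vienna(
    entries: Iterable[tuple[str, str, SecondaryStructure]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for rid, seq, struct in entries:
            fh.write(f">{rid}\n{seq}\n{struct.db} ({struct.mfe:.2f})\n")


SIDECAR_COLUMNS = ("id", "efe", "freq_mfe", "diversity", "dH", "dS", "tm")


def read_sidecar(path: str | Path) -> dict[str, dict[str, float]]:
    """Read the ensemble/thermo sidecar TSV into {id: row} mappings."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SIDECAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sidecar missing columns: {sorted(missing)}")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out[str(row["id"])] = {
            c: float(row[c]) for c in SIDECAR_COLUMNS if c != "id"
        }
    return out


def write_sidecar(rows: dict[str, dict[str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SIDECAR_COLUMNS) + "\n")
        for rid, row in rows.items():
            vals = [rid] + [
                f"{row.get(c, float('nan')):.6g}" if row.get(c) is not None else "nan"
                for c in SIDECAR_COLUMNS
                if c != "id"
            ]
            fh.write("\t".join(vals) + "\n")
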