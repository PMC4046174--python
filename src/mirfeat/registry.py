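"""Feature-set registries (FS1–FS7, SELECT, ALL85) and the extraction driver.

The registry is the authoritative, ordered definition of which features each
published set contains:

* FS1 — 48 miscellaneous sequence/structure/ensemble/thermo/z-score features
  (microPred's full catalog);
* FS2 — the 21-feature subset of FS1 used to train microPred;
* FS3 — the 7 features used by the G2DE-based classifier;
* FS4 — the 32 sequence-structure triplet frequencies (triplet-SVM);
* FS5 — sequence-structure motif counts (mirident; 1,300 by default);
* FS6 — FS4 plus MFE and the folding-stability p-value (MiPred, 34);
* FS7 — FS2 plus the four stacking triplets and three additional sequence/
  structure features (HuntMi, 28);
* SELECT — the 13 features retained by F-score/importance selection, in
  order of relevance;
* ALL85 — the union of FS1, FS6 and the three FS7 extras (85 features).

:func:`extract` drives per-record computation lazily, so a set never touches
a backend capability it does not declare (in particular, sets without
shuffle-based features never fold shuffled sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import seq_features as sf
from . import struct_features as stf
from .pattern_features import (
    MotifVocabulary,
    TRIPLET_NAMES,
    default_vocabulary,
    motif_counts,
    ss_string,
    stacking_triplets,
    triplet_profile,
)
from .rna_structures import (
    HairpinRecord,
    NoStructureSourceError,
    StructureBackend,
    decompose,
)
from .shuffle_stats import ShuffleConfig, randfold_p, zscore_features
from .struct_features import FeatureBlock

__all__ = [
    "FeatureSetDefinition",
    "FeatureMatrix",
    "FEATURE_SET_IDS",
    "get_feature_set",
    "extract",
    "PAPER_NAMES",
]

_DINUC_NAMES = tuple(f"dinuc_{d}" for d in sf.DINUCLEOTIDES)

_FS1 = _DINUC_NAMES + (
    "gc_content",
    "dG", "MFEI1", "MFEI2", "MFEI3", "MFEI4", "NEFE", "Diff", "Freq",
    "dP", "dQ", "Diversity", "dD",
    "Avg_Bp_Stem",
    "AU_L", "GC_L", "GU_L", "AU_stems", "GC_stems", "GU_stems",
    "dS", "dS_L", "dH", "dH_L", "Tm", "Tm_L",
    "dF",
    "zG", "zP", "zQ", "zD", "zF",
)

_FS2 = (
    "gc_content",
    "dG", "MFEI1", "MFEI2", "MFEI3", "MFEI4", "NEFE", "Diff",
    "dQ", "Diversity",
    "Avg_Bp_Stem",
    "AU_L", "GC_L", "GU_L", "AU_stems", "GC_stems", "GU_stems",
    "dS", "dS_L",
    "dF",
    "zD",
)

_FS3 = ("dG", "MFEI1", "MFEI2", "dP", "dQ", "dD", "dF")

_FS4 = TRIPLET_NAMES

_STACK = ("stack_A", "stack_C", "stack_G", "stack_U")
_FS7_EXTRAS = ("low_complexity_pct", "max_aa_run", "internal_loops_cum")

_FS6 = TRIPLET_NAMES + ("MFE", "randfold_p")
_FS7 = _FS2 + _STACK + _FS7_EXTRAS

#: the features retained by selection, in order of relevance
_SELECT = (
    "MFEI1", "MFEI2", "dG", "dQ", "dF", "NEFE", "Diff",
    "dS", "dS_L", "GC_L", "GU_L", "GU_stems", "MFEI3",
)

_ALL85 = _FS1 + _FS6 + ("max_aa_run", "low_complexity_pct", "internal_loops_cum")

#: canonical column id -> name as printed in the catalog
PAPER_NAMES = {
    "gc_content": "G+C content",
    "max_aa_run": "Maximal length of the amino acid string without stop codons",
    "low_complexity_pct": "Low complexity regions detected in the sequence (%)",
    "MFE": "Minimum free energy of folding (MFE)",
    "randfold_p": "Randfold (p)",
    "dG": "Normalized MFE (dG)",
    "MFEI1": "MFE index 1 (MFEI1)",
    "MFEI2": "MFE index 2 (MFEI2)",
    "MFEI3": "MFE index 3 (MFEI3)",
    "MFEI4": "MFE index 4 (MFEI4)",
    "NEFE": "Normalized ensemble free energy (NEFE)",
    "Diff": "Normalized difference (MFE-EFE) (Diff)",
    "Freq": "Frequency of the MFE structure (Freq)",
    "dP": "Normalized base-pairing propensity (dP)",
    "dQ": "Normalized Shannon entropy (dQ)",
    "Diversity": "Structural diversity (Diversity)",
    "dD": "Normalized base-pair distance (dD)",
    "Avg_Bp_Stem": "Average base pairs per stem (Avg_Bp_Stem)",
    "AU_L": "|A-U|/L",
    "GC_L": "|G-C|/L",
    "GU_L": "|G-U|/L",
    "AU_stems": "%(A-U)/stems",
    "GC_stems": "%(G-C)/stems",
    "GU_stems": "%(G-U)/stems",
    "internal_loops_cum": "Cumulative size of internal loops",
    "dS": "Structure entropy (dS)",
    "dS_L": "Normalized structure entropy (dS/L)",
    "dH": "Structure enthalpy (dH)",
    "dH_L": "Normalized structure enthalpy (dH/L)",
    "Tm": "Melting energy of the structure",
    "Tm_L": "Normalized melting energy of the structure",
    "dF": "Topological descriptor (dF)",
    "zG": "Normalized variant (zG)",
    "zP": "Normalized variant (zP)",
    "zQ": "Normalized variant (zQ)",
    "zD": "Normalized variant (zD)",
    "zF": "Normalized variant (zF)",
}

_SHUFFLE_FEATURES = frozenset({"zG", "zP", "zQ", "zD", "zF", "randfold_p"})
_ENSEMBLE_FEATURES = frozenset(
    {"NEFE", "Diff", "Freq", "dQ", "Diversity", "dD", "zG", "zP", "zQ",
     "zD", "zF"}
)
_THERMO_FEATURES = frozenset({"dS", "dS_L", "dH", "dH_L", "Tm", "Tm_L"})


@dataclass(frozen=True)
class FeatureSetDefinition:
    """An ordered, named feature set and its backend requirements."""

    id: str
    features: tuple[str, ...]
    requires: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"duplicate features in set {self.id}")

    @property
    def cardinality(self) -> int:
        return len(self.features)

    def __len__(self) -> int:
        return len(self.features)


def _requirements(features: Sequence[str]) -> frozenset[str]:
    req = set()
    fs = set(features)
    if fs - {"gc_content", "max_aa_run", "low_complexity_pct"} - set(_DINUC_NAMES):
        req.add("fold")
    if fs & _ENSEMBLE_FEATURES:
        req.add("ensemble")
    if fs & _THERMO_FEATURES:
        req.add("thermo")
    if fs & _SHUFFLE_FEATURES:
        req.add("shuffle")
    return frozenset(req)


def _definition(set_id: str, features: tuple[str, ...]) -> FeatureSetDefinition:
    return FeatureSetDefinition(
        id=set_id, features=features, requires=_requirements(features)
    )


FEATURE_SET_IDS = ("FS1", "FS2", "FS3", "FS4", "FS5", "FS6", "FS7",
                   "SELECT", "ALL85")


def get_feature_set(
    set_id: str, vocab: MotifVocabulary | None = None
) -> FeatureSetDefinition:
    """The registry entry for ``set_id``.

    FS5 is parameterized by a motif vocabulary (the deterministic default of
    1,300 motifs unless one is supplied).
    """
    if set_id == "FS5":
        v = vocab if vocab is not None else default_vocabulary()
        return _definition("FS5", v.names)
    table = {
        "FS1": _FS1,
        "FS2": _FS2,
        "FS3": _FS3,
        "FS4": _FS4,
        "FS6": _FS6,
        "FS7": _FS7,
        "SELECT": _SELECT,
        "ALL85": _ALL85,
    }
    if set_id not in table:
        raise KeyError(
            f"unknown feature set {set_id!r}; valid ids: {FEATURE_SET_IDS}"
        )
    return _definition(set_id, table[set_id])


# ---------------------------------------------------------------------------
# Extraction


class _RecordContext:
    """Lazily computes and caches per-record profiles and feature blocks."""

    def __init__(
        self,
        record: HairpinRecord,
        backend: StructureBackend,
        shuffle_cfg: ShuffleConfig,
        vocab: MotifVocabulary | None,
    ) -> None:
        self.record = record
        self.backend = backend
        self.shuffle_cfg = shuffle_cfg
        self.vocab = vocab
        self._cache: dict[str, object] = {}

    def _get(self, key: str, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def structure(self):
        return self._get(
            "structure",
            lambda: self.backend.fold(self.record.seq, self.record.id),
        )

    @property
    def elements(self):
        return self._get(
            "elements", lambda: decompose(self.record.seq, self.structure)
        )

    @property
    def ensemble(self):
        return self._get(
            "ensemble",
            lambda: self.backend.ensemble(self.record.seq, self.record.id),
        )

    @property
    def thermo(self):
        return self._get(
            "thermo",
            lambda: self.backend.thermo(self.record.seq, self.record.id),
        )

    def block(self, name: str) -> FeatureBlock:
        return self._get(f"block:{name}", lambda: self._build_block(name))

    def _build_block(self, name: str) -> FeatureBlock:
        rec = self.record
        b = FeatureBlock()
        if name == "dinuc":
            for d, v in sf.dinucleotide_frequencies(rec.seq).items():
                b.set(f"dinuc_{d}", v)
        elif name == "seq":
            b.set("gc_content", sf.gc_content(rec.seq))
            b.set("max_aa_run", sf.max_aa_run(rec.seq))
            b.set("low_complexity_pct", sf.low_complexity_pct(rec.seq))
        elif name == "energy":
            b.update(
                stf.energy_features(
                    self.structure, self.elements, self.ensemble,
                    sf.gc_content(rec.seq),
                )
            )
        elif name == "pairing":
            b.update(stf.pairing_features(rec.seq, self.elements))
        elif name == "ens":
            b.update(stf.ensemble_features(self.structure, self.ensemble))
        elif name == "topo":
            b.set("dF", stf.topological_dF(self.elements))
        elif name == "thermo":
            b.update(stf.thermo_features(self.thermo, rec.L))
        elif name == "mfe":
            b.set("MFE", self.structure.mfe)
        elif name == "triplet":
            for k, v in triplet_profile(rec.seq, self.structure).items():
                b.set(k, v)
        elif name == "stack":
            prof = triplet_profile(rec.seq, self.structure)
            for k, v in stacking_triplets(prof).items():
                b.set(k, v)
        elif name == "motif":
            tokens = ss_string(rec.seq, self.structure)
            for k, v in motif_counts(tokens, self.vocab).items():
                b.set(k, v)
        elif name == "zscores":
            b.update(zscore_features(rec, self.backend, self.shuffle_cfg))
        elif name == "randfold":
            b.set("randfold_p", randfold_p(rec, self.backend, self.shuffle_cfg))
        else:  # pragma: no cover
            raise KeyError(name)
        return b


_FEATURE_GROUP = {}
for _d in _DINUC_NAMES:
    _FEATURE_GROUP[_d] = "dinuc"
for _n in ("gc_content", "max_aa_run", "low_complexity_pct"):
    _FEATURE_GROUP[_n] = "seq"
for _n in ("dG", "MFEI1", "MFEI2", "MFEI3", "MFEI4", "NEFE", "Diff", "Freq"):
    _FEATURE_GROUP[_n] = "energy"
for _n in ("dP", "Avg_Bp_Stem", "AU_L", "GC_L", "GU_L", "AU_stems",
           "GC_stems", "GU_stems", "internal_loops_cum"):
    _FEATURE_GROUP[_n] = "pairing"
for _n in ("dQ", "Diversity", "dD"):
    _FEATURE_GROUP[_n] = "ens"
_FEATURE_GROUP["dF"] = "topo"
for _n in ("dS", "dS_L", "dH", "dH_L", "Tm", "Tm_L"):
    _FEATURE_GROUP[_n] = "thermo"
_FEATURE_GROUP["MFE"] = "mfe"
for _n in TRIPLET_NAMES:
    _FEATURE_GROUP[_n] = "triplet"
for _n in _STACK:
    _FEATURE_GROUP[_n] = "stack"
for _n in ("zG", "zP", "zQ", "zD", "zF"):
    _FEATURE_GROUP[_n] = "zscores"
_FEATURE_GROUP["randfold_p"] = "randfold"


def _group_of(feature: str) -> str:
    if feature in _FEATURE_GROUP:
        return _FEATURE_GROUP[feature]
    if feature.startswith("motif_"):
        return "motif"
    raise KeyError(f"unknown feature {feature!r}")


@dataclass
class FeatureMatrix:
    """A rectangular feature matrix with degenerate flags and provenance."""

    ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    flags: np.ndarray  # bool, same shape as values
    metadata: dict = field(default_factory=dict)
    row_errors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.values.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError("values shape inconsistent with ids/features")
        if self.flags.shape != self.values.shape:
            raise ValueError("flags shape inconsistent with values")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in sorted(self.metadata.items()):
                fh.write(f"# {k}: {v}\n")
            fh.write("id\t" + "\t".join(self.feature_names) + "\tflags\n")
            for r, rid in enumerate(self.ids):
                if rid in self.row_errors:
                    flag_txt = "!ERROR:" + self.row_errors[rid].replace(
                        "\t", " ").replace("\n", " ")
                else:
                    flagged = [
                        self.feature_names[c]
                        for c in range(len(self.feature_names))
                        if self.flags[r, c]
                    ]
                    flag_txt = ";".join(flagged)
                vals = "\t".join(f"{v:.10g}" for v in self.values[r])
                fh.write(f"{rid}\t{vals}\t{flag_txt}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        metadata: dict[str, str] = {}
        rows: list[tuple[str, list[float], str]] = []
        header: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("# ")
                    if ":" in body:
                        k, v = body.split(":", 1)
                        metadata[k.strip()] = v.strip()
                    continue
                parts = line.split("\t")
                if header is None:
                    header = parts
                    continue
                rows.append((parts[0], [float(x) for x in parts[1:-1]],
                             parts[-1]))
        if header is None:
            raise ValueError("empty feature matrix file")
        names = tuple(header[1:-1])
        ids = tuple(r[0] for r in rows)
        values = np.array([r[1] for r in rows], dtype=float).reshape(
            len(rows), len(names)
        )
        flags = np.zeros_like(values, dtype=bool)
        row_errors = {}
        idx = {n: i for i, n in enumerate(names)}
        for r, (rid, _, flag_txt) in enumerate(rows):
            if flag_txt.startswith("!ERROR:"):
                row_errors[rid] = flag_txt[len("!ERROR:"):]
                flags[r, :] = True
            elif flag_txt:
                for n in flag_txt.split(";"):
                    flags[r, idx[n]] = True
        return cls(ids=ids, feature_names=names, values=values, flags=flags,
                   metadata=metadata, row_errors=row_errors)


def extract(
    records: Iterable[HairpinRecord],
    set_id: str,
    backend: StructureBackend,
    *,
    vocab: MotifVocabulary | None = None,
    shuffle: ShuffleConfig | None = None,
    seed: int = 0,
) -> FeatureMatrix:
    """Compute the feature matrix of ``set_id`` for ``records``.

    Per-record failures are isolated: the offending row is zeroed, fully
    flagged and recorded in ``row_errors`` while extraction continues.
    A backend lacking a capability the set requires raises upfront, naming
    the blocked features.
    """
    definition = get_feature_set(set_id, vocab=vocab)
    shuffle_cfg = shuffle if shuffle is not None else ShuffleConfig(seed=seed)
    records = list(records)

    missing = definition.requires - set(backend.capabilities) - {"shuffle"}
    if missing:
        blocked = [
            f for f in definition.features
            if (_group_of(f) in ("energy", "ens") and "ensemble" in missing)
            or (_group_of(f) == "thermo" and "thermo" in missing)
            or ("fold" in missing)
        ]
        raise NoStructureSourceError(
            f"backend lacks {sorted(missing)} required by {set_id}; "
            f"blocked features: {blocked}"
        )

    vocab_obj = vocab
    if set_id == "FS5" and vocab_obj is None:
        vocab_obj = default_vocabulary()

    n, d = len(records), definition.cardinality
    values = np.zeros((n, d))
    flags = np.zeros((n, d), dtype=bool)
    row_errors: dict[str, str] = {}
    col = {f: i for i, f in enumerate(definition.features)}
    groups_needed = sorted({_group_of(f) for f in definition.features})

    for r, rec in enumerate(records):
        ctx = _RecordContext(rec, backend, shuffle_cfg, vocab_obj)
        try:
            merged = FeatureBlock()
            for g in groups_needed:
                merged.update(ctx.block(g))
            for f in definition.features:
                values[r, col[f]] = merged.values[f]
                if f in merged.degenerate:
                    flags[r, col[f]] = True
        except Exception as exc:  # isolate per-record failure
            values[r, :] = 0.0
            flags[r, :] = True
            row_errors[rec.id] = f"{type(exc).__name__}: {exc}"

    metadata = {
        "feature_set": set_id,
        "cardinality": d,
        "backend": type(backend).__name__,
        "seed": seed,
        "n_shuffles": shuffle_cfg.n_shuffles,
        "n_shuffles_p": shuffle_cfg.n_shuffles_p,
    }
    if set_id == "FS5":
        metadata["vocabulary"] = vocab_obj.id
    return FeatureMatrix(
        ids=tuple(rec.id for rec in records),
        feature_names=definition.features,
        values=values,
        flags=flags,
        metadata=metadata,
        row_errors=row_errors,
    )
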