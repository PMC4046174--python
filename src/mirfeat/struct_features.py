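"""Thermodynamic, ensemble, pairing and topological features.

All features follow the catalog conventions used across the microPred
lineage of pre-miRNA classifiers:

* ``dG`` is the MFE normalized by sequence length; ``MFEI1``–``MFEI4``
  normalize further by G+C *percentage*, stem count, loop count and base-pair
  count respectively (note: MFEI1 divides by the percentage, e.g. 50, not the
  fraction 0.5 — this changes the feature scale by a factor of 100).
* ``NEFE`` is the ensemble free energy per base and ``Diff`` the signed
  difference (MFE − EFE)/L.
* ``dQ`` is the Shannon entropy of the base-pair probabilities per base
  (log base 2), ``dD`` the expected base-pair distance to the MFE structure
  per base, ``Diversity`` the ensemble diversity.
* ``dF`` is the algebraic connectivity (second-smallest Laplacian
  eigenvalue) of the tree-graph representation of the structure — a
  compactness descriptor.

Degenerate denominators (no stems, no loops, no pairs, zero G+C) never
produce NaN: the feature is emitted as 0 and its name is recorded in the
block's ``degenerate`` set, which the extraction driver surfaces as a flag
column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rna_structures import (
    EnsembleProfile,
    NoStructureSourceError,
    SecondaryStructure,
    StructureElements,
    ThermoProfile,
)

__all__ = [
    "FeatureBlock",
    "energy_features",
    "pairing_features",
    "ensemble_features",
    "topological_dF",
    "thermo_features",
]


@dataclass
class FeatureBlock:
    """Named feature values plus the set of degenerate-flagged names."""

    values: dict[str, float] = field(default_factory=dict)
    degenerate: set[str] = field(default_factory=set)

    def set(self, name: str, value: float) -> None:
        self.values[name] = float(value)

    def set_ratio(self, name: str, num: float, denom: float) -> None:
        """num/denom, or 0 with a degenerate flag when denom == 0."""
        if denom == 0:
            self.values[name] = 0.0
            self.degenerate.add(name)
        else:
            self.values[name] = float(num / denom)

    def update(self, other: "FeatureBlock") -> None:
        self.values.update(other.values)
        self.degenerate.update(other.degenerate)


def energy_features(
    structure: SecondaryStructure,
    elements: StructureElements,
    ensemble: EnsembleProfile,
    gc_pct: float,
) -> FeatureBlock:
    """dG, MFEI1–MFEI4, NEFE, Diff and Freq."""
    L = structure.L
    mfe, efe = structure.mfe, ensemble.efe
    b = FeatureBlock()
    b.set_ratio("dG", mfe, L)
    dG = b.values["dG"]
    b.set_ratio("MFEI1", dG, gc_pct)
    b.set_ratio("MFEI2", dG, elements.n_stems)
    b.set_ratio("MFEI3", dG, elements.n_loops)
    b.set_ratio("MFEI4", mfe, elements.bp_total)
    b.set_ratio("NEFE", efe, L)
    b.set_ratio("Diff", mfe - efe, L)
    b.set("Freq", ensemble.freq_mfe)
    return b


def pairing_features(seq: str, elements: StructureElements) -> FeatureBlock:
    """Pairing propensities per base and per stem, plus loop totals."""
    L = len(seq)
    b = FeatureBlock()
    b.set_ratio("dP", elements.bp_total, L)
    b.set_ratio("Avg_Bp_Stem", elements.bp_total, elements.n_stems)
    for cls, n in (
        ("AU", elements.bp_AU),
        ("GC", elements.bp_GC),
        ("GU", elements.bp_GU),
    ):
        b.set_ratio(f"{cls}_L", n, L)
        b.set_ratio(f"{cls}_stems", n, elements.n_stems)
    b.set("internal_loops_cum", elements.internal_loop_total)
    # pair-free structures carry no pairing signal at all: flag the zeros
    if elements.bp_total == 0:
        for name in ("dP", "AU_L", "GC_L", "GU_L"):
            b.degenerate.add(name)
    return b


def ensemble_features(
    structure: SecondaryStructure, ensemble: EnsembleProfile
) -> FeatureBlock:
    """dQ (positional Shannon entropy), Diversity and dD (normalized
    expected base-pair distance to the MFE structure)."""
    if ensemble is None:
        raise NoStructureSourceError("no ensemble profile available")
    L = structure.L
    mfe_pairs = structure.pair_set()
    dq = 0.0
    dd = 0.0
    for pair, p in ensemble.bpp.items():
        if 0.0 < p < 1.0:
            dq -= p * math.log2(p)
        if pair in mfe_pairs:
            dd += 1.0 - p
        else:
            dd += p
    # MFE pairs absent from the (sparse) bpp map still contribute distance 1
    for pair in mfe_pairs:
        if pair not in ensemble.bpp:
            dd += 1.0
    b = FeatureBlock()
    b.set_ratio("dQ", dq, L)
    b.set("Diversity", ensemble.diversity if ensemble.diversity > 0
          else _diversity_from_bpp(ensemble))
    b.set_ratio("dD", dd, L)
    return b


def _diversity_from_bpp(ensemble: EnsembleProfile) -> float:
    return sum(2.0 * p * (1.0 - p) for p in ensemble.bpp.values())


def topological_dF(elements: StructureElements) -> float:
    """Algebraic connectivity of the structure's tree graph.

    Vertices are the loops plus the exterior region, edges the stems.  A
    single-vertex graph (open chain) scores 0; a plain hairpin is K2 with
    eigenvalues {0, 2}, hence dF = 2.
    """
    n = elements.n_tree_vertices
    if n <= 1:
        return 0.0
    lap = np.zeros((n, n))
    for a, bv in elements.tree_edges:
        lap[a, a] += 1
        lap[bv, bv] += 1
        lap[a, bv] -= 1
        lap[bv, a] -= 1
    eig = np.linalg.eigvalsh(lap)
    return float(eig[1])


def thermo_features(thermo: ThermoProfile, L: int) -> FeatureBlock:
    """Structure entropy/enthalpy/melting energy with per-base variants."""
    if thermo is None:
        raise NoStructureSourceError(
            "no thermodynamic profile: features dS, dS_L, dH, dH_L, Tm, Tm_L "
            "require a thermo backend or sidecar"
        )
    if L < 1:
        raise ValueError("L must be positive")
    b = FeatureBlock()
    b.set("dS", thermo.dS)
    b.set("dS_L", thermo.dS / L)
    b.set("dH", thermo.dH)
    b.set("dH_L", thermo.dH / L)
    if thermo.tm is None:
        b.set("Tm", 0.0)
        b.set("Tm_L", 0.0)
        b.degenerate.update({"Tm", "Tm_L"})
    else:
        b.set("Tm", thermo.tm)
        b.set("Tm_L", thermo.tm / L)
    return b
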