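"""Dot-bracket parsing, structural decomposition, backends and file I/O."""

import math

import numpy as np
import pytest

from mirfeat.rna_structures import (
    DotBracketError,
    FixtureBackend,
    HairpinRecord,
    NoStructureSourceError,
    NonCanonicalPairError,
    SecondaryStructure,
    decompose,
    normalize_sequence,
    parse_dotbracket,
    read_vienna,
    render_dotbracket,
    validate_min_loop,
    write_vienna,
)


def stack_oracle(db: str) -> dict[int, int]:
    """Independent explicit-stack pairing oracle (1-based)."""
    stack, out = [], {}
    for i, c in enumerate(db, 1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            out[i], out[j] = j, i
    return out


class TestParseDotbracket:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("((..))", {1: 6, 6: 1, 2: 5, 5: 2}),
            ("......", {}),
        ],
    )
    def test_small_cases(self, db, expected):
        pairs = parse_dotbracket(db)
        got = {i: pairs[i] for i in range(1, len(db) + 1) if pairs[i]}
        assert got == expected

    def test_matches_stack_oracle(self):
        db = "((..))((...))"
        pairs = parse_dotbracket(db)
        oracle = stack_oracle(db)
        for i in range(1, 14):
            assert pairs[i] == oracle.get(i, 0)

    @pytest.mark.parametrize("db,pos", [("((.)", 1), (".))", 2), ("(x)", 2)])
    def test_errors_name_offending_index(self, db, pos):
        with pytest.raises(DotBracketError, match=str(pos)):
            parse_dotbracket(db)

    def test_involution_and_roundtrip(self):
        for db in ["((..))", "......", "((..))((...))", "((.((...)).))"]:
            pairs = parse_dotbracket(db)
            for i in range(1, len(db) + 1):
                if pairs[i]:
                    assert pairs[pairs[i]] == i
            assert render_dotbracket(pairs) == db

    def test_min_loop_validation(self):
        validate_min_loop(parse_dotbracket("((...))"))
        with pytest.raises(ValueError, match="hairpin loop"):
            validate_min_loop(parse_dotbracket("((..))"))


class TestDecompose:
    def test_canonical_hairpin(self):
        el = decompose("GGGAAACCC", SecondaryStructure.from_db("(((...)))"))
        assert el.n_stems == 1
        assert len(el.stems[0]) == 3
        assert el.loops[:-1] == (("hairpin", 3),)
        assert el.internal_loop_total == 0
        assert (el.bp_GC, el.bp_AU, el.bp_GU) == (3, 0, 0)
        assert el.bp_total == 3

    def test_two_stem_internal_loop(self):
        # 13-nt structure: outer stem of 2, internal loop of 2 (one base each
        # side), inner stem of 2, hairpin of 3
        el = decompose(
            "GGAGGAAACCACC", SecondaryStructure.from_db("((.((...)).))")
        )
        assert [len(s) for s in el.stems] == [2, 2]
        kinds = [k for k, _ in el.loops]
        assert kinds == ["internal", "hairpin", "exterior"]
        assert dict(el.loops[:-1])["internal"] == 2
        assert el.internal_loop_total == 2

    def test_open_chain(self):
        el = decompose("AAAAAAAAA", SecondaryStructure.from_db("........."))
        assert el.n_stems == 0
        assert el.n_loops == 0
        assert el.bp_total == 0
        assert el.tree_edges == ()

    def test_non_canonical_pair_rejected(self):
        with pytest.raises(NonCanonicalPairError, match=r"A-C|C-A"):
            decompose("AAC", SecondaryStructure.from_db("(.)"))

    def test_bulge_taxonomy(self):
        el = decompose(
            "GGAGGAAACCCC", SecondaryStructure.from_db("((.((...))))")
        )
        kinds = [k for k, _ in el.loops[:-1]]
        assert "bulge" in kinds
        assert el.internal_loop_total == 1

    def test_stem_sizes_sum_to_bp_total(self, small_dataset):
        pos, neg = small_dataset
        for sr in pos + neg:
            el = decompose(sr.record.seq, sr.structure)
            assert sum(len(s) for s in el.stems) == el.bp_total
            # every position is in exactly one element: pairs + loop sizes
            in_loops = sum(n for _, n in el.loops)
            assert 2 * el.bp_total + in_loops == sr.record.L


class TestRecordsAndNormalization:
    def test_t_mapped_and_casefolded(self):
        rec = HairpinRecord(id="x", seq="acgt")
        assert rec.seq == "ACGU"
        assert rec.L == 4

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError, match="N"):
            normalize_sequence("ACGN")


class TestViennaIO:
    def test_file_echo(self, tmp_path):
        p = tmp_path / "f.vienna"
        p.write_text(">r1\nGGAAGG\n((..)) (-1.20)\n")
        (rid, seq, struct), = list(read_vienna(p))
        assert rid == "r1"
        assert struct.mfe == -1.20
        assert struct.db == "((..))"

    def test_roundtrip_identity(self, tmp_path):
        entries = [
            ("a", "GGGAAACCC", SecondaryStructure.from_db("(((...)))", -2.5)),
            ("b", "ACGUACGU", SecondaryStructure.from_db("........", 0.0)),
            ("c", "GGAAGG", SecondaryStructure.from_db("((..))", -1.2)),
        ]
        p1, p2 = tmp_path / "a.vienna", tmp_path / "b.vienna"
        write_vienna(entries, p1)
        write_vienna(list(read_vienna(p1)), p2)
        assert p1.read_text() == p2.read_text()


class TestBackends:
    def test_fixture_backend_reads_files(self, dataset_files, small_dataset):
        fb = FixtureBackend(dataset_files["vienna"], dataset_files["sidecar"])
        pos, _ = small_dataset
        sr = pos[0]
        st = fb.fold(sr.record.seq, sr.record.id)
        assert st.db == sr.structure.db
        assert st.mfe == pytest.approx(sr.structure.mfe)
        ens = fb.ensemble(sr.record.seq, sr.record.id)
        assert ens.freq_mfe == pytest.approx(sr.sidecar["freq_mfe"], rel=1e-4)
        th = fb.thermo(sr.record.seq, sr.record.id)
        assert th.dS == pytest.approx(sr.sidecar["dS"], rel=1e-4)

    def test_no_structure_source_error(self):
        fb = FixtureBackend()
        with pytest.raises(NoStructureSourceError, match="no fixture"):
            fb.fold("ACGUACGU", "unknown")

    def test_short_sequence_folds_open(self, vienna_backend):
        st = vienna_backend.fold("ACG")
        assert st.db == "..."
        assert st.mfe == 0.0

    def test_fixture_agrees_with_live_engine(self, tmp_path, vienna_backend):
        seqs = {
            "h1": "GGGGGAAAACCCCC",
            "h2": "GCGCGCAAAGCGCGC",
            "h3": "AAUUGGCCAAAGGCCAAUU",
        }
        entries = [
            (rid, seq, vienna_backend.fold(seq)) for rid, seq in seqs.items()
        ]
        p = tmp_path / "live.vienna"
        write_vienna(entries, p)
        fb = FixtureBackend(p)
        for rid, seq in seqs.items():
            live = vienna_backend.fold(seq)
            fixed = fb.fold(seq, rid)
            assert fixed.db == live.db
            assert fixed.mfe == pytest.approx(live.mfe, abs=0.005)

    def test_ensemble_invariants_live(self, vienna_backend):
        ens = vienna_backend.ensemble("GGGGGAAAACCCCC")
        assert 0.0 <= ens.freq_mfe <= 1.0
        assert all(0.0 <= p <= 1.0 for p in ens.bpp.values())
        assert ens.diversity >= 0.0

    def test_thermo_live_consistency(self, vienna_backend):
        seq = "GGGGGAAAACCCCC"
        th = vienna_backend.thermo(seq)
        mfe = vienna_backend.fold(seq).mfe
        # dG = dH - T*dS/1000 holds by construction at the base temperature
        assert mfe == pytest.approx(th.dH - 310.15 * th.dS / 1000.0, abs=1e-6)
        assert math.isfinite(th.tm)
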