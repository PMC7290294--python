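"""Inactivating-mutation scanning, status calls, and branch assignment."""

import pytest

from omegascan import (
    MutationKind,
    RawAlignment,
    classify_status,
    map_events_to_branches,
    scan_sequence,
)
from omegascan.inactivation import MutationEvent, ScanConfigError
from omegascan.trees import PhyloTree

# a 30-nt (10-codon) intact reference ORF, no internal ATG after codon 0
REF = "ATGGCCAAACTGGTCCGCGATTACCGCTAA"


def _aln(rows: dict[str, str], anchor: int = 1) -> RawAlignment:
    return RawAlignment(taxa=list(rows), rows=list(rows.values()), frame_anchor=anchor)


class TestScanSequence:
    def test_identical_to_references_yields_nothing(self, code):
        aln = _aln({"r1": REF, "r2": REF, "r3": REF, "q": REF})
        assert scan_sequence(aln, "q", ["r1", "r2", "r3"], code) == []

    def test_mixed_catalog_recovered(self, code):
        # two insertions, two nonsense mutations, one deletion in one taxon
        # (the classic fully-pseudogenized profile)
        ref = "ATG" + "GCC" * 10 + "AAA" + "CTG" * 10 + "GTCCGCGATTAC"
        q = list(ref)
        r = list(ref)
        q[15:18] = "TGA"  # nonsense at codon 6
        q[45:48] = "TAG"  # nonsense at codon 16
        q[60] = "-"       # 1-nt deletion at codon 21
        # insertions applied back-to-front so coordinates stay valid
        q[33:33], r[33:33] = list("GG"), list("--")  # 2-nt insertion
        q[9:9], r[9:9] = list("T"), list("-")        # 1-nt insertion
        aln = _aln({"r1": "".join(r), "r2": "".join(r), "r3": "".join(r),
                    "q": "".join(q)})
        events = scan_sequence(aln, "q", ["r1", "r2", "r3"], code)
        kinds = sorted(e.kind.value for e in events)
        assert kinds == [
            "frameshift_deletion",
            "frameshift_insertion",
            "frameshift_insertion",
            "premature_stop",
            "premature_stop",
        ]
        stops = sorted(e.column_start for e in events
                       if e.kind is MutationKind.premature_stop)
        # codon 6 starts at nt 16; +1 for the upstream 1-nt insertion
        # codon 16 starts at nt 46; +3 for both upstream insertions
        assert stops == [17, 49]

    def test_compensated_colocated_insertions_are_not_frameshifts(self, code):
        # 2-nt + 4-nt insertions at the same site: net 6, in frame
        ref = "ATGGCCAAACTG------GTCCGCGATTAC"
        q = "ATGGCCAAACTGTTTTTTGTCCGCGATTAC"
        aln = _aln({"r1": ref, "r2": ref, "q": q})
        events = scan_sequence(aln, "q", ["r1", "r2"], code)
        assert [e for e in events if "frameshift" in e.kind.value] == []

    def test_start_loss_without_rescue(self, code):
        q = "GTG" + REF[3:]
        aln = _aln({"r1": REF, "r2": REF, "q": q})
        events = scan_sequence(aln, "q", ["r1", "r2"], code, rescue_window_nt=100)
        assert [e.kind for e in events] == [MutationKind.start_loss]
        assert events[0].column_start == 1

    def test_start_mutation_rescued_by_inframe_atg(self, code):
        # mutated start but an in-frame ATG at codon 3, well inside the window
        ref = "ATGGCCAAACTGGTCCGCGATTAC"
        q = "GTGGCCATGCTGGTCCGCGATTAC"
        aln = _aln({"r1": ref, "r2": ref, "q": q})
        assert scan_sequence(aln, "q", ["r1", "r2"], code, rescue_window_nt=100) == []

    def test_displaced_out_of_frame_start_is_putative_shift(self, code):
        ref = "ATGGCCAAACTGGTCCGCGATTACCGC"
        q = "GTGGCCAAACATGGCCCGCGATTACCGC"[:27]  # ATG at nt 11 (offset 10, %3=1)
        aln = _aln({"r1": ref, "r2": ref, "q": q})
        events = scan_sequence(aln, "q", ["r1", "r2"], code)
        assert [e.kind for e in events] == [MutationKind.start_stop_shift]

    def test_errors(self, code):
        aln = _aln({"r1": REF, "q": REF})
        with pytest.raises(KeyError):
            scan_sequence(aln, "missing", ["r1"], code)
        with pytest.raises(ScanConfigError):
            scan_sequence(aln, "q", ["q"], code)  # empty after self-exclusion


class TestClassify:
    def test_rules(self):
        fs = MutationEvent(
            kind=MutationKind.frameshift_deletion, column_start=5, column_end=5,
            length_nt=1, taxa=("x",),
        )
        shift = MutationEvent(
            kind=MutationKind.start_stop_shift, column_start=1, column_end=3,
            length_nt=3, taxa=("x",),
        )
        assert classify_status("x", [fs]).status == "pseudogene"
        assert classify_status("x", []).status == "intact"
        st = classify_status("x", [shift])
        assert st.status == "pseudogene" and st.putative

    def test_invariant_status_iff_events(self):
        from omegascan.inactivation import GeneStatus

        with pytest.raises(ValueError):
            GeneStatus(taxon="x", status="pseudogene", events=[])


class TestBranchAssignment:
    TREE = PhyloTree.from_newick("((w1:1,(w2:1,w3:1):1):1,(o1:1,(o2:1,o3:1):1):1);")

    def _stop(self, taxon, col=10):
        return MutationEvent(
            kind=MutationKind.premature_stop, column_start=col, column_end=col + 2,
            length_nt=3, taxa=(taxon,),
        )

    def test_shared_event_lands_on_stem(self):
        statuses = [classify_status(t, [self._stop(t)]) for t in ("w1", "w2", "w3")]
        mapped = map_events_to_branches(statuses, self.TREE)
        assert len(mapped) == 1
        assert mapped[0].branch == ("w1", "w2", "w3")

    def test_single_carrier_lands_on_terminal_branch(self):
        statuses = [classify_status("o2", [self._stop("o2")])]
        mapped = map_events_to_branches(statuses, self.TREE)
        assert mapped[0].branch == ("o2",)

    def test_non_clade_carriers_split_into_maximal_subclades(self):
        # same column in w2,w3 (a clade) and o1 (not connected): two events
        statuses = [classify_status(t, [self._stop(t)]) for t in ("w2", "w3", "o1")]
        mapped = map_events_to_branches(statuses, self.TREE)
        branches = sorted(e.branch for e in mapped)
        assert branches == [("o1",), ("w2", "w3")]

    def test_different_columns_stay_independent(self):
        statuses = [
            classify_status("w1", [self._stop("w1", col=10)]),
            classify_status("o1", [self._stop("o1", col=40)]),
        ]
        mapped = map_events_to_branches(statuses, self.TREE)
        assert len(mapped) == 2

    def test_carriers_partition_exactly(self):
        statuses = [classify_status(t, [self._stop(t)]) for t in ("w1", "w2", "o1", "o2", "o3")]
        mapped = map_events_to_branches(statuses, self.TREE)
        seen = [t for e in mapped for t in e.taxa]
        assert sorted(seen) == ["o1", "o2", "o3", "w1", "w2"]

    def test_unknown_carrier_raises(self):
        statuses = [classify_status("zz", [self._stop("zz")])]
        with pytest.raises(KeyError):
            map_events_to_branches(statuses, self.TREE)
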