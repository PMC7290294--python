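"""Detection of inactivating mutations and their phylogenetic placement.

A sequence is scanned against the reading frame defined by a set of intact
reference taxa: frameshift indels (net run length not a multiple of 3),
premature stop codons in the reference frame, start-codon loss (with an
in-frame ATG rescue window), and the putative start+stop displacement
pattern.  Shared events are merged across carriers and assigned to the
stem branch of the smallest clade containing exactly those carriers
(Dollo-style single origin); carriers that do not form a clade are split
into maximal sub-clades, each with its own independent event.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .alignment import RawAlignment
from .genetics import NUCLEOTIDES, GeneticCode
from .trees import Node, PhyloTree

UNASSIGNED = ("UNASSIGNED",)

#: Indel runs separated by at most this many matching columns are merged
#: before the mod-3 frameshift test (handles compensated insertions).
MERGE_GAP = 2


class MutationKind(str, Enum):
    frameshift_insertion = "frameshift_insertion"
    frameshift_deletion = "frameshift_deletion"
    premature_stop = "premature_stop"
    start_loss = "start_loss"
    start_stop_shift = "start_stop_shift"


@dataclass(frozen=True)
class MutationEvent:
    """One inactivating mutation, possibly shared by several taxa."""

    kind: MutationKind
    column_start: int  # 1-based alignment column
    column_end: int
    length_nt: int
    taxa: tuple[str, ...]
    branch: tuple[str, ...] = UNASSIGNED  # clade id of the assigned stem edge

    def __post_init__(self) -> None:
        if self.column_start > self.column_end:
            raise ValueError("column_start must be <= column_end")
        if self.kind in (MutationKind.frameshift_insertion, MutationKind.frameshift_deletion):
            if self.length_nt % 3 == 0:
                raise ValueError("frameshift events must have length_nt % 3 != 0")
        if self.kind is MutationKind.premature_stop and self.length_nt != 3:
            raise ValueError("premature_stop events have length_nt = 3")

    @property
    def signature(self) -> tuple:
        return (self.kind, self.column_start, self.length_nt)


@dataclass
class GeneStatus:
    taxon: str
    status: str  # "intact" | "pseudogene"
    events: list[MutationEvent]
    putative: bool = False

    def __post_init__(self) -> None:
        if (self.status == "pseudogene") != bool(self.events):
            raise ValueError("status must be pseudogene iff events is non-empty")


class ScanConfigError(ValueError):
    pass


# --------------------------------------------------------------------------
# consensus reference frame
# --------------------------------------------------------------------------


def consensus_row(raw: RawAlignment, reference_taxa: Sequence[str]) -> str:
    """Majority-rule consensus over the reference taxa, gap as a state.

    Ties break toward a base over a gap, then alphabetically; N loses to
    any concrete base.
    """
    if not reference_taxa:
        raise ScanConfigError("empty reference set")
    rows = [raw.row(t) for t in reference_taxa]
    out = []
    for c in range(raw.n_columns):
        counts: dict[str, int] = defaultdict(int)
        for r in rows:
            counts[r[c]] += 1
        # sort: count desc, bases before N before gap, alphabetical
        def rank(item):
            ch, n = item
            klass = 2 if ch == "-" else (1 if ch == "N" else 0)
            return (-n, klass, ch)

        out.append(sorted(counts.items(), key=rank)[0][0])
    return "".join(out)


def _reference_codons(consensus: str, frame_anchor: int) -> list[tuple[int, int, int]]:
    """0-based column triples of the reference codons (consensus non-gap)."""
    cols = [c for c in range(frame_anchor - 1, len(consensus)) if consensus[c] != "-"]
    return [tuple(cols[i : i + 3]) for i in range(0, len(cols) - len(cols) % 3, 3)]


def _indel_runs(focal: str, consensus: str, frame_anchor: int) -> list[dict]:
    """Merged indel runs of the focal row relative to the consensus.

    Each run records inserted and deleted base counts and its column span;
    runs separated by <= MERGE_GAP matching columns are merged before the
    frameshift (mod 3) test.
    """
    diffs = []  # (col, +1 insertion / -1 deletion)
    for c in range(frame_anchor - 1, len(consensus)):
        f, r = focal[c], consensus[c]
        if f != "-" and r == "-":
            diffs.append((c, 1))
        elif f == "-" and r != "-":
            diffs.append((c, -1))
    runs: list[dict] = []
    for col, d in diffs:
        if runs and col - runs[-1]["last"] <= MERGE_GAP + 1:
            run = runs[-1]
        else:
            run = {"start": col, "last": col, "ins": 0, "dele": 0}
            runs.append(run)
        run["last"] = col
        if d > 0:
            run["ins"] += 1
        else:
            run["dele"] += 1
    return runs


def _find_inframe_atg(
    focal: str,
    ref_codons: list[tuple[int, int, int]],
    window_nt: int,
) -> bool:
    """Is there an in-frame ATG within window_nt of the start, focal row?"""
    n_codons = min(len(ref_codons), window_nt // 3 + 1)
    for k in range(n_codons):
        codon = "".join(focal[c] for c in ref_codons[k])
        if codon == "ATG":
            return True
    return False


def scan_sequence(
    raw: RawAlignment,
    taxon: str,
    reference_taxa: Iterable[str],
    code: GeneticCode,
    rescue_window_nt: int = 100,
) -> list[MutationEvent]:
    """Scan one taxon against the reference reading frame.

    Returns the inactivating mutations of the focal sequence: frameshift
    indels, premature stops (in the reference frame), start-codon loss
    (unless rescued by an in-frame ATG within ``rescue_window_nt``), and
    the putative start+stop displacement pattern (a mutated start with an
    out-of-frame ATG nearby downstream).
    """
    refs = [t for t in reference_taxa if t != taxon]
    if not refs:
        raise ScanConfigError("empty reference set after excluding the focal taxon")
    focal = raw.row(taxon)  # raises KeyError if absent
    cons = consensus_row(raw, refs)
    events: list[MutationEvent] = []

    # (a) frameshift indels
    for run in _indel_runs(focal, cons, raw.frame_anchor):
        net = run["ins"] - run["dele"]
        if net % 3 == 0:
            continue
        kind = (
            MutationKind.frameshift_insertion
            if run["ins"] >= run["dele"]
            else MutationKind.frameshift_deletion
        )
        events.append(
            MutationEvent(
                kind=kind,
                column_start=run["start"] + 1,
                column_end=run["last"] + 1,
                length_nt=abs(net),
                taxa=(taxon,),
            )
        )

    ref_codons = _reference_codons(cons, raw.frame_anchor)
    if not ref_codons:
        return events

    # (b) premature stops in the reference frame (the final reference codon
    # is allowed to be a stop: it is the ORF terminator)
    for k, triple in enumerate(ref_codons[:-1]):
        codon = "".join(focal[c] for c in triple)
        if code.is_stop(codon):
            events.append(
                MutationEvent(
                    kind=MutationKind.premature_stop,
                    column_start=triple[0] + 1,
                    column_end=triple[2] + 1,
                    length_nt=3,
                    taxa=(taxon,),
                )
            )

    # (c) start-codon loss, with the in-frame ATG rescue window
    start_codon = "".join(focal[c] for c in ref_codons[0])
    if start_codon != "ATG" and "-" not in start_codon and "N" not in start_codon:
        if not _find_inframe_atg(focal, ref_codons, rescue_window_nt):
            # (d) out-of-frame ATG nearby downstream => putative start+stop shift
            limit = ref_codons[0][0] + rescue_window_nt
            window = focal[ref_codons[0][0] : limit + 3].replace("-", "")
            shifted = any(
                window[i : i + 3] == "ATG" and i % 3 != 0
                for i in range(len(window) - 2)
            )
            kind = MutationKind.start_stop_shift if shifted else MutationKind.start_loss
            events.append(
                MutationEvent(
                    kind=kind,
                    column_start=ref_codons[0][0] + 1,
                    column_end=ref_codons[0][2] + 1,
                    length_nt=3,
                    taxa=(taxon,),
                )
            )
    return events


def classify_status(taxon: str, events: list[MutationEvent]) -> GeneStatus:
    """Intact vs pseudogene call from a taxon's scanned events.

    Any frameshift, premature stop, or start loss makes a pseudogene; a
    start+stop shift alone also does, but flagged as putative.
    """
    if not events:
        return GeneStatus(taxon=taxon, status="intact", events=[])
    decisive = {
        MutationKind.frameshift_insertion,
        MutationKind.frameshift_deletion,
        MutationKind.premature_stop,
        MutationKind.start_loss,
    }
    putative = not any(e.kind in decisive for e in events)
    return GeneStatus(taxon=taxon, status="pseudogene", events=list(events), putative=putative)


def _maximal_subclades(tree: PhyloTree, carriers: set[str]) -> list[Node]:
    """Deterministic preorder split of a taxon set into maximal clades."""
    found: list[Node] = []

    def visit(node: Node) -> None:
        leaves = set(node.leaf_names())
        if leaves <= carriers:
            found.append(node)
            return
        if leaves & carriers:
            for c in node.children:
                visit(c)

    visit(tree.root)
    return found


def map_events_to_branches(
    statuses: Sequence[GeneStatus], tree: PhyloTree
) -> list[MutationEvent]:
    """Merge shared events and assign each to a stem branch.

    Events with identical (kind, column_start, length_nt) are merged across
    taxa; each merged event lands on the stem edge of the smallest clade
    containing exactly its carriers.  Carriers that do not form a clade are
    split into maximal sub-clades, yielding independent events.
    """
    leaves = set(tree.leaves)
    groups: dict[tuple, dict] = {}
    order: list[tuple] = []
    for st in statuses:
        for ev in st.events:
            missing = set(ev.taxa) - leaves
            if missing:
                raise KeyError(f"event carriers not in tree: {sorted(missing)}")
            g = groups.get(ev.signature)
            if g is None:
                groups[ev.signature] = g = {"event": ev, "taxa": set()}
                order.append(ev.signature)
            g["taxa"].update(ev.taxa)

    out: list[MutationEvent] = []
    for sig in order:
        ev = groups[sig]["event"]
        carriers = groups[sig]["taxa"]
        for node in _maximal_subclades(tree, carriers):
            part = tuple(sorted(node.leaf_names()))
            out.append(replace(ev, taxa=part, branch=part))
    return out
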