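"""Synthetic codon alignments under branch-specific omega, with injected
inactivation events and a truth table.

Sequences evolve along a tree by per-branch transition-matrix sampling
(site-independent): root codons are drawn from the equilibrium
distribution, and each branch multiplies through P(t) = exp(Qt) built
with that branch's omega.  Inactivation events — frameshift indels,
nonsense substitutions, start-codon loss, and start+stop displacement —
are injected afterwards onto designated branches, so the selection signal
(omega) and the disruption signal (events) stay independently
controllable, mirroring the two diagnostic criteria the scanner and the
model fits implement.

Defaults emulate a conserved single-copy marker gene under purifying
selection: background omega 0.4, relaxed foreground omega around 1,
transition/transversion ratio kappa = 2, sequence length 324 codons
(a 972-bp ORF, the modal intact length of the marker this package was
built around).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import RawAlignment
from .codon_model import CodonFrequencies, FrequencyScheme, build_rate_matrix
from .genetics import NUCLEOTIDES, STANDARD_CODE, GeneticCode
from .inactivation import MutationEvent, MutationKind
from .trees import Node, PhyloTree

DEFAULT_BACKGROUND_OMEGA = 0.4
DEFAULT_FOREGROUND_OMEGA = 1.0
DEFAULT_KAPPA = 2.0
DEFAULT_N_CODONS = 324


@dataclass(frozen=True)
class Injection:
    """One inactivation event to inject.

    ``branch`` is the clade id (sorted tuple of descendant leaf labels, or
    a single leaf label) of the edge the event occurs on; ``position_nt``
    is 1-based in the pre-injection sequence.  For nonsense and start
    events the position must sit on a codon boundary; for
    ``start_stop_shift`` the ``length_nt`` is the downstream displacement
    of the new (out-of-frame) start, not a multiple of 3.
    """

    branch: tuple[str, ...] | str
    kind: MutationKind
    position_nt: int
    length_nt: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", MutationKind(self.kind))
        if isinstance(self.branch, str):
            object.__setattr__(self, "branch", (self.branch,))
        else:
            object.__setattr__(self, "branch", tuple(sorted(self.branch)))
        if self.position_nt < 1:
            raise ValueError("position_nt is 1-based")
        if self.kind in (MutationKind.frameshift_insertion, MutationKind.frameshift_deletion):
            if self.length_nt % 3 == 0:
                raise ValueError("frameshift injection length must not be a multiple of 3")
        if self.kind is MutationKind.premature_stop and self.position_nt % 3 != 1:
            raise ValueError("nonsense injections must start on a codon boundary")
        if self.kind is MutationKind.start_stop_shift and self.length_nt % 3 == 0:
            raise ValueError("start_stop_shift displacement must be out of frame")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic data set."""

    tree: PhyloTree
    omega_by_category: dict[int, float] = field(
        default_factory=lambda: {0: DEFAULT_BACKGROUND_OMEGA, 1: DEFAULT_FOREGROUND_OMEGA}
    )
    kappa: float = DEFAULT_KAPPA
    freqs: CodonFrequencies | None = None  # None => uniform over sense codons
    n_codons: int = DEFAULT_N_CODONS
    seed: int = 0
    injections: list[Injection] = field(default_factory=list)
    fix_start_codon: bool = True

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0 or any(w < 0 for w in self.omega_by_category.values()):
            raise ValueError("kappa must be > 0 and omegas >= 0")


@dataclass
class SimulatedBundle:
    alignment: RawAlignment
    truth_params: dict
    truth_events: list[MutationEvent]
    leaf_states: dict[str, np.ndarray] = field(default_factory=dict)
    root_states: np.ndarray | None = None


def _resolve_branch(tree: PhyloTree, clade: tuple[str, ...]) -> Node:
    for node in tree.postorder():
        if node.parent is not None and tuple(sorted(node.leaf_names())) == clade:
            return node
    raise KeyError(f"no branch subtends exactly {clade}")


def simulate_alignment(
    cfg: SimulationConfig, code: GeneticCode = STANDARD_CODE
) -> SimulatedBundle:
    """Evolve codon sequences along the tree; inject configured events.

    Deterministic given the seed: identical configs produce byte-identical
    alignments.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = cfg.freqs or CodonFrequencies(FrequencyScheme.CF0, np.full(61, 1.0 / 61.0))
    matrices = {
        cat: build_rate_matrix(freqs, cfg.kappa, w, code)
        for cat, w in cfg.omega_by_category.items()
    }
    n = cfg.n_codons
    root = rng.choice(61, size=n, p=freqs.pi)
    atg = code.index("ATG")
    if cfg.fix_start_codon:
        root[0] = atg

    states: dict[int, np.ndarray] = {id(cfg.tree.root): root}
    for node in cfg.tree.preorder():
        if node.parent is None:
            continue
        if node.length is None:
            raise ValueError(f"branch above {node.name or 'internal node'} has no length")
        if node.category not in matrices:
            raise KeyError(f"no omega configured for category {node.category}")
        P = matrices[node.category].transition_probabilities(node.length)
        parent = states[id(node.parent)]
        child = np.empty_like(parent)
        for s in np.unique(parent):
            idx = np.nonzero(parent == s)[0]
            child[idx] = rng.choice(61, size=idx.size, p=P[s])
        if cfg.fix_start_codon:
            child[0] = atg
        states[id(node)] = child

    leaf_order = cfg.tree.leaves
    leaf_states = {
        node.name: states[id(node)]
        for node in cfg.tree.postorder()
        if node.is_leaf
    }
    rows = [
        "".join(code.sense_codons[s] for s in leaf_states[name]) for name in leaf_order
    ]
    bundle = SimulatedBundle(
        alignment=RawAlignment(taxa=list(leaf_order), rows=rows, frame_anchor=1),
        truth_params={
            "kappa": cfg.kappa,
            "omega_by_category": dict(cfg.omega_by_category),
            "branch_lengths": {
                cfg.tree.clade_id(b): b.length for b in cfg.tree.branches
            },
            "seed": cfg.seed,
        },
        truth_events=[],
        leaf_states=leaf_states,
        root_states=root,
    )
    if cfg.injections:
        bundle = inject_inactivation(bundle, cfg.injections, cfg.tree, code, rng)
    return bundle


def _scrub_window_atg(
    rows: dict[str, list[str]],
    carriers: list[str],
    window_nt: int,
    protected: set[int] = frozenset(),
) -> None:
    """Remove every ATG the start-codon scan could see in carrier rows.

    Keeps start-codon injections unambiguous: a chance ATG downstream would
    otherwise rescue the reading frame (in frame) or mimic a displaced
    start (out of frame).  The scan is over the *ungapped* carrier sequence
    (so ATGs created across indel junctions are caught too), out to a
    margin beyond the rescue window.  One base of each offending triplet is
    replaced by C, which can neither create a stop codon (no stop contains
    C) nor a new ATG; columns in ``protected`` (injected stop codons and a
    deliberately written displaced start) are never modified.
    """
    for t in carriers:
        row = rows[t]
        limit = min(len(row), window_nt + 30)
        cols = [c for c in range(limit) if row[c] != "-"]
        for j in range(len(cols) - 2):
            triple = cols[j : j + 3]
            if [row[c] for c in triple] == ["A", "T", "G"]:
                for c in triple:
                    if c not in protected:
                        row[c] = "C"
                        break


def inject_inactivation(
    bundle: SimulatedBundle,
    injections: list[Injection],
    tree: PhyloTree,
    code: GeneticCode = STANDARD_CODE,
    rng: np.random.Generator | None = None,
    rescue_window_nt: int = 100,
) -> SimulatedBundle:
    """Apply inactivation events to a simulated alignment.

    Events are applied in position order; insertion offsets are tracked so
    each truth record carries the final 1-based alignment column the
    scanner should report, together with the expected branch assignment.
    Co-located indel injections on the same branch whose net length is a
    multiple of 3 are compensated and produce no truth event.
    """
    rng = rng or np.random.default_rng(0)
    aln = bundle.alignment
    n_nt = len(aln.rows[0])
    rows: dict[str, list[str]] = {t: list(r) for t, r in zip(aln.taxa, aln.rows)}
    all_taxa = list(aln.taxa)

    body = [i for i in injections
            if i.kind not in (MutationKind.start_loss, MutationKind.start_stop_shift)]
    starts = [i for i in injections if i not in body]

    pending: list[dict] = []
    #: (original 0-based position, inserted length) of applied insertions
    ins_log: list[tuple[int, int]] = []
    #: alignment columns that must not be touched by the ATG scrub
    protected: set[int] = set()
    offset = 0
    for inj in sorted(body, key=lambda i: i.position_nt):
        if inj.position_nt > n_nt:
            raise IndexError(
                f"injection at nt {inj.position_nt} beyond sequence length {n_nt}"
            )
        node = _resolve_branch(tree, inj.branch)
        carriers = sorted(node.leaf_names())
        col = inj.position_nt - 1 + offset  # 0-based alignment column

        if inj.kind is MutationKind.frameshift_insertion:
            insert = "".join(rng.choice(list(NUCLEOTIDES), size=inj.length_nt))
            for t in all_taxa:
                piece = insert if t in carriers else "-" * inj.length_nt
                rows[t][col:col] = list(piece)
            pending.append(
                {"kind": inj.kind, "col": col, "net": inj.length_nt,
                 "last": col + inj.length_nt - 1, "branch": tuple(carriers)}
            )
            ins_log.append((inj.position_nt - 1, inj.length_nt))
            offset += inj.length_nt

        elif inj.kind is MutationKind.frameshift_deletion:
            if inj.position_nt + inj.length_nt - 1 > n_nt:
                raise IndexError("deletion runs past the end of the sequence")
            for t in carriers:
                for c in range(col, col + inj.length_nt):
                    rows[t][c] = "-"
            pending.append(
                {"kind": inj.kind, "col": col, "net": -inj.length_nt,
                 "last": col + inj.length_nt - 1, "branch": tuple(carriers)}
            )

        else:  # premature stop
            for t in carriers:
                rows[t][col : col + 3] = list("TGA")
            protected.update(range(col, col + 3))
            pending.append(
                {"kind": inj.kind, "col": col, "net": 0, "last": col + 2,
                 "branch": tuple(carriers)}
            )

    def col_of(pos: int) -> int:
        """Alignment column of an original 0-based sequence position."""
        return pos + sum(ln for p, ln in ins_log if p <= pos)

    # start-codon events go last so the ATG scrub sees the final alignment
    for inj in starts:
        node = _resolve_branch(tree, inj.branch)
        carriers = sorted(node.leaf_names())
        col = col_of(inj.position_nt - 1)
        for t in carriers:
            rows[t][col : col + 3] = list("GTG")
        if inj.kind is MutationKind.start_stop_shift:
            atg_cols = [col_of(inj.position_nt - 1 + inj.length_nt + k) for k in range(3)]
            p0 = inj.position_nt - 1 + inj.length_nt
            for t in carriers:
                for c, base in zip(atg_cols, "ATG"):
                    rows[t][c] = base
                # the out-of-frame ATG straddles two reference codons and
                # its bases can complete an in-frame stop with the flanking
                # bases; neutralize any stop so created
                for m in (p0 // 3, (p0 + 2) // 3):
                    cods = [col_of(3 * m + k) for k in range(3)]
                    if cods[2] >= len(rows[t]):
                        continue
                    codon = "".join(rows[t][c] for c in cods)
                    if code.is_stop(codon):
                        for c in cods:
                            if c not in protected and c not in atg_cols:
                                rows[t][c] = "C"
                                break
            keep = set(atg_cols)
        else:
            keep = set()
        _scrub_window_atg(rows, carriers, rescue_window_nt, protected | keep)
        pending.append(
            {"kind": inj.kind, "col": col, "net": 0, "last": col + 2,
             "branch": tuple(carriers)}
        )

    # fold compensated co-located indels (same branch, runs within the
    # scanner's merge distance, net length a multiple of 3)
    truth: list[MutationEvent] = []
    by_branch: dict[tuple, list[dict]] = {}
    for rec in pending:
        by_branch.setdefault(rec["branch"], []).append(rec)
    for branch, recs in by_branch.items():
        recs.sort(key=lambda r: r["col"])
        merged: list[dict] = []
        for rec in recs:
            if (
                rec["kind"] in (MutationKind.frameshift_insertion, MutationKind.frameshift_deletion)
                and merged
                and merged[-1]["kind"] in (MutationKind.frameshift_insertion, MutationKind.frameshift_deletion)
                and rec["col"] - merged[-1]["last"] <= 3
            ):
                merged[-1]["net"] += rec["net"]
                merged[-1]["last"] = max(merged[-1]["last"], rec["last"])
            else:
                merged.append(dict(rec))
        for rec in merged:
            if rec["kind"] in (MutationKind.frameshift_insertion, MutationKind.frameshift_deletion):
                if rec["net"] % 3 == 0:
                    continue  # compensated: no inactivation
                kind = (
                    MutationKind.frameshift_insertion
                    if rec["net"] > 0
                    else MutationKind.frameshift_deletion
                )
                length = abs(rec["net"])
            else:
                kind = rec["kind"]
                length = 3
            truth.append(
                MutationEvent(
                    kind=kind,
                    column_start=rec["col"] + 1,
                    column_end=rec["last"] + 1,
                    length_nt=length,
                    taxa=branch,
                    branch=branch,
                )
            )
    truth.sort(key=lambda e: (e.column_start, e.kind.value, e.branch))

    new_rows = ["".join(rows[t]) for t in all_taxa]
    return SimulatedBundle(
        alignment=RawAlignment(taxa=all_taxa, rows=new_rows, frame_anchor=aln.frame_anchor),
        truth_params=bundle.truth_params,
        truth_events=truth,
        leaf_states=bundle.leaf_states,
        root_states=bundle.root_states,
    )


def random_injection_scenario(
    n_taxa: int,
    n_codons: int,
    rng: np.random.Generator,
    max_events: int = 4,
    background_omega: float = DEFAULT_BACKGROUND_OMEGA,
    kappa: float = DEFAULT_KAPPA,
) -> tuple[SimulationConfig, list[str]]:
    """Draw a random tree plus a random set of injectable inactivations.

    Returns the simulation config and the taxa guaranteed to carry no
    event (the intact reference set, always >= 2).  Injection positions
    sit on codon boundaries at least four codons apart so independent
    events cannot interact through the scanner's indel-run merging, and at
    most one start-codon event is drawn per scenario.
    """
    if n_taxa < 5:
        raise ValueError("scenarios need >= 5 taxa to keep 2 intact references")
    tree = random_tree(n_taxa, rng)
    leaves = set(tree.leaves)
    candidates = [
        b for b in tree.branches if len(b.leaf_names()) <= n_taxa - 2
    ]
    n_events = int(rng.integers(1, max_events + 1))
    rng.shuffle(candidates)
    chosen: list[Node] = []
    carriers: set[str] = set()
    for b in candidates:
        extra = carriers | set(b.leaf_names())
        if len(leaves - extra) >= 2:
            chosen.append(b)
            carriers = extra
        if len(chosen) == n_events:
            break

    body_kinds = [
        MutationKind.premature_stop,
        MutationKind.frameshift_insertion,
        MutationKind.frameshift_deletion,
    ]
    start_kinds = [MutationKind.start_loss, MutationKind.start_stop_shift]
    # distinct codon-boundary positions, >= 4 codons apart, clear of both
    # ends and of the start-displacement region scanned by rule (d)
    slots = list(range(8, n_codons - 4, 4))
    rng.shuffle(slots)
    injections: list[Injection] = []
    start_used = False
    for b in chosen:
        clade = tuple(sorted(b.leaf_names()))
        use_start = (not start_used) and rng.random() < 0.25
        if use_start:
            start_used = True
            kind = start_kinds[int(rng.integers(len(start_kinds)))]
            length = 3 if kind is MutationKind.start_loss else int(rng.choice([16, 17]))
            injections.append(
                Injection(branch=clade, kind=kind, position_nt=1, length_nt=length)
            )
            continue
        kind = body_kinds[int(rng.integers(len(body_kinds)))]
        pos = 3 * slots.pop() + 1
        if kind is MutationKind.premature_stop:
            length = 3
        else:
            length = int(rng.choice([1, 2, 4, 5]))
        injections.append(
            Injection(branch=clade, kind=kind, position_nt=pos, length_nt=length)
        )

    cfg = SimulationConfig(
        tree=tree,
        omega_by_category={0: background_omega},
        kappa=kappa,
        n_codons=n_codons,
        seed=int(rng.integers(2**31 - 1)),
        injections=injections,
    )
    references = sorted(leaves - carriers)
    return cfg, references


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    mean_length: float = 0.15,
    prefix: str = "t",
) -> PhyloTree:
    """Random bifurcating tree with exponential branch lengths.

    A convenience for simulation studies and property tests; taxa are
    labelled ``t1..tN`` and every branch starts in category 0.
    """
    nodes = [Node(name=f"{prefix}{i + 1}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = PhyloTree(nodes[0])
    for b in tree.branches:
        b.length = float(rng.exponential(mean_length)) + 0.01
    return tree
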