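"""End-to-end analysis: scan -> classify -> map -> per-clade model fits.

The pipeline reads an aligned FASTA and a Newick species tree, scans every
taxon for inactivating mutations against a reference (intact) set, maps
shared events onto tree branches, and then, for each configured clade,
subsets the alignment and tree, fits the one-ratio null and the branch
model with the configured foreground categories, and reports omega
estimates with the likelihood-ratio test of relaxed selection.  Optional
extras per clade: the free-ratio exploratory screen and the branch-site
positive-selection test.

Configuration is a YAML/dict structure; outputs are a TSV report, a TSV
mutation-event table, and a JSON run manifest sufficient to rerun the
analysis bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (
    CleaningPolicy,
    CodonAlignment,
    RawAlignment,
    clean_alignment,
    read_fasta_alignment,
)
from .codon_model import FrequencyScheme
from .genetics import STANDARD_CODE, GeneticCode
from .inactivation import (
    GeneStatus,
    MutationEvent,
    classify_status,
    map_events_to_branches,
    scan_sequence,
)
from .selection import (
    CodonModelSpec,
    FitResult,
    LRTResult,
    ModelFamily,
    fit_branch_site,
    fit_free_ratio,
    fit_model,
    likelihood_ratio_test,
    select_frequency_model,
)
from .trees import PhyloTree

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class CladeConfig:
    """One foreground/background contrast.

    ``categories`` maps omega-category index (>= 1) to the taxa assigned to
    it; a plain ``foreground`` list is shorthand for ``{1: foreground}``.
    ``background`` is an explicit taxon list or ``"auto"``, meaning every
    intact-status taxon not in a foreground category.
    """

    name: str
    categories: dict[int, list[str]]
    background: list[str] | str = "auto"
    gene: str = ""
    clade_inclusive: bool = True
    branch_site: bool = False
    free_ratio: bool = False

    @classmethod
    def from_dict(cls, d: dict, gene: str = "") -> "CladeConfig":
        d = dict(d)
        if "foreground" in d and "categories" in d:
            raise ConfigurationError(
                f"clade {d.get('name')!r}: give foreground or categories, not both"
            )
        if "foreground" in d:
            cats = {1: list(d.pop("foreground"))}
        else:
            cats = {int(k): list(v) for k, v in d.pop("categories", {}).items()}
        if not cats or any(k < 1 for k in cats):
            raise ConfigurationError(
                f"clade {d.get('name')!r}: foreground categories must be numbered from 1"
            )
        fg_all = [t for taxa in cats.values() for t in taxa]
        if len(set(fg_all)) != len(fg_all):
            raise ConfigurationError(
                f"clade {d.get('name')!r}: a taxon appears in two foreground categories"
            )
        return cls(
            name=d["name"],
            categories=cats,
            background=d.get("background", "auto"),
            gene=d.get("gene", gene),
            clade_inclusive=bool(d.get("clade_inclusive", True)),
            branch_site=bool(d.get("branch_site", False)),
            free_ratio=bool(d.get("free_ratio", False)),
        )

    @property
    def foreground_taxa(self) -> list[str]:
        return [t for taxa in self.categories.values() for t in taxa]


@dataclass
class ReportRow:
    clade: str
    gene: str
    scheme: str
    foreground_omega: dict[int, float]
    background_omega: float
    lnl_null: float
    lnl_alt: float
    lrt: LRTResult
    n_foreground: int
    n_background: int
    branch_site_p: float | None = None
    free_ratio_flagged: list = field(default_factory=list)

    def as_dict(self) -> dict:
        fg = ";".join(f"{k}:{v:.4g}" for k, v in sorted(self.foreground_omega.items()))
        return {
            "clade": self.clade,
            "gene": self.gene,
            "scheme": self.scheme,
            "foreground_omega": fg,
            "background_omega": f"{self.background_omega:.4g}",
            "lnL_null": f"{self.lnl_null:.6f}",
            "lnL_alt": f"{self.lnl_alt:.6f}",
            "lrt_stat": f"{self.lrt.stat:.6f}",
            "lrt_df": self.lrt.df,
            "lrt_p": f"{self.lrt.p_value:.6g}",
            "n_foreground": self.n_foreground,
            "n_background": self.n_background,
            "branch_site_p": "" if self.branch_site_p is None else f"{self.branch_site_p:.6g}",
            "free_ratio_flagged": ";".join(
                "|".join(b) if isinstance(b, tuple) else str(b)
                for b in self.free_ratio_flagged
            ),
        }


@dataclass
class PipelineResult:
    statuses: list[GeneStatus]
    events: list[MutationEvent]
    rows: list[ReportRow]
    scheme: FrequencyScheme
    manifest: dict


def subset_alignment(
    raw: RawAlignment,
    tree: PhyloTree,
    clade: CladeConfig,
    background: list[str],
    code: GeneticCode = STANDARD_CODE,
    policy: CleaningPolicy | None = None,
) -> tuple[CodonAlignment, PhyloTree]:
    """Restrict alignment and tree to one clade's foreground + background.

    The alignment is re-cleaned for the active subset; the pruned tree gets
    the clade's omega-category labels (foreground terminal branches plus,
    when ``clade_inclusive``, all internal branches of a pure foreground
    clade, including its stem).
    """
    fg = clade.foreground_taxa
    if not fg:
        raise ConfigurationError(f"clade {clade.name!r}: empty foreground")
    overlap = set(fg) & set(background)
    if overlap:
        raise ConfigurationError(
            f"clade {clade.name!r}: foreground and background overlap: {sorted(overlap)}"
        )
    active = fg + [t for t in background if t not in fg]
    missing = set(active) - set(raw.taxa)
    if missing:
        raise ConfigurationError(
            f"clade {clade.name!r}: taxa not in alignment: {sorted(missing)}"
        )
    base_policy = policy or CleaningPolicy()
    sub_policy = CleaningPolicy(
        minor_insertion_fraction=base_policy.minor_insertion_fraction,
        active_taxa=active,
    )
    codon_aln, _ = clean_alignment(raw, code, sub_policy)
    pruned = tree.prune_to(active)
    pruned.set_categories(reset=True)
    for cat, taxa in sorted(clade.categories.items()):
        pruned.set_categories(
            foreground=taxa, category=cat, clade_inclusive=clade.clade_inclusive
        )
    pruned.validate_categories()
    return codon_aln, pruned


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def detect_reference_taxa(
    raw: RawAlignment, code: GeneticCode, rescue_window_nt: int = 100
) -> list[str]:
    """Auto-detect intact reference taxa by a two-pass scan.

    First pass scans every taxon against the consensus of all taxa; taxa
    with no events seed the reference set, which is then used to rescan.
    """
    candidates = []
    for t in raw.taxa:
        refs = [x for x in raw.taxa if x != t]
        if not scan_sequence(raw, t, refs, code, rescue_window_nt):
            candidates.append(t)
    if len(candidates) < 2:
        raise ConfigurationError(
            "auto reference detection found fewer than 2 intact taxa"
        )
    refined = [
        t for t in candidates
        if not scan_sequence(raw, t, [x for x in candidates if x != t], code, rescue_window_nt)
    ]
    return refined if len(refined) >= 2 else candidates


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> PipelineResult:
    """Execute the full analysis described by a configuration mapping.

    Writes ``report.tsv``, ``mutations.tsv`` and ``manifest.json`` under
    ``outdir`` and returns the in-memory results.
    """
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene = cfg.get("gene", "gene")
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    rescue = int(cfg.get("rescue_window_nt", 100))
    policy = CleaningPolicy(
        minor_insertion_fraction=float(cfg.get("minor_insertion_fraction", 0.10))
    )
    estimate_bl = bool(cfg.get("estimate_branch_lengths", True))
    n_restarts = int(cfg.get("n_restarts", 3))

    aln_path = Path(cfg["alignment"])
    tree_path = Path(cfg["tree"])
    raw = read_fasta_alignment(aln_path)
    raw.frame_anchor = int(cfg.get("frame_anchor", 1))
    tree = PhyloTree.read(tree_path)

    shared = [t for t in raw.taxa if t in set(tree.leaves)]
    dropped = [t for t in raw.taxa if t not in set(tree.leaves)]
    if dropped:
        logger.warning("dropping %d taxa absent from the tree: %s", len(dropped), dropped)
        raw = raw.subset(shared)
    tree = tree.prune_to(shared)

    # --- stage 1: scan, classify, map ---------------------------------
    ref_cfg = cfg.get("reference_taxa", "auto")
    if ref_cfg == "auto":
        references = detect_reference_taxa(raw, code, rescue)
        logger.info("auto-detected %d reference taxa", len(references))
    else:
        references = list(ref_cfg)
        missing = set(references) - set(raw.taxa)
        if missing:
            raise ConfigurationError(f"reference taxa not in alignment: {sorted(missing)}")
    statuses = [
        classify_status(t, scan_sequence(raw, t, references, code, rescue))
        for t in raw.taxa
    ]
    events = map_events_to_branches(statuses, tree)
    intact = [s.taxon for s in statuses if s.status == "intact"]

    # --- stage 2: frequency-model selection ----------------------------
    scheme_cfg = cfg.get("frequency_scheme", "CF0")
    if scheme_cfg == "auto":
        intact_policy = CleaningPolicy(
            minor_insertion_fraction=policy.minor_insertion_fraction,
            active_taxa=intact,
        )
        intact_aln, _ = clean_alignment(raw, code, intact_policy)
        intact_tree = tree.prune_to(intact)
        ranked = select_frequency_model(
            intact_aln, intact_tree, seed=seed,
            estimate_branch_lengths=estimate_bl, n_restarts=max(1, n_restarts - 1),
        )
        scheme = ranked[0].spec.freq_scheme
        logger.info("AIC selected frequency scheme %s", scheme.value)
    else:
        scheme = FrequencyScheme(scheme_cfg)

    # --- stage 3: per-clade fits ---------------------------------------
    rows: list[ReportRow] = []
    clade_cfgs = [CladeConfig.from_dict(c, gene) for c in cfg.get("clades", [])]
    for ci, clade in enumerate(clade_cfgs):
        clade_seed = seed + 1000 * (ci + 1)
        background = (
            [t for t in intact if t not in set(clade.foreground_taxa)]
            if clade.background == "auto"
            else list(clade.background)
        )
        if not background:
            raise ConfigurationError(f"clade {clade.name!r}: empty background")
        sub_aln, sub_tree = subset_alignment(raw, tree, clade, background, code, policy)
        if not estimate_bl and any(b.length is None for b in sub_tree.branches):
            raise ConfigurationError(
                "estimate_branch_lengths=false but the tree lacks branch lengths"
            )
        null_spec = CodonModelSpec(
            family=ModelFamily.one_ratio, freq_scheme=scheme,
            estimate_branch_lengths=estimate_bl, n_restarts=n_restarts,
        )
        alt_spec = CodonModelSpec(
            family=ModelFamily.branch, freq_scheme=scheme,
            estimate_branch_lengths=estimate_bl, n_restarts=n_restarts,
        )
        null_fit = fit_model(sub_aln, sub_tree, null_spec, seed=clade_seed)
        alt_fit = fit_model(sub_aln, sub_tree, alt_spec, seed=clade_seed + 1)
        lrt = likelihood_ratio_test(null_fit, alt_fit)
        alt_omegas = alt_fit.omega_report()
        row = ReportRow(
            clade=clade.name,
            gene=clade.gene or gene,
            scheme=scheme.value,
            foreground_omega={k: v for k, v in alt_omegas.items() if k != 0},
            background_omega=alt_omegas[0],
            lnl_null=null_fit.lnL,
            lnl_alt=alt_fit.lnL,
            lrt=lrt,
            n_foreground=len(clade.foreground_taxa),
            n_background=len(background),
        )
        if clade.branch_site:
            if len(clade.categories) != 1:
                logger.warning(
                    "clade %s: branch-site test needs exactly one foreground "
                    "category, skipping", clade.name,
                )
            else:
                bs_null = fit_branch_site(
                    sub_aln, sub_tree, alternative=False, seed=clade_seed + 2,
                    freq_scheme=scheme, estimate_branch_lengths=estimate_bl,
                    n_restarts=n_restarts,
                )
                bs_alt = fit_branch_site(
                    sub_aln, sub_tree, alternative=True, seed=clade_seed + 3,
                    freq_scheme=scheme, estimate_branch_lengths=estimate_bl,
                    n_restarts=n_restarts,
                )
                row.branch_site_p = likelihood_ratio_test(bs_null, bs_alt).p_value
        if clade.free_ratio:
            fr = fit_free_ratio(
                sub_aln, sub_tree, seed=clade_seed + 4, freq_scheme=scheme,
                estimate_branch_lengths=estimate_bl, n_restarts=max(1, n_restarts - 1),
            )
            row.free_ratio_flagged = fr.flagged_branches
        rows.append(row)
        logger.info(
            "clade %s: fg omega %s, bg omega %.3f, LRT p=%.3g",
            clade.name, row.foreground_omega, row.background_omega, lrt.p_value,
        )

    # --- stage 4: outputs ----------------------------------------------
    report_df = pd.DataFrame([r.as_dict() for r in rows], columns=list(
        ReportRow(
            clade="", gene="", scheme="", foreground_omega={}, background_omega=0.0,
            lnl_null=0.0, lnl_alt=0.0,
            lrt=LRTResult(0.0, 1, 1.0), n_foreground=0, n_background=0,
        ).as_dict()
    ))
    report_df.to_csv(outdir / "report.tsv", sep="\t", index=False)

    mut_rows = [
        {
            "kind": e.kind.value,
            "column_start": e.column_start,
            "column_end": e.column_end,
            "length_nt": e.length_nt,
            "taxa": ";".join(e.taxa),
            "branch": ";".join(e.branch),
        }
        for e in events
    ]
    pd.DataFrame(
        mut_rows,
        columns=["kind", "column_start", "column_end", "length_nt", "taxa", "branch"],
    ).to_csv(outdir / "mutations.tsv", sep="\t", index=False)

    status_rows = [
        {"taxon": s.taxon, "status": s.status, "putative": s.putative,
         "n_events": len(s.events)}
        for s in statuses
    ]
    pd.DataFrame(status_rows).to_csv(outdir / "status.tsv", sep="\t", index=False)

    manifest = {
        "package": "omegascan",
        "version": __version__,
        "seed": seed,
        "inputs": {
            "alignment": {"path": str(aln_path), "sha256": _sha256(aln_path)},
            "tree": {"path": str(tree_path), "sha256": _sha256(tree_path)},
        },
        "config": {k: v for k, v in cfg.items() if k not in ("alignment", "tree")},
        "frequency_scheme": scheme.value,
        "reference_taxa": references,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(
        statuses=statuses, events=events, rows=rows, scheme=scheme, manifest=manifest
    )
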