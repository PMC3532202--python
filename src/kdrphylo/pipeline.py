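"""End-to-end orchestration: classify -> matrix prep -> model selection ->
ML search + bootstrap -> SOWH monophyly test -> origin counting.

The unit of phylogenetic analysis is the *unique haplotype*: input
sequences are classified and named first, duplicates collapse onto one
representative, and the tree is built over haplotype names.  Every number
in the report is recomputable from config + inputs + seeds; the provenance
block echoes all applied defaults.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .haplotypes import (
    FragmentLayout,
    HaplotypeCatalog,
    RESISTANT_CLASSES,
    assign_names,
    build_record,
)
from .origins import OriginReport, derive_sequential_pairs, origin_report
from .phylo_models import (
    Alignment,
    AlignmentError,
    DEFAULT_CANDIDATES,
    ModelFit,
    select_model_bic,
)
from .sowh import SOWHResult, sowh_test
from .tree_search import (
    ConstraintSpec,
    SearchConfig,
    bootstrap_support,
    midpoint_root,
    ml_search,
)
from .trees import PhyloTree


logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage, exc):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage
        self.cause = exc


@dataclass
class RunConfig:
    """Configuration of one full analysis run (defaults: 20 search
    replicates, 100 bootstrap replicates with 2 search replicates each,
    100 SOWH replicates)."""

    fasta: str | None = None
    layout: FragmentLayout | None = None
    matrix: str = "full"                # "full" or "strict"
    ambiguous_columns: tuple = ()       # columns excluded by the strict mask
    candidates: tuple = DEFAULT_CANDIDATES
    search_reps: int = 20
    bootstrap_reps: int = 100
    bootstrap_search_reps: int = 2
    sowh_reps: int = 100
    sowh_search_reps: int = 2
    seed: int = 0
    outdir: str = "kdrphylo_out"

    def __post_init__(self):
        if self.matrix not in ("full", "strict"):
            raise ValueError("matrix must be 'full' or 'strict'")
        for name in ("search_reps", "bootstrap_reps", "sowh_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "layout" in raw and raw["layout"] is not None:
            raw["layout"] = FragmentLayout(**raw["layout"])
        if "ambiguous_columns" in raw and raw["ambiguous_columns"] is not None:
            raw["ambiguous_columns"] = tuple(raw["ambiguous_columns"])
        return cls(**raw)

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        d["layout"] = dataclasses.asdict(self.layout) if self.layout else None
        d["candidates"] = [list(c) for c in self.candidates]
        d["ambiguous_columns"] = list(self.ambiguous_columns)
        d["version"] = __version__
        return d


@dataclass
class RunReport:
    """Machine-readable outcome of :func:`run_full_analysis`."""

    provenance: dict
    catalog: HaplotypeCatalog
    model_fit: ModelFit
    bic_table: list
    best_tree: PhyloTree
    best_lnl: float
    support: dict                    # bipartition frozenset -> percent
    display_tree_newick: str
    sowh: SOWHResult | None
    sowh_note: str | None
    origins: OriginReport
    sequential_pairs: list
    tip_classes: dict

    def to_json_dict(self) -> dict:
        m = self.model_fit.model
        sowh = None
        if self.sowh is not None:
            sowh = {
                "observed_delta": self.sowh.observed_delta,
                "lnl_best": self.sowh.lnl_best,
                "lnl_constrained": self.sowh.lnl_constrained,
                "p_value": self.sowh.p_value,
                "p_display": self.sowh.p_display,
                "p_is_bound": self.sowh.p_is_bound,
                "corrected_p": self.sowh.corrected_p,
                "n_reps": self.sowh.n_reps,
                "replicate_deltas": [float(d) for d in self.sowh.replicate_deltas],
            }
        return {
            "provenance": self.provenance,
            "catalog": [
                {
                    "name": e.name,
                    "label": e.label,
                    "class": e.allele_class,
                    "aa918": e.aa918,
                    "aa1014": e.aa1014,
                }
                for e in self.catalog
            ],
            "intron_groups": self.catalog.intron_groups(),
            "sequential_pairs": [[a, list(b)] for a, b in self.sequential_pairs],
            "model": {
                "family": m.family,
                "freqs": list(m.freqs),
                "kappa": m.kappa,
                "rel_rates": list(m.rel_rates),
                "alpha": m.alpha,
                "lnl": self.model_fit.lnl,
                "bic": self.model_fit.bic,
            },
            "bic_table": self.bic_table,
            "best_tree": self.best_tree.to_newick(),
            "best_lnl": self.best_lnl,
            "support": sorted(
                [sorted(bp), pct] for bp, pct in self.support.items()
            ),
            "display_tree": self.display_tree_newick,
            "sowh": sowh,
            "sowh_note": self.sowh_note,
            "origins": {
                "clade_counts": self.origins.clade_counts,
                "clades": {
                    c: [sorted(s) for s in v] for c, v in self.origins.clades.items()
                },
                "gains": {
                    c: dataclasses.asdict(g) for c, g in self.origins.gains.items()
                },
                "root_sensitivity": {
                    c: list(v) for c, v in self.origins.root_sensitivity.items()
                },
            },
            "tip_classes": dict(sorted(self.tip_classes.items())),
        }


def _annotated_display_tree(
    best_tree: PhyloTree, support: dict, min_show: float = 50.0
) -> str:
    """Midpoint-rooted Newick with bootstrap percentages above ``min_show``
    as internal-node labels (the usual majority-support display convention)."""
    ref = min(best_tree.taxa)
    dtree = midpoint_root(best_tree)
    all_taxa = set(best_tree.taxa)
    for nd in dtree.postorder_internal_node_iter():
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        key = frozenset(all_taxa - leaves) if ref in leaves else leaves
        pct = support.get(key)
        if pct is not None and pct > min_show:
            nd.label = f"{pct:.0f}"
    return dtree.as_string(schema="newick", suppress_rooting=True).strip()


def run_full_analysis(
    config: RunConfig,
    alignment: Alignment | None = None,
    search_config: SearchConfig | None = None,
) -> RunReport:
    """Execute all stages in order; any stage failure aborts with a
    stage-tagged :class:`StageError`.  ``alignment`` may be passed directly
    (e.g. from the synthetic generator) instead of ``config.fasta``."""
    rng = np.random.default_rng(config.seed)

    def stage(name, fn):
        logger.info("stage %s: start", name)
        try:
            out = fn()
            logger.info("stage %s: done", name)
            return out
        except Exception as e:  # noqa: BLE001 - stage tagging is the point
            raise StageError(name, e) from e

    def load():
        if alignment is not None:
            return alignment
        if config.fasta is None:
            raise AlignmentError("no input alignment (fasta or in-memory)")
        return Alignment.from_fasta(config.fasta)

    aln_in = stage("input", load)
    if config.layout is None:
        raise StageError("input", ValueError("config.layout is required"))

    def classify():
        records = [
            build_record(t, s, config.layout)
            for t, s in zip(aln_in.taxa, aln_in.sequences)
        ]
        catalog = HaplotypeCatalog()
        assign_names(records, catalog)
        return records, catalog

    records, catalog = stage("classify", classify)

    def build_matrix():
        # one row per unique haplotype; mask by matrix choice
        mask = np.ones(aln_in.n_sites, bool)
        if config.matrix == "strict":
            cols = np.asarray(config.ambiguous_columns, int)
            if cols.size:
                mask[cols] = False
        return Alignment(
            [e.name for e in catalog],
            [e.sequence for e in catalog],
            mask,
        )

    aln = stage("matrix", build_matrix)
    tip_classes = {e.name: e.allele_class for e in catalog}

    fit = stage(
        "model_selection",
        lambda: select_model_bic(aln, config.candidates),
    )
    bic_table = [
        {"family": fam, "gamma": g} for fam, g in config.candidates
    ]

    res = stage(
        "ml_search",
        lambda: ml_search(
            aln,
            fit.model,
            n_replicates=config.search_reps,
            seed=int(rng.integers(2**31)),
            config=search_config,
        ),
    )

    support = stage(
        "bootstrap",
        lambda: bootstrap_support(
            aln,
            fit.model,
            n_boot=config.bootstrap_reps,
            search_reps_per_boot=config.bootstrap_search_reps,
            seed=int(rng.integers(2**31)),
            focal_tree=res.best_tree,
            config=search_config,
        ),
    )

    resistant = frozenset(
        n for n, c in tip_classes.items() if c in RESISTANT_CLASSES
    )
    sowh_res, sowh_note = None, None
    if not resistant:
        sowh_note = "no resistant haplotypes; monophyly test not applicable"
    elif len(resistant) == len(catalog):
        sowh_note = "all haplotypes resistant; monophyly test not applicable"
    else:
        sowh_res = stage(
            "sowh",
            lambda: sowh_test(
                aln,
                fit.model,
                ConstraintSpec(resistant),
                n_reps=config.sowh_reps,
                seed=int(rng.integers(2**31)),
                search_reps=config.sowh_search_reps,
                observed_search_reps=config.search_reps,
                config=search_config,
            ),
        )

    def origins_stage():
        rooted = midpoint_root(res.best_tree)
        return origin_report(rooted, res.best_tree, tip_classes)

    origins = stage("origins", origins_stage)
    display = stage(
        "display", lambda: _annotated_display_tree(res.best_tree, support)
    )

    return RunReport(
        provenance=config.provenance(),
        catalog=catalog,
        model_fit=fit,
        bic_table=bic_table,
        best_tree=res.best_tree,
        best_lnl=res.best_lnl,
        support=support,
        display_tree_newick=display,
        sowh=sowh_res,
        sowh_note=sowh_note,
        origins=origins,
        sequential_pairs=derive_sequential_pairs(catalog),
        tip_classes=tip_classes,
    )


def write_report(report: RunReport, outdir) -> list:
    """Write the report artifacts (Newick, FASTA, TSV, JSON); deterministic
    byte-wise given the report.  Returns the written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(name, text):
        p = out / name
        p.write_text(text)
        written.append(p)

    emit("report.json", json.dumps(report.to_json_dict(), indent=2, sort_keys=True))
    report.catalog.to_tsv(out / "catalog.tsv")
    written.append(out / "catalog.tsv")
    report.catalog.unique_haplotypes_fasta(out / "haplotypes.fasta")
    written.append(out / "haplotypes.fasta")
    emit("best_tree.nwk", report.best_tree.to_newick() + "\n")
    emit("display_tree.nwk", report.display_tree_newick + "\n")
    lines = ["bipartition\tsupport_pct"]
    for bp, pct in sorted(
        report.support.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
    ):
        lines.append(",".join(sorted(bp)) + f"\t{pct:.1f}")
    emit("bootstrap.tsv", "\n".join(lines) + "\n")
    lines = ["class\tclade_count\tmin_gains\troot_min\troot_max"]
    for cls, k in report.origins.clade_counts.items():
        g = report.origins.gains[cls]
        lo, hi = report.origins.root_sensitivity[cls]
        lines.append(f"{cls}\t{k}\t{g.gains}\t{lo}\t{hi}")
    emit("origins.tsv", "\n".join(lines) + "\n")
    if report.sowh is not None:
        emit(
            "sowh.json",
            json.dumps(report.to_json_dict()["sowh"], indent=2, sort_keys=True),
        )
    return written
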