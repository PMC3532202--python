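"""Synthetic Vssc-like data with planted resistance origins.

Generates the inputs the rest of the pipeline consumes: a Yule genealogy, a
scenario that plants 1..k independent origins of each resistance class on
its branches (super-kdr only ever arising on a kdr background, mirroring
the sequential-evolution model), and an intron+exon alignment shaped like
the ~350 bp fragment around codon 1014: a hypervariable neutral intron, a
conserved exon evolving at a reduced rate, deterministic codon states at
918/1014 given the tip's class, and a configurable fraction of intron
columns flagged alignment-ambiguous (the "strict" matrix excludes them).

Defaults (64 taxa, 350 sites of which 250 are intron, tree height 0.15
substitutions/site, AT-rich HKY with kappa 3) are the package's standard
study conditions; see docs/methods.md for the rationale.
"""
from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np

from .haplotypes import FragmentLayout, RESISTANT_CLASSES
from .origins import count_maximal_clades
from .phylo_models import Alignment, SubstModel, simulate_alignment
from .trees import PhyloTree


class ScenarioError(ValueError):
    pass


# codon written at 918/1014 for each allele class (deterministic by default
# so that classification truth is unambiguous)
CLASS_CODONS = {
    "susceptible": ("ATG", "TTA"),  # M918, L1014
    "kdr": ("ATG", "TTT"),          # M918, F1014
    "kdr-his": ("ATG", "CAT"),      # M918, H1014
    "super-kdr": ("ACG", "TTT"),    # T918, F1014
}

DEFAULT_MODEL = SubstModel(
    family="HKY85", freqs=(0.35, 0.15, 0.15, 0.35), kappa=3.0
)
DEFAULT_N_TAXA = 64
DEFAULT_N_SITES = 350
DEFAULT_TREE_HEIGHT = 0.15
DEFAULT_EXON_RATE = 0.1
DEFAULT_AMBIGUOUS_FRACTION = 0.1


def default_layout(n_sites: int = DEFAULT_N_SITES) -> FragmentLayout:
    """350-column fragment: exon with codons 918/1014, then a 250-column
    intron starting one codon downstream of 1014, then a short exon tail."""
    if n_sites < 120:
        raise ScenarioError("fragment too short for the default geometry")
    intron_end = n_sites - 3
    return FragmentLayout(
        codon1014_offset=91,
        intron_start=97,
        intron_end=intron_end,
        codon918_offset=30,
        canonical_geometry=True,
    )


def simulate_rooted_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    height: float = DEFAULT_TREE_HEIGHT,
) -> dendropy.Tree:
    """Pure-birth (Yule) genealogy, branch lengths rescaled so the maximum
    root-to-tip distance equals ``height``; deterministic given the seed."""
    if n_taxa < 4:
        raise ScenarioError("n_taxa must be >= 4")
    from dendropy.model.birthdeath import birth_death_tree

    tree = birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(int(seed)),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1:03d}"
    tree.seed_node.edge.length = 0.0
    depth = max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
    scale = height / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    height: float = DEFAULT_TREE_HEIGHT,
) -> PhyloTree:
    """Unrooted view of :func:`simulate_rooted_tree`."""
    return PhyloTree.from_dendropy(
        simulate_rooted_tree(n_taxa, birth_rate, seed, height)
    )


@dataclass
class SimScenario:
    """A planted-origins simulation design.

    ``origin_edges`` maps allele class to the list of tip sets of the
    subtrees where gains occurred; every tip's class is determined by the
    innermost origin above it (super-kdr origins nest strictly inside kdr
    origin subtrees).
    """

    rooted: dendropy.Tree
    tree: PhyloTree
    model: SubstModel
    layout: FragmentLayout
    tip_classes: dict
    origin_edges: dict
    requested: dict
    realized: dict
    n_taxa: int
    n_sites: int
    seed: int

    @property
    def resistant_taxa(self) -> frozenset:
        return frozenset(
            t for t, c in self.tip_classes.items() if c in RESISTANT_CLASSES
        )


def plant_origins(
    rooted: dendropy.Tree,
    k_kdr: int = 0,
    k_kdrhis: int = 0,
    k_superkdr: int = 0,
    seed: int = 0,
    max_tries: int = 500,
) -> dict:
    """Sample origin branches for each class subject to the nesting rules.

    kdr and kdr-his origins are mutually non-nested; each super-kdr origin
    lies strictly inside a kdr origin subtree (sequential evolution).  The
    assignment is rejected and resampled until the realized number of
    maximal clades per class equals the request and at least one
    susceptible tip remains.

    Returns ``{"tip_classes": ..., "origin_edges": ..., "realized": ...}``.
    """
    if k_superkdr > 0 and k_kdr == 0:
        raise ScenarioError("super-kdr origins require at least one kdr origin")
    if min(k_kdr, k_kdrhis, k_superkdr) < 0:
        raise ScenarioError("origin counts must be >= 0")
    rng = random.Random(int(seed))
    nodes = [nd for nd in rooted.preorder_node_iter() if nd.parent_node is not None]
    n_tips = len(rooted.leaf_nodes())

    def descendants(nd):
        return set(nd.preorder_iter())

    for _ in range(max_tries):
        pool = list(nodes)
        rng.shuffle(pool)
        kdr_nodes, his_nodes, sk_nodes = [], [], []
        used = set()

        def non_nested(nd, chosen):
            return all(
                nd not in descendants(c) and c not in descendants(nd)
                for c in chosen
            )

        for nd in pool:
            if len(kdr_nodes) < k_kdr and non_nested(nd, kdr_nodes + his_nodes):
                kdr_nodes.append(nd)
            elif len(his_nodes) < k_kdrhis and non_nested(
                nd, kdr_nodes + his_nodes
            ):
                his_nodes.append(nd)
        if len(kdr_nodes) < k_kdr or len(his_nodes) < k_kdrhis:
            continue
        ok = True
        for _ in range(k_superkdr):
            cands = [
                nd
                for k in kdr_nodes
                for nd in descendants(k)
                if nd is not k and nd.parent_node is not None
                and non_nested(nd, sk_nodes)
            ]
            if not cands:
                ok = False
                break
            sk_nodes.append(rng.choice(cands))
        if not ok:
            continue

        origin_of = {}
        for nd in kdr_nodes:
            origin_of[nd] = "kdr"
        for nd in his_nodes:
            origin_of[nd] = "kdr-his"
        for nd in sk_nodes:
            origin_of[nd] = "super-kdr"
        cls = {}
        state = {rooted.seed_node: "susceptible"}
        for nd in rooted.preorder_node_iter():
            if nd.parent_node is not None:
                state[nd] = origin_of.get(nd, state[nd.parent_node])
            if nd.is_leaf():
                cls[nd.taxon.label] = state[nd]

        realized = {}
        good = True
        for c, want in (
            ("kdr", k_kdr),
            ("kdr-his", k_kdrhis),
            ("super-kdr", k_superkdr),
        ):
            realized[c], _ = count_maximal_clades(rooted, cls, c)
            if realized[c] != want:
                good = False
        n_susc = sum(1 for v in cls.values() if v == "susceptible")
        if not good or n_susc == 0:
            continue
        origin_edges = {
            c: sorted(
                frozenset(lf.taxon.label for lf in nd.leaf_iter())
                for nd in group
            )
            for c, group in (
                ("kdr", kdr_nodes),
                ("kdr-his", his_nodes),
                ("super-kdr", sk_nodes),
            )
        }
        return {
            "tip_classes": cls,
            "origin_edges": origin_edges,
            "realized": realized,
        }
    raise ScenarioError(
        f"could not place origins (kdr={k_kdr}, kdr-his={k_kdrhis}, "
        f"super-kdr={k_superkdr}) on a {n_tips}-tip tree in {max_tries} tries"
    )


def make_scenario(
    n_taxa: int = DEFAULT_N_TAXA,
    n_sites: int = DEFAULT_N_SITES,
    k_kdr: int = 2,
    k_kdrhis: int = 3,
    k_superkdr: int = 2,
    seed: int = 0,
    model: SubstModel = DEFAULT_MODEL,
    tree_height: float = DEFAULT_TREE_HEIGHT,
    birth_rate: float = 1.0,
) -> SimScenario:
    """Build a full simulation design (tree + planted origins + layout).

    The default origin counts (2 kdr, 3 kdr-his, 2 super-kdr) mirror the
    multiple-origins pattern reported for the real data; use
    ``k_kdr=1, k_kdrhis=0, k_superkdr=0`` for a single-origin (null)
    scenario.
    """
    rooted = simulate_rooted_tree(n_taxa, birth_rate, seed, tree_height)
    planted = plant_origins(rooted, k_kdr, k_kdrhis, k_superkdr, seed=seed + 1)
    return SimScenario(
        rooted=rooted,
        tree=PhyloTree.from_dendropy(rooted),
        model=model,
        layout=default_layout(n_sites),
        tip_classes=planted["tip_classes"],
        origin_edges=planted["origin_edges"],
        requested={"kdr": k_kdr, "kdr-his": k_kdrhis, "super-kdr": k_superkdr},
        realized=planted["realized"],
        n_taxa=n_taxa,
        n_sites=n_sites,
        seed=seed,
    )


@dataclass
class SimulatedData:
    """Alignment plus ground truth emitted for one scenario."""

    alignment: Alignment          # full matrix (all sites included)
    strict_mask: np.ndarray       # mask excluding the ambiguous intron columns
    layout: FragmentLayout
    tip_classes: dict
    scenario: SimScenario

    def strict_alignment(self) -> Alignment:
        return Alignment(
            list(self.alignment.taxa),
            list(self.alignment.sequences),
            self.strict_mask.copy(),
        )


def simulate_vssc_alignment(
    scenario: SimScenario,
    seed: int | None = None,
    exon_rate: float = DEFAULT_EXON_RATE,
    ambiguous_fraction: float = DEFAULT_AMBIGUOUS_FRACTION,
) -> SimulatedData:
    """Simulate the intron+exon fragment for a scenario.

    Intron columns evolve under the scenario's model at the full rate; the
    other exon columns evolve with branch lengths scaled by ``exon_rate``;
    the 918/1014 codons are overwritten deterministically from each tip's
    class.  A fraction of intron columns is flagged ambiguous to mimic
    alignment-uncertain regions (column-wise, characters untouched).
    """
    if seed is None:
        seed = scenario.seed + 10_000
    rng = np.random.default_rng(int(seed))
    lay = scenario.layout
    tree = scenario.tree
    n_sites = scenario.n_sites
    n_intron = lay.intron_end - lay.intron_start

    intron = simulate_alignment(tree, scenario.model, n_intron, seed=None, rng=rng)
    slow = tree.copy()
    for k in slow.lengths:
        slow.lengths[k] *= exon_rate
    exon = simulate_alignment(
        slow, scenario.model, n_sites - n_intron, seed=None, rng=rng
    )

    seqs = []
    for taxon in tree.taxa:
        ei = exon.taxa.index(taxon)
        ii = intron.taxa.index(taxon)
        e = exon.sequences[ei]
        s = (
            e[: lay.intron_start]
            + intron.sequences[ii]
            + e[lay.intron_start :]
        )
        c918, c1014 = CLASS_CODONS[scenario.tip_classes[taxon]]
        s = (
            s[: lay.codon918_offset]
            + c918
            + s[lay.codon918_offset + 3 : lay.codon1014_offset]
            + c1014
            + s[lay.codon1014_offset + 3 :]
        )
        seqs.append(s)

    strict = np.ones(n_sites, bool)
    n_ambig = int(round(ambiguous_fraction * n_intron))
    if n_ambig:
        cols = rng.choice(np.arange(lay.intron_start, lay.intron_end),
                          size=n_ambig, replace=False)
        strict[cols] = False
    aln = Alignment(list(tree.taxa), seqs)
    return SimulatedData(
        alignment=aln,
        strict_mask=strict,
        layout=lay,
        tip_classes=dict(scenario.tip_classes),
        scenario=scenario,
    )
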