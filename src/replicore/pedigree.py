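"""Deterministic replicore pedigree under parity or disparity mutagenesis.

A replicore is a replication unit copied semiconservatively: each replication
yields two daughter molecules, one templated continuously (the leading-strand
copy) and one discontinuously (the lagging-strand copy). The pedigree model
tracks a single replicore over ``g`` doublings as a complete binary tree.
Mutations follow the infinite-sites convention: every new substitution hits a
previously untouched site, so a genotype is simply a set of uniquely labelled
mutation events and back-mutation cannot occur.

Two mutagenesis modes are compared at equal total mutational input
(``d`` new mutations per replication event, default 2):

* ``disparity`` - all ``d`` new mutations go to the lagging-strand daughter;
  the leading-strand daughter is an exact copy of its parent. Consequences:
  the ancestral zero-mutation genotype persists forever, and any genotype
  that ever appears is retained in all later generations.
* ``parity`` - the ``d`` mutations are split evenly, ``d/2`` to each
  daughter. Every lineage then accumulates mutations at the same steady
  rate and no genotype survives a single generation unchanged.

The model is fully deterministic: no fitness, no drift, no randomness.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Literal

import dendropy

__all__ = [
    "PedigreeNode",
    "PedigreeTree",
    "replicate",
    "grow",
    "census",
    "census_frame",
    "genotype_persistence",
    "export_newick",
    "DEFAULT_MAX_GENERATIONS",
]

Mode = Literal["parity", "disparity"]
StrandOrigin = Literal["leading", "lagging", "root"]

#: node-count guard: 2**21 - 1 nodes for a full tree of depth 20
DEFAULT_MAX_GENERATIONS = 20


@dataclass(frozen=True)
class PedigreeNode:
    """One replicore molecule in the pedigree.

    ``genotype`` is the inherited set of mutation-event labels; leading-origin
    nodes share their parent's genotype object, lagging-origin nodes carry a
    strict superset (in disparity mode).
    """

    node_id: int
    generation: int
    parent_id: int | None
    strand_origin: StrandOrigin
    genotype: frozenset[int]

    @property
    def mutation_count(self) -> int:
        return len(self.genotype)

    @property
    def new_mutations(self) -> int:
        """Mutations gained on the edge from the parent (0 for the root)."""
        return len(self.genotype) - self._parent_count

    # set by the tree builder; root defaults to its own size so new_mutations=0
    _parent_count: int = field(default=0, repr=False, compare=False)


@dataclass
class PedigreeTree:
    """Complete binary pedigree of depth ``generations``.

    Nodes are stored in heap order: node ``i`` has children ``2i+1`` (leading)
    and ``2i+2`` (lagging), so generation ``t`` occupies indices
    ``2**t - 1 .. 2**(t+1) - 2``.
    """

    mode: Mode
    d: int
    generations: int
    nodes: list[PedigreeNode]

    def nodes_at(self, generation: int) -> list[PedigreeNode]:
        if not 0 <= generation <= self.generations:
            raise ValueError(
                f"generation {generation} outside tree depth 0..{self.generations}"
            )
        lo = 2**generation - 1
        hi = 2 ** (generation + 1) - 1
        return self.nodes[lo:hi]

    @property
    def root(self) -> PedigreeNode:
        return self.nodes[0]

    def children(self, node: PedigreeNode) -> tuple[PedigreeNode, PedigreeNode] | None:
        i = 2 * node.node_id + 1
        if i + 1 < len(self.nodes):
            return self.nodes[i], self.nodes[i + 1]
        return None


def replicate(
    node: PedigreeNode,
    mode: Mode,
    d: int,
    event_allocator: Iterator[int],
) -> tuple[PedigreeNode, PedigreeNode]:
    """Semiconservative replication of one node.

    Returns ``(daughter_leading, daughter_lagging)``. In disparity mode the
    leading daughter inherits the parental genotype unchanged and the lagging
    daughter gains ``d`` fresh event labels. In parity mode each daughter
    gains ``d/2`` fresh labels (``d`` must be even); leading-daughter labels
    are drawn from the allocator before lagging-daughter labels.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if mode == "parity":
        if d % 2 != 0:
            raise ValueError(
                f"parity mode splits d evenly between the two daughters; d={d} is odd"
            )
        n_lead, n_lag = d // 2, d // 2
    elif mode == "disparity":
        n_lead, n_lag = 0, d
    else:
        raise ValueError(f"mode must be 'parity' or 'disparity', got {mode!r}")

    lead_events = frozenset(itertools.islice(event_allocator, n_lead))
    lag_events = frozenset(itertools.islice(event_allocator, n_lag))

    gen = node.generation + 1
    leading = PedigreeNode(
        node_id=2 * node.node_id + 1,
        generation=gen,
        parent_id=node.node_id,
        strand_origin="leading",
        genotype=node.genotype if not lead_events else node.genotype | lead_events,
        _parent_count=node.mutation_count,
    )
    lagging = PedigreeNode(
        node_id=2 * node.node_id + 2,
        generation=gen,
        parent_id=node.node_id,
        strand_origin="lagging",
        genotype=node.genotype | lag_events,
        _parent_count=node.mutation_count,
    )
    return leading, lagging


def grow(
    mode: Mode,
    d: int = 2,
    g: int = 5,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> PedigreeTree:
    """Grow the complete pedigree of depth ``g``.

    Deterministic: event labels 1, 2, 3, ... are allocated depth-first,
    leading daughter before lagging daughter, so two calls with identical
    arguments produce identical trees.
    """
    if g < 0:
        raise ValueError(f"g must be >= 0, got {g}")
    if g > max_generations:
        raise ValueError(
            f"g={g} exceeds the node budget (max_generations={max_generations}, "
            f"i.e. at most 2**{max_generations} genomes)"
        )

    allocator = itertools.count(1)
    nodes: list[PedigreeNode | None] = [None] * (2 ** (g + 1) - 1)
    root = PedigreeNode(
        node_id=0, generation=0, parent_id=None, strand_origin="root",
        genotype=frozenset(),
    )
    nodes[0] = root

    def descend(node: PedigreeNode) -> None:
        if node.generation == g:
            return
        leading, lagging = replicate(node, mode, d, allocator)
        nodes[leading.node_id] = leading
        nodes[lagging.node_id] = lagging
        descend(leading)
        descend(lagging)

    descend(root)
    return PedigreeTree(mode=mode, d=d, generations=g, nodes=nodes)  # type: ignore[arg-type]


def census(tree: PedigreeTree, generation: int) -> dict[int, int]:
    """Count genomes by mutation count at one generation.

    Returns ``{mutation_count: n_genomes}``; counts sum to ``2**generation``.
    """
    return dict(sorted(Counter(n.mutation_count for n in tree.nodes_at(generation)).items()))


def census_frame(tree: PedigreeTree, generations: list[int] | None = None):
    """Long-format census table over the given generations (default: all).

    Columns: ``generation, mutation_count, n_genomes`` — the TSV layout the
    CLI writes.
    """
    import pandas as pd

    if generations is None:
        generations = list(range(tree.generations + 1))
    rows = [
        (t, k, n)
        for t in generations
        for k, n in census(tree, t).items()
    ]
    return pd.DataFrame(rows, columns=["generation", "mutation_count", "n_genomes"])


def genotype_persistence(tree: PedigreeTree) -> bool:
    """True iff every genotype present at generation t is also present at t+1.

    Holds for any disparity tree (each molecule's leading daughter is an
    exact copy); fails for parity trees with d >= 2 because every daughter
    mutates, so even the ancestral genotype vanishes after generation 0.
    """
    for t in range(tree.generations):
        now = {n.genotype for n in tree.nodes_at(t)}
        nxt = {n.genotype for n in tree.nodes_at(t + 1)}
        if not now <= nxt:
            return False
    return True


def export_newick(
    tree: PedigreeTree, annotate: Literal["mutation_count", "new_mutations"] = "mutation_count"
) -> str:
    """Serialize the pedigree as a Newick string.

    Branch lengths are the number of NEW mutations on each edge (0 on every
    leading edge in disparity mode); node labels are ``n<id>_<value>`` where
    value is the chosen annotation.
    """
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def label(n: PedigreeNode) -> str:
        v = n.mutation_count if annotate == "mutation_count" else n.new_mutations
        return f"n{n.node_id}_{v}"

    def build(node: PedigreeNode, dnode: dendropy.Node) -> None:
        dnode.edge.length = node.new_mutations
        kids = tree.children(node)
        if kids is None:
            dnode.taxon = taxa.new_taxon(label(node))
        else:
            dnode.label = label(node)
            for kid in kids:
                build(kid, dnode.new_child())

    build(tree.root, dtree.seed_node)
    return dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=False,
    ).strip()
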