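"""Known-fusion catalogue and bipartite partitioning of fusion partner genes.

Fusion partner genes form a graph: each curated fusion pair (e.g. EML4–ALK)
is an edge between two gene vertices.  Because a read supporting a fusion
junction must split across *two different* partner genes, the search is
organised by 2-coloring this graph: genes are divided into two independent
sets U and V such that every known fusion pair connects U to V.  Reads are
then aligned once against each set and chiastic split signals are only
evaluated between known partners.

Curated catalogues are bipartite in practice (no odd cycles); if a
user-supplied pair list does contain an odd cycle, every gene on such a cycle
is placed in *both* sets (``dual``) so that all of its known partners remain
searchable, and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)


class FusionTableError(ValueError):
    """Malformed known-fusion pair table."""


class UnknownGeneError(KeyError):
    """Gene symbol absent from the bipartite index."""


@dataclass(frozen=True)
class FusionPair:
    """One curated fusion gene pair, 5' partner first.

    Gene identity is by symbol string; no alias resolution is attempted —
    the catalogue file controls naming, and reference FASTA records must use
    the same symbols.
    """

    gene5: str
    gene3: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("gene symbols must be non-empty")
        if self.gene5 == self.gene3:
            raise ValueError(
                f"fusion pair must join two distinct genes, got {self.gene5!r} twice"
            )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset((self.gene5, self.gene3))


@dataclass
class BipartiteIndex:
    """Two-set partition of all catalogued fusion partner genes.

    ``setU`` and ``setV`` are the two independent sets; ``dual`` holds genes
    that sit on an odd cycle and therefore belong to both sets.  ``edges``
    keeps the loaded pairs for partner lookups.
    """

    setU: set[str]
    setV: set[str]
    dual: set[str] = field(default_factory=set)
    edges: list[FusionPair] = field(default_factory=list)

    def genes(self) -> set[str]:
        return self.setU | self.setV

    def side(self, gene: str) -> str:
        """'U', 'V' or 'both' for a catalogued gene."""
        if gene in self.dual:
            return "both"
        if gene in self.setU:
            return "U"
        if gene in self.setV:
            return "V"
        raise UnknownGeneError(gene)


def load_fusion_pairs(path: str | Path) -> list[FusionPair]:
    """Load a known-fusion pair table.

    The file is TSV with at least two columns ``gene5<TAB>gene3`` and an
    optional third free-text ``source`` column; lines starting with ``#`` are
    comments.  Symbols are upper-cased; exact duplicate pairs are dropped,
    keeping file order of first occurrence.
    """
    path = Path(path)
    pairs: list[FusionPair] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FusionTableError(
                    f"{path}:{lineno}: expected at least 2 tab-separated columns "
                    f"(gene5, gene3), got {line!r}"
                )
            gene5 = fields[0].strip().upper()
            gene3 = fields[1].strip().upper()
            source = fields[2].strip() if len(fields) > 2 else ""
            key = (gene5, gene3)
            if key in seen:
                continue
            seen.add(key)
            try:
                pairs.append(FusionPair(gene5, gene3, source))
            except ValueError as exc:
                raise FusionTableError(f"{path}:{lineno}: {exc}") from exc
    if not pairs:
        logger.warning("fusion pair table %s contains no pairs", path)
    return pairs


def build_bipartition(pairs: list[FusionPair]) -> BipartiteIndex:
    """Partition fusion partner genes into two independent sets U and V.

    Each connected component is 2-colored breadth-first with neighbours
    visited in sorted order, seeded at the component's lexicographically
    smallest 5'-partner gene (falling back to the smallest gene when the
    component has none), which is placed in U — so U collects the 5' side
    where orientation allows (e.g. EML4 and NPM1 land in U, their shared
    partner ALK in V).  The result is deterministic and invariant to the
    input pair order.  Genes lying on an odd cycle (equivalently: genes of
    a non-bipartite biconnected block — every vertex of a 2-connected
    non-bipartite graph lies on an odd cycle) are placed in both sets and
    reported in ``dual``.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.gene5, p.gene3)
    five_prime = {p.gene5 for p in pairs}

    set_u: set[str] = set()
    set_v: set[str] = set()
    for component in nx.connected_components(graph):
        heads = component & five_prime
        seed = min(heads) if heads else min(component)
        # BFS parity coloring with deterministic neighbour order.
        color = {seed: 0}
        frontier = [seed]
        while frontier:
            nxt: list[str] = []
            for node in frontier:
                for nbr in sorted(graph.neighbors(node)):
                    if nbr not in color:
                        color[nbr] = color[node] ^ 1
                        nxt.append(nbr)
            frontier = nxt
        for gene, c in color.items():
            (set_u if c == 0 else set_v).add(gene)

    dual: set[str] = set()
    for block in nx.biconnected_components(graph):
        if len(block) < 3:
            continue
        if not nx.is_bipartite(graph.subgraph(block)):
            dual |= set(block)
    if dual:
        logger.warning(
            "fusion pair graph contains odd cycle(s); %d gene(s) placed in both "
            "sets: %s",
            len(dual),
            ", ".join(sorted(dual)),
        )
        set_u |= dual
        set_v |= dual

    return BipartiteIndex(setU=set_u, setV=set_v, dual=dual, edges=list(pairs))


def known_partners(index: BipartiteIndex, gene: str) -> set[str]:
    """All genes catalogued as fusion partners of ``gene``."""
    if gene not in index.genes():
        raise UnknownGeneError(f"gene {gene!r} is not in the fusion catalogue")
    partners: set[str] = set()
    for pair in index.edges:
        if pair.gene5 == gene:
            partners.add(pair.gene3)
        elif pair.gene3 == gene:
            partners.add(pair.gene5)
    return partners
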