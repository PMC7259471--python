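"""Benchmark metrics: match calls to a truth set, compute precision/recall/F.

precision = TP/(TP+FP), recall = TP/(TP+FN),
F = 2 * precision * recall / (precision + recall).

Benchmark mode enforces two preconditions before matching: calls must have
at least 3 supporting reads, and read-through artefacts (two genes on the
same chromosome less than 100,000 bp apart) are removed when genomic gene
coordinates are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx


@dataclass(frozen=True)
class BenchmarkResult:
    TP: int
    FP: int
    FN: int
    precision: float | None
    recall: float | None
    f_measure: float | None


def match_calls(calls: Sequence, truth: Sequence, mode: str = "gene_pair",
                bp_tol: int = 5) -> tuple[int, int, int]:
    """Match fusion calls against truth records.

    ``calls`` and ``truth`` items need attributes ``gene5``/``gene3`` (and
    ``bp5``/``bp3`` in breakpoint mode); tuples ``(gene5, gene3[, bp5, bp3])``
    are also accepted.  Matching is on the *unordered* gene pair; in
    ``breakpoint`` mode both breakpoints must additionally agree within
    ``bp_tol``.  Each truth record matches at most one call (maximum
    bipartite matching, so duplicate calls of one truth count 1 TP + rest FP
    and the counts are invariant to call order).
    """
    if mode not in ("gene_pair", "breakpoint"):
        raise ValueError(f"unknown match mode {mode!r}")

    def unpack(item):
        if hasattr(item, "gene5"):
            bp5 = getattr(item, "bp5", None)
            bp3 = getattr(item, "bp3", None)
            return item.gene5, item.gene3, bp5, bp3
        g5, g3, *rest = item
        bp5 = rest[0] if rest else None
        bp3 = rest[1] if len(rest) > 1 else None
        return g5, g3, bp5, bp3

    calls_u = [unpack(c) for c in calls]
    truth_u = [unpack(t) for t in truth]

    graph = nx.Graph()
    call_nodes = [("c", i) for i in range(len(calls_u))]
    truth_nodes = [("t", j) for j in range(len(truth_u))]
    graph.add_nodes_from(call_nodes, bipartite=0)
    graph.add_nodes_from(truth_nodes, bipartite=1)
    for i, (cg5, cg3, cb5, cb3) in enumerate(calls_u):
        for j, (tg5, tg3, tb5, tb3) in enumerate(truth_u):
            if frozenset((cg5, cg3)) != frozenset((tg5, tg3)):
                continue
            if mode == "breakpoint":
                if cb5 is None or cb3 is None or tb5 is None or tb3 is None:
                    continue
                # Honour orientation when comparing coordinates.
                if cg5 == tg5:
                    ok = abs(cb5 - tb5) <= bp_tol and abs(cb3 - tb3) <= bp_tol
                else:
                    ok = abs(cb5 - tb3) <= bp_tol and abs(cb3 - tb5) <= bp_tol
                if not ok:
                    continue
            graph.add_edge(("c", i), ("t", j))
    matching = nx.bipartite.maximum_matching(graph, top_nodes=call_nodes)
    tp = sum(1 for node in call_nodes if node in matching)
    fp = len(calls_u) - tp
    fn = len(truth_u) - tp
    return tp, fp, fn


def compute_metrics(tp: int, fp: int, fn: int) -> BenchmarkResult:
    """Precision/recall/F from raw counts; undefined ratios become ``None``."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f_measure = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f_measure = 0.0
    else:
        f_measure = None
    return BenchmarkResult(TP=tp, FP=fp, FN=fn, precision=precision,
                           recall=recall, f_measure=f_measure)


def benchmark_filter(calls: Iterable, gene_coords=None, min_support: int = 3,
                     readthrough_dist: int = 100_000) -> list:
    """Apply the benchmark preconditions (support >= 3, read-through removal).

    Thin wrapper over :func:`circfuse.fusion_call.filter_calls` with
    benchmark-mode dropping enabled.
    """
    from circfuse.fusion_call import filter_calls

    return filter_calls(list(calls), gene_coords=gene_coords,
                        min_support=min_support,
                        readthrough_dist=readthrough_dist,
                        drop_readthrough=True)
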