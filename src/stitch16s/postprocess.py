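"""Contig-graph post-processing: bubble resolution and variant splitting.

Two post-assembly repairs recover long 16S sequences that strict assembly
thresholds leave fragmented:

* **Bubble resolution** — when a genus holds two distinct 16S variants,
  assembly stops at the divergent region and the graph shows a bubble: two
  branch contigs sharing a predecessor and a successor.  Branch contigs
  with mean read coverage below ``branch_min_cov`` (default 10) are
  discarded; for every surviving branch the shared base contigs are copied
  and concatenated around it, emitting one linear sequence per branch.
  Plain linear chains are concatenated directly (overlapping junction bases
  emitted once).

* **Variant splitting** — two 16S variants differing by only a few bases
  merge into a single contig.  Columns whose second-most-frequent base is
  supported by at least ``minor_min`` reads are flagged; base patterns over
  the flagged columns observed within single spanning reads are counted,
  patterns with at least ``pattern_min`` supporting reads survive, and the
  contig is duplicated once per surviving pattern with the pattern's bases
  substituted.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import edlib
import numpy as np

from .assemble import BASE_INDEX, Contig, ContigGraph, _CIGAR_RE, _pileup, _polish
from .config import PipelineConfig

log = logging.getLogger(__name__)

_BASES = "ACGT"
_MAX_PATHS = 16  # safety cap on path enumeration per component


def _concat(contigs: list[Contig], overlaps: list[int], new_id: str) -> Contig:
    """Concatenate a chain of contigs, writing each junction overlap once.

    Multi-contig chains are re-polished so junction columns settle on the
    pileup majority of all contributing reads.
    """
    seq = contigs[0].consensus
    members = list(contigs[0].members)
    for nxt, ovl in zip(contigs[1:], overlaps):
        seq += nxt.consensus[ovl:]
        members += nxt.members
    out = Contig(new_id, seq, members)
    if len(contigs) > 1:
        out = _polish(out)
        out.id = new_id
    else:
        _pileup(out)
    return out


def resolve_bubbles(graph: ContigGraph, cfg: PipelineConfig) -> list[Contig]:
    """Resolve the contig graph into linear contigs.

    Branch contigs (members of a bubble) with mean coverage below
    ``cfg.branch_min_cov`` are discarded; every surviving source-to-sink
    path is emitted as one concatenated contig (shared segments copied per
    path).  A cyclic graph is rejected.
    """
    import networkx as nx

    for c in graph.contigs:
        if c.counts is None:
            _pileup(c)
    g = nx.DiGraph()
    for c in graph.contigs:
        g.add_node(c.id)
    ovl_of: dict[tuple[str, str], int] = {}
    for e in graph.edges:
        g.add_edge(e.src, e.dst)
        ovl_of[(e.src, e.dst)] = e.trim
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("contig graph is cyclic; cannot linearise")

    # identify bubble branches: nodes with an alternative sharing both the
    # same predecessor and the same successor
    branch_nodes: set[str] = set()
    for node in g.nodes:
        preds = set(g.predecessors(node))
        succs = set(g.successors(node))
        for other in g.nodes:
            if other == node:
                continue
            if preds and succs and preds & set(g.predecessors(other)) and succs & set(
                g.successors(other)
            ):
                branch_nodes.add(node)
                branch_nodes.add(other)

    dropped: set[str] = set()
    for cid in branch_nodes:
        c = graph.contig(cid)
        if c.mean_depth < cfg.branch_min_cov:
            dropped.add(cid)
            log.info(
                "discarding bubble branch %s (mean coverage %.1f < %s)",
                cid, c.mean_depth, cfg.branch_min_cov,
            )
    g.remove_nodes_from(dropped)

    out: list[Contig] = []
    counter = itertools.count()
    for comp in nx.weakly_connected_components(g):
        sub = g.subgraph(comp)
        sources = [n for n in sub.nodes if sub.in_degree(n) == 0]
        sinks = [n for n in sub.nodes if sub.out_degree(n) == 0]
        paths: list[list[str]] = []
        for s in sorted(sources, key=lambda n: int(n[1:])):
            for t in sorted(sinks, key=lambda n: int(n[1:])):
                if s == t:
                    paths.append([s])
                else:
                    paths.extend(nx.all_simple_paths(sub, s, t))
                if len(paths) > _MAX_PATHS:
                    raise ValueError("contig graph too tangled to enumerate")
        # a node on no source-sink path (isolated after pruning) still emits
        covered = {n for p in paths for n in p}
        for n in sorted(comp - covered, key=lambda n: int(n[1:])):
            paths.append([n])
        for path in paths:
            chain = [graph.contig(n) for n in path]
            overlaps = [ovl_of[(a, b)] for a, b in zip(path, path[1:])]
            out.append(_concat(chain, overlaps, f"p{next(counter)}"))
    return out


def _flagged_columns(contig: Contig, cfg: PipelineConfig) -> list[int]:
    body = contig.counts[:4]
    order = np.sort(body, axis=0)
    minor = order[-2]  # second-most-frequent base count per column
    return [int(i) for i in np.nonzero(minor >= cfg.minor_min)[0]]


def _read_bases_at(contig: Contig, cols: list[int]) -> dict[str, str]:
    """Per spanning read, its bases at the given consensus columns."""
    out: dict[str, str] = {}
    colset = cols
    for read in contig.members:
        rid = read.record.id
        span = contig.alignments.get(rid)
        if span is None or span[0] > colset[0] or span[1] <= colset[-1]:
            continue
        res = edlib.align(read.record.bases, contig.consensus, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        start, _ = res["locations"][0]
        col = start
        qpos = 0
        want = {c: None for c in colset}
        for n, op in _CIGAR_RE.findall(res["cigar"]):
            n = int(n)
            if op in "=XM":
                for c in colset:
                    if col <= c < col + n:
                        want[c] = read.record.bases[qpos + (c - col)]
                col += n
                qpos += n
            elif op == "D":
                for c in colset:
                    if col <= c < col + n:
                        want[c] = "-"
                col += n
            else:
                qpos += n
        if all(v is not None for v in want.values()):
            out[rid] = "".join(want[c] for c in colset)
    return out


def split_variants(contig: Contig, cfg: PipelineConfig) -> list[Contig]:
    """Split a contig that merged near-identical 16S variants.

    Returns the input contig unchanged when fewer than two base patterns
    survive the support thresholds.
    """
    if contig.counts is None:
        _pileup(contig)
    cols = _flagged_columns(contig, cfg)
    if not cols:
        return [contig]
    patterns_by_read = _read_bases_at(contig, cols)
    if not patterns_by_read:
        log.warning(
            "contig %s: no read spans all %d flagged columns; keeping "
            "per-column majority", contig.id, len(cols),
        )
        return [contig]
    tally: dict[str, int] = {}
    for pat in patterns_by_read.values():
        tally[pat] = tally.get(pat, 0) + 1
    surviving = sorted(
        (p for p, n in tally.items() if n >= cfg.pattern_min and "-" not in p),
        key=lambda p: (-tally[p], p),
    )
    if not surviving:
        return [contig]
    if len(surviving) == 1:
        # a single surviving pattern: impose it on the consensus
        seq = list(contig.consensus)
        for c, b in zip(cols, surviving[0]):
            seq[c] = b
        fixed = Contig(contig.id, "".join(seq), contig.members)
        _pileup(fixed)
        return [fixed]
    out: list[Contig] = []
    for vi, pat in enumerate(surviving):
        seq = list(contig.consensus)
        for c, b in zip(cols, pat):
            seq[c] = b
        members = [
            r for r in contig.members
            if patterns_by_read.get(r.record.id, pat) == pat
        ]
        var = Contig(f"{contig.id}v{vi}", "".join(seq), members)
        _pileup(var)
        out.append(var)
        log.info(
            "contig %s: variant pattern %s supported by %d reads",
            contig.id, pat, tally[pat],
        )
    return out


def postprocess_genus(
    graph: ContigGraph, cfg: PipelineConfig
) -> list[Contig]:
    """Bubble resolution followed by variant splitting of each contig."""
    out: list[Contig] = []
    for contig in resolve_bubbles(graph, cfg):
        out.extend(split_variants(contig, cfg))
    return out
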