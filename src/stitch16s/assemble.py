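"""Per-genus greedy overlap-consensus assembly with a contig graph.

Reads of one genus (all oriented to the forward strand) are merged
greedily: the pair of contigs with the highest-identity, then longest,
suffix-prefix overlap is merged first, and merging continues while the best
remaining overlap reaches ``asm_min_ovl`` base pairs at ``asm_min_id``
identity (identity = matches / alignment columns, gaps counting as
columns).  Overlap candidates are found by shared-k-mer seeding (k = 16,
diagonal voting) and evaluated by edit-distance alignment of the implied
overlap region (edlib).

Reads from two 16S variants that diverge below the identity floor refuse to
merge across the divergent region, so each variant keeps its own contig.
The contig *graph* records the remaining adjacency: a directed edge is laid
from contig u to contig v when u's suffix overlaps v's prefix by at least
``edge_min_ovl`` bp (default 40, the span neighbouring amplicons need to
support each other) at ``edge_min_id`` identity (slightly laxer than the
merge identity, absorbing consensus artifacts at contig ends) but below
the merge length.  Two
contigs sharing a predecessor and a successor form a bubble
(:mod:`stitch16s.postprocess` resolves those).

After assembly every member read is re-aligned to its contig to produce
per-column base counts (A/C/G/T/gap), the basis of branch coverage and
variant splitting.
"""

from __future__ import annotations

import heapq
import itertools
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from ._dna import kmer_codes
from .config import PipelineConfig
from .preprocess import TrimmedRead

SEED_K = 16
MIN_SEED_VOTES = 4   # shared k-mers on one diagonal band before alignment
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class Contig:
    id: str
    consensus: str
    members: list[TrimmedRead]
    counts: Optional[np.ndarray] = None       # (5, L): A,C,G,T,gap
    alignments: dict[str, tuple[int, int]] = field(default_factory=dict)
    ambiguous_cols: list[int] = field(default_factory=list)

    @property
    def mean_depth(self) -> float:
        if self.counts is None:
            raise ValueError(f"contig {self.id}: pileup not computed")
        return float(self.counts.sum(axis=0).mean())

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class Edge:
    src: str
    dst: str
    overlap: int        # alignment columns shared by src suffix / dst prefix
    support: int        # read support for the adjacency
    dst_trim: Optional[int] = None  # dst prefix bases covered by src (defaults
                                    # to ``overlap`` when indel-free)

    @property
    def trim(self) -> int:
        return self.overlap if self.dst_trim is None else self.dst_trim


@dataclass
class ContigGraph:
    contigs: list[Contig]
    edges: list[Edge]

    def contig(self, cid: str) -> Contig:
        for c in self.contigs:
            if c.id == cid:
                return c
        raise KeyError(cid)


@dataclass
class _Overlap:
    kind: str            # "contain" (s2 inside s1) or "extend" (s1 -> s2)
    d: int               # s2 start on s1 coordinates
    identity: float
    ovl: int             # alignment columns over the shared region
    consumed: int = 0    # s2 prefix bases covered by the s1 suffix (extend)


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an edlib extended cigar."""
    match = cols = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        cols += n
        if op == "=":
            match += n
    return match, cols


def _seed_profile(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(sorted unique k-mer codes, their first positions) for seeding."""
    codes = kmer_codes(seq, SEED_K)
    valid = codes >= 0
    u, first = np.unique(codes[valid], return_index=True)
    pos = np.nonzero(valid)[0][first]
    return u, pos


def _diagonal_from_seeds(
    p1: tuple[np.ndarray, np.ndarray], p2: tuple[np.ndarray, np.ndarray]
) -> tuple[Optional[int], int]:
    """Most-voted offset d (s2[i] pairs with s1[i+d]) and its vote count."""
    u1, pos1 = p1
    u2, pos2 = p2
    common, i1, i2 = np.intersect1d(u1, u2, assume_unique=True, return_indices=True)
    if common.size == 0:
        return None, 0
    diags = pos1[i1] - pos2[i2]
    lo = int(diags.min())
    counts = np.bincount(diags - lo)
    pooled = np.convolve(counts, np.ones(7, dtype=np.int64), mode="same")
    best = int(np.argmax(pooled))
    votes = int(pooled[best])
    # centre of the winning band: strongest single diagonal within it
    w0 = max(0, best - 3)
    w1 = min(counts.size, best + 4)
    d = int(np.argmax(counts[w0:w1])) + w0 + lo
    return d, votes


def _align_overlap(s1: str, s2: str, d: int) -> Optional[_Overlap]:
    """Evaluate the overlap implied by placing s2 at offset d on s1 (d>=0)."""
    if d < 0:
        return None
    if d + len(s2) <= len(s1) + 5:  # containment (small slack for indels)
        lo = max(0, d - 8)
        hi = min(len(s1), d + len(s2) + 8)
        res = edlib.align(s2, s1[lo:hi], mode="HW", task="path")
        if res["editDistance"] < 0:
            return None
        m, cols = _cigar_stats(res["cigar"])
        return _Overlap("contain", d, m / cols if cols else 0.0, cols)
    suffix = s1[d:]
    if not suffix:
        return None
    res = edlib.align(suffix, s2, mode="SHW", task="path")
    if res["editDistance"] < 0:
        return None
    consumed = res["locations"][0][1] + 1
    m, cols = _cigar_stats(res["cigar"])
    if cols == 0:
        return None
    return _Overlap("extend", d, m / cols, cols, consumed)


def compute_overlap(s1: str, s2: str) -> Optional[_Overlap]:
    """Best overlap placing s2 at a non-negative offset on s1.

    Returns None when no shared seed exists or the seeds place s2 before
    s1's start.  Callers try both argument orders.
    """
    d, votes = _diagonal_from_seeds(_seed_profile(s1), _seed_profile(s2))
    if d is None or d < 0 or votes == 0:
        return None
    return _align_overlap(s1, s2, d)


def _merge(c1: Contig, c2: Contig, ov: _Overlap, new_id: str) -> Contig:
    """Merge c2 into c1 given an overlap computed on their consensuses.

    Over the shared region the consensus of the contig with more member
    reads wins (ties keep c1), emulating majority choice at pair scale.
    """
    if ov.kind == "contain":
        consensus = c1.consensus
    else:
        if len(c1.members) >= len(c2.members):
            consensus = c1.consensus + c2.consensus[ov.consumed :]
        else:
            consensus = c1.consensus[: ov.d] + c2.consensus
    return Contig(new_id, consensus, c1.members + c2.members)


def _pileup(contig: Contig) -> None:
    """Per-column base counts by re-aligning every member read (edlib HW)."""
    L = len(contig.consensus)
    counts = np.zeros((5, L), dtype=np.int32)
    alignments: dict[str, tuple[int, int]] = {}
    for read in contig.members:
        res = edlib.align(read.record.bases, contig.consensus, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        start, end = res["locations"][0]
        col = start
        qpos = 0
        q = read.record.bases
        for n, op in _CIGAR_RE.findall(res["cigar"]):
            n = int(n)
            if op in "=XM":
                for j in range(n):
                    counts[BASE_INDEX.get(q[qpos + j], 4), col + j] += 1
                col += n
                qpos += n
            elif op == "D":          # consensus columns absent from the read
                counts[4, col : col + n] += 1
                col += n
            else:                    # insertion in read: no consensus column
                qpos += n
        alignments[read.record.id] = (start, end + 1)
    contig.counts = counts
    contig.alignments = alignments
    # flag consensus columns where the majority was ambiguous (tie)
    body = counts[:4]
    top = body.max(axis=0)
    contig.ambiguous_cols = [
        int(i)
        for i in np.nonzero((body == top[None, :]).sum(axis=0) > 1)[0]
        if top[i] > 0
    ]


class _Assembler:
    """Greedy merger with cached seed profiles and a lazy candidate heap."""

    def __init__(self, reads: Sequence[TrimmedRead], cfg: PipelineConfig):
        self.cfg = cfg
        self.counter = itertools.count()
        self.seq_no = itertools.count()
        self.contigs: dict[str, Contig] = {}
        self.profiles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.kmer_index: dict[int, list[str]] = {}
        self.alive: set[str] = set()
        self.heap: list[tuple] = []
        for r in reads:
            self._add(Contig(f"c{next(self.counter)}", r.record.bases, [r]))

    def _add(self, contig: Contig) -> None:
        cid = contig.id
        self.contigs[cid] = contig
        prof = _seed_profile(contig.consensus)
        self.profiles[cid] = prof
        self.alive.add(cid)
        for code in prof[0]:
            self.kmer_index.setdefault(int(code), []).append(cid)

    def neighbours(self, cid: str) -> list[str]:
        """Live contigs sharing a seed k-mer, in deterministic id order."""
        out: set[str] = set()
        for code in self.profiles[cid][0]:
            out.update(self.kmer_index.get(int(code), ()))
        out.discard(cid)
        return sorted(
            (c for c in out if c in self.alive), key=lambda c: int(c[1:])
        )

    def evaluate(self, a: str, b: str) -> Optional[tuple]:
        """Best qualifying merge between contigs a and b, as a heap entry."""
        d, votes = _diagonal_from_seeds(self.profiles[a], self.profiles[b])
        if d is None or votes < MIN_SEED_VOTES:
            return None
        if d < 0:
            a, b = b, a
            d = -d
        ca, cb = self.contigs[a], self.contigs[b]
        ov = _align_overlap(ca.consensus, cb.consensus, d)
        if ov is None:
            return None
        cfg = self.cfg
        eff = ov.ovl if ov.kind == "extend" else min(len(ca), len(cb))
        need = min(cfg.asm_min_ovl, len(ca), len(cb))
        if ov.identity >= cfg.asm_min_id and eff >= need:
            return (-ov.identity, -eff, next(self.seq_no), a, b, ov)
        return None

    def push(self, a: str, b: str) -> None:
        entry = self.evaluate(a, b)
        if entry is not None:
            heapq.heappush(self.heap, entry)

    def run(self) -> list[Contig]:
        seen: set[tuple[str, str]] = set()
        for cid in sorted(self.alive, key=lambda c: int(c[1:])):
            for nb in self.neighbours(cid):
                key = (cid, nb) if cid < nb else (nb, cid)
                if key not in seen:
                    seen.add(key)
                    self.push(*key)
        while self.heap:
            _, _, _, a, b, ov = heapq.heappop(self.heap)
            if a not in self.alive or b not in self.alive:
                continue
            merged = _merge(
                self.contigs[a], self.contigs[b], ov, f"c{next(self.counter)}"
            )
            self.alive.discard(a)
            self.alive.discard(b)
            self._add(merged)
            for nb in self.neighbours(merged.id):
                self.push(merged.id, nb)
        return [
            self.contigs[cid]
            for cid in sorted(self.alive, key=lambda c: int(c[1:]))
        ]

def _polish(contig: Contig) -> Contig:
    """Replace the consensus with the per-column pileup majority.

    Pairwise merging can retain a single read's error in the consensus;
    majority vote over the full pileup washes those out.  Columns where a
    gap outvotes every base are removed.
    """
    if contig.counts is None:
        _pileup(contig)
    counts = contig.counts
    best = counts.argmax(axis=0)
    covered = counts.sum(axis=0) > 0
    bases = np.array(list("ACGT-"))[best]
    old = np.array(list(contig.consensus))
    bases = np.where(covered, bases, old)
    seq = "".join(b for b in bases if b != "-")
    out = Contig(contig.id, seq, contig.members)
    _pileup(out)
    return out


def graph_edges(final: Sequence[Contig], cfg: PipelineConfig) -> list[Edge]:
    """Adjacency for real-but-short overlaps between final contigs."""
    profiles = {c.id: _seed_profile(c.consensus) for c in final}
    edges: list[Edge] = []
    for ca, cb in itertools.permutations(final, 2):
        d, votes = _diagonal_from_seeds(profiles[ca.id], profiles[cb.id])
        if d is None or d <= 0 or votes == 0:
            continue
        ov = _align_overlap(ca.consensus, cb.consensus, d)
        if ov is None or ov.kind != "extend":
            continue
        if ov.identity >= cfg.edge_min_id and ov.ovl >= cfg.edge_min_ovl:
            edges.append(
                Edge(
                    ca.id, cb.id, ov.ovl,
                    min(len(ca.members), len(cb.members)),
                    dst_trim=ov.consumed,
                )
            )
    return edges


def assemble_genus(
    reads: Sequence[TrimmedRead], cfg: PipelineConfig
) -> ContigGraph:
    """Assemble one genus's reads into a contig graph.

    Greedy highest-identity-first merging under the ``asm_min_ovl`` /
    ``asm_min_id`` contract; singleton reads remain singleton contigs;
    consensus sequences are polished by pileup majority; the returned graph
    carries adjacency edges for overlaps that were real but too short to
    merge.
    """
    if not reads:
        raise ValueError("no reads to assemble")
    asm = _Assembler(reads, cfg)
    final = [_polish(c) for c in asm.run()]
    return ContigGraph(final, graph_edges(final, cfg))


def contig_stats(
    graph_or_contigs: ContigGraph | Sequence[Contig],
    reads: Sequence[TrimmedRead],
) -> tuple[int, float, float]:
    """(longest contig length, mean trimmed read length, their ratio)."""
    contigs = (
        graph_or_contigs.contigs
        if isinstance(graph_or_contigs, ContigGraph)
        else list(graph_or_contigs)
    )
    if not contigs or not reads:
        raise ValueError("contig_stats needs at least one contig and one read")
    lcl = max(len(c) for c in contigs)
    mrl = float(np.mean([r.trimmed_len for r in reads]))
    return lcl, mrl, lcl / mrl
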