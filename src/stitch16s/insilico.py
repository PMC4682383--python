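"""In-silico primer-panel evaluation.

Electronic PCR (ePCR) predicts amplification of a reference by a primer
pair: the forward primer must match the plus strand and the reverse
primer's reverse complement a downstream site, each with at most
``epcr_mm`` mismatches (no indels; IUPAC degeneracy counts as a match),
and the product length must fall inside the pair's insert range.

From per-reference hits the module derives:

* span-aware **sensitivity** per primer — amplifiable references divided by
  references whose span (located by alignment to a canonical anchor
  sequence) reaches both binding sites, plus a union row over the six
  primers;
* **amplicon stitching** — hits on one reference are interval-merged when
  they overlap by >= ``stitch_min_ovl`` bp (10 by default); the fraction of
  references whose merged run reaches ``long_len`` (1000 bp) is reported
  over references covering the binding sites of four consecutive primers;
* the **panel-vs-single-primer comparison** — among full-length references
  (those covering the near-full-length pair's two sites), the percentage
  missed by all six panel primers versus missed by the single pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from ._dna import mask_array, revcomp
from .config import PipelineConfig
from .panel import fwd_site, rev_site
from .seq_io import PrimerPair, ReferenceDB

MAX_ANCHOR_DIVERGENCE = 0.35  # edit distance / length beyond which a
                              # reference is called unalignable to the anchor


@dataclass
class AmpliconHit:
    ref_id: str
    primer: str
    fwd_start: int      # 0-based, on the reference
    rev_end: int        # 0-based exclusive
    mm_fwd: int
    mm_rev: int

    @property
    def product_len(self) -> int:
        return self.rev_end - self.fwd_start


@dataclass
class SensitivityRow:
    primer: str
    n_covering: int
    n_amplifiable: int

    @property
    def pct(self) -> float:
        if self.n_covering == 0:
            return 0.0
        return 100.0 * self.n_amplifiable / self.n_covering


@dataclass
class SensitivityReport:
    rows: list[SensitivityRow]
    union: SensitivityRow
    union_all: SensitivityRow     # union with all aligned refs as denominator
    n_excluded: int               # references unalignable to the anchor

    def as_tsv(self) -> str:
        lines = ["primer\tn_covering\tn_amplifiable\tpct"]
        for r in self.rows + [self.union]:
            lines.append(
                f"{r.primer}\t{r.n_covering}\t{r.n_amplifiable}\t{r.pct:.1f}"
            )
        return "\n".join(lines) + "\n"


def expected_amplicon_span(pair: PrimerPair) -> int:
    """Expected product span in bp from the positional name alone."""
    return pair.rev_pos - pair.fwd_pos + 1


def _site_mismatches(seq_mask: np.ndarray, primer: str) -> np.ndarray:
    """Mismatch count of the primer at every start position of the sequence."""
    pm = mask_array(primer)
    L = pm.size
    if seq_mask.size < L:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seq_mask, L)
    return ((windows & pm[None, :]) == 0).sum(axis=1)


def epcr(
    ref_seq: str, pair: PrimerPair, cfg: PipelineConfig, ref_id: str = "ref"
) -> list[AmpliconHit]:
    """All qualifying amplicons of one primer pair on one reference."""
    m = mask_array(ref_seq)
    fwd_mm = _site_mismatches(m, pair.fwd_seq)
    rev_mm = _site_mismatches(m, revcomp(pair.rev_seq))
    fwd_hits = np.nonzero(fwd_mm <= cfg.epcr_mm)[0]
    rev_hits = np.nonzero(rev_mm <= cfg.epcr_mm)[0]
    out: list[AmpliconHit] = []
    rlen = len(pair.rev_seq)
    for i in fwd_hits:
        for j in rev_hits:
            end = int(j) + rlen
            plen = end - int(i)
            if pair.insert_min <= plen <= pair.insert_max:
                out.append(
                    AmpliconHit(
                        ref_id, pair.name, int(i), end,
                        int(fwd_mm[i]), int(rev_mm[j]),
                    )
                )
    return out


def epcr_naive(
    ref_seq: str, pair: PrimerPair, cfg: PipelineConfig, ref_id: str = "ref"
) -> list[AmpliconHit]:
    """Position-by-position rescan of the same contract (cross-check oracle
    for the vectorised scan)."""
    from ._dna import hamming_iupac

    out = []
    fseq, rseq = pair.fwd_seq, revcomp(pair.rev_seq)
    for i in range(len(ref_seq) - len(fseq) + 1):
        if hamming_iupac(fseq, ref_seq[i : i + len(fseq)]) > cfg.epcr_mm:
            continue
        mmf = hamming_iupac(fseq, ref_seq[i : i + len(fseq)])
        for j in range(len(ref_seq) - len(rseq) + 1):
            mmr = hamming_iupac(rseq, ref_seq[j : j + len(rseq)])
            if mmr > cfg.epcr_mm:
                continue
            plen = j + len(rseq) - i
            if pair.insert_min <= plen <= pair.insert_max:
                out.append(AmpliconHit(ref_id, pair.name, i, j + len(rseq), mmf, mmr))
    return out


def locate_spans(
    refdb: ReferenceDB, anchor: str
) -> tuple[dict[str, tuple[int, int]], list[str]]:
    """Anchor-space span of every reference, by infix alignment to the anchor.

    Returns (spans, unalignable ids); spans are 0-based half-open on the
    anchor coordinate system.
    """
    spans: dict[str, tuple[int, int]] = {}
    excluded: list[str] = []
    for rec in refdb.records:
        res = edlib.align(rec.bases, anchor, mode="HW", task="locations")
        if (
            res["editDistance"] < 0
            or res["editDistance"] / max(1, len(rec.bases)) > MAX_ANCHOR_DIVERGENCE
        ):
            excluded.append(rec.id)
            continue
        start, end = res["locations"][0]
        spans[rec.id] = (start, end + 1)
    return spans, excluded


def _covers(span: tuple[int, int], site: tuple[int, int]) -> bool:
    return span[0] <= site[0] and span[1] >= site[1]


def _covers_pair(span: tuple[int, int], pair: PrimerPair) -> bool:
    return _covers(span, fwd_site(pair)) and _covers(span, rev_site(pair))


def primer_sensitivity(
    refdb: ReferenceDB,
    panel: Sequence[PrimerPair],
    anchor_ref: str,
    cfg: PipelineConfig,
) -> SensitivityReport:
    """Span-aware per-primer sensitivity plus the union-of-panel row."""
    spans, excluded = locate_spans(refdb, anchor_ref)
    amplified: dict[str, set[str]] = {p.name: set() for p in panel}
    for rec in refdb.records:
        if rec.id not in spans:
            continue
        for pair in panel:
            if epcr(rec.bases, pair, cfg, rec.id):
                amplified[pair.name].add(rec.id)
    rows = []
    for pair in panel:
        covering = [r for r, sp in spans.items() if _covers_pair(sp, pair)]
        n_amp = sum(1 for r in covering if r in amplified[pair.name])
        rows.append(SensitivityRow(pair.name, len(covering), n_amp))
    any_cov = [
        r for r, sp in spans.items() if any(_covers_pair(sp, p) for p in panel)
    ]
    any_amp_ids = set().union(*amplified.values()) if amplified else set()
    union = SensitivityRow(
        "any", len(any_cov), sum(1 for r in any_cov if r in any_amp_ids)
    )
    union_all = SensitivityRow(
        "any/all", len(spans), sum(1 for r in spans if r in any_amp_ids)
    )
    return SensitivityReport(rows, union, union_all, len(excluded))


def merge_intervals(
    intervals: Sequence[tuple[int, int]], min_ovl: int
) -> list[tuple[int, int]]:
    """Merge half-open intervals that overlap by at least ``min_ovl`` bp."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if out[-1][1] - s >= min_ovl:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def stitch_amplicons(
    hits_per_ref: dict[str, list[AmpliconHit]],
    cfg: PipelineConfig,
    spans: Optional[dict[str, tuple[int, int]]] = None,
    panel: Optional[Sequence[PrimerPair]] = None,
) -> tuple[dict[str, list[int]], int, float]:
    """Interval-merge each reference's amplicons; count long assemblies.

    Returns (per-ref merged segment lengths, number of references whose
    longest merged run reaches ``cfg.long_len``, and that count divided by
    the number of references covering four consecutive primers' binding
    sites).  When spans/panel are not supplied the denominator falls back
    to all references with hits.
    """
    lengths: dict[str, list[int]] = {}
    n_long = 0
    for rid, hits in hits_per_ref.items():
        merged = merge_intervals(
            [(h.fwd_start, h.rev_end) for h in hits], cfg.stitch_min_ovl
        )
        lens = [e - s for s, e in merged]
        lengths[rid] = lens
        if lens and max(lens) >= cfg.long_len:
            n_long += 1
    if spans is not None and panel is not None:
        ordered = sorted(panel, key=lambda p: p.fwd_pos)
        denom = 0
        for rid, sp in spans.items():
            for i in range(len(ordered) - 3):
                if all(_covers_pair(sp, p) for p in ordered[i : i + 4]):
                    denom += 1
                    break
    else:
        denom = len(hits_per_ref)
    frac = n_long / denom if denom else 0.0
    return lengths, n_long, frac


def compare_single_primer(
    refdb: ReferenceDB,
    panel: Sequence[PrimerPair],
    single_pair: PrimerPair,
    cfg: PipelineConfig,
    anchor_ref: str,
) -> tuple[float, float, int]:
    """Percentage of full-length references missed by the six-primer panel
    versus by the single near-full-length pair.

    Full-length references are those whose anchor span covers both of the
    single pair's binding sites.  Returns (pct missed by panel, pct missed
    by single pair, number of full-length references).
    """
    spans, _ = locate_spans(refdb, anchor_ref)
    full = [r for r, sp in spans.items() if _covers_pair(sp, single_pair)]
    if not full:
        return 0.0, 0.0, 0
    seqs = {rec.id: rec.bases for rec in refdb.records}
    missed_panel = 0
    missed_single = 0
    for rid in full:
        if not any(epcr(seqs[rid], p, cfg, rid) for p in panel):
            missed_panel += 1
        if not epcr(seqs[rid], single_pair, cfg, rid):
            missed_single += 1
    n = len(full)
    return 100.0 * missed_panel / n, 100.0 * missed_single / n, n
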