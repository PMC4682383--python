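"""Read preprocessing: primer-of-origin assignment, trimming, length filter.

Reads from a pooled multi-primer amplicon library carry the amplification
primer at their 5' end.  Demultiplexing compares each read's 5' prefix with
every panel member's forward and reverse primer (IUPAC-aware, bounded
mismatches); reads matching a reverse primer are reverse-complemented so the
whole downstream pipeline works on one strand.  Demultiplexing necessarily
precedes trimming, which removes a fixed number of bases from both read ends
(covering the primer) and drops reads that end up shorter than the length
floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from ._dna import hamming_iupac, revcomp
from .config import PipelineConfig
from .seq_io import PrimerPair, SequenceRecord

UNASSIGNED = "unassigned"


@dataclass
class TrimmedRead:
    """A read after demultiplexing (and possibly trimming)."""

    record: SequenceRecord
    primer_label: str
    orig_len: int
    trimmed_len: int


def _best_primer(
    bases: str, panel: Sequence[PrimerPair], max_mm: int
) -> tuple[Optional[str], Optional[str], int]:
    """Best (label, end, mismatches) for a read 5' prefix, or (None, None, -1).

    Ties are broken by fewest mismatches, then panel order with the forward
    primer of a pair considered before its reverse primer.
    """
    best: tuple[Optional[str], Optional[str], int] = (None, None, max_mm + 1)
    for pair in panel:
        for end, primer in (("fwd", pair.fwd_seq), ("rev", pair.rev_seq)):
            if len(bases) < len(primer):
                continue
            mm = hamming_iupac(primer, bases[: len(primer)])
            if mm < best[2]:
                best = (pair.name, end, mm)
    if best[0] is None:
        return None, None, -1
    return best


def demultiplex(
    reads: Sequence[SequenceRecord],
    panel: Sequence[PrimerPair],
    max_mm: int = 2,
) -> list[TrimmedRead]:
    """Label each read with its primer of origin; orient to forward strand.

    A read whose 5' prefix matches a reverse primer within ``max_mm``
    mismatches is reverse-complemented (its qualities reversed).  Unmatched
    reads are kept with label ``"unassigned"``.
    """
    if not panel:
        raise ValueError("primer panel is empty")
    out: list[TrimmedRead] = []
    for rec in reads:
        label, end, _ = _best_primer(rec.bases, panel, max_mm)
        if label is None:
            oriented = rec
            label = UNASSIGNED
        elif end == "rev":
            oriented = SequenceRecord(
                rec.id,
                revcomp(rec.bases),
                None if rec.quals is None else rec.quals[::-1],
                primer_label=label,
            )
        else:
            oriented = SequenceRecord(rec.id, rec.bases, rec.quals, primer_label=label)
        oriented.primer_label = label
        out.append(
            TrimmedRead(
                record=oriented,
                primer_label=label,
                orig_len=len(rec.bases),
                trimmed_len=len(rec.bases),
            )
        )
    return out


def trim_and_filter(
    reads: Sequence[TrimmedRead | SequenceRecord], cfg: PipelineConfig
) -> tuple[list[TrimmedRead], dict[str, int]]:
    """Trim ``cfg.trim_len`` bases off both ends; keep reads >= ``min_read_len``.

    Accepts demultiplexed reads or raw records (labelled unassigned).
    Returns the kept reads and a count dict with keys ``input``, ``kept``,
    ``dropped`` (kept + dropped == input).
    """
    t = cfg.trim_len
    kept: list[TrimmedRead] = []
    n_in = 0
    for r in reads:
        n_in += 1
        if isinstance(r, SequenceRecord):
            r = TrimmedRead(r, r.primer_label or UNASSIGNED, len(r), len(r))
        rec = r.record
        bases = rec.bases[t : len(rec.bases) - t] if t else rec.bases
        if len(rec.bases) <= 2 * t:
            bases = ""
        if len(bases) < cfg.min_read_len:
            continue
        quals = None
        if rec.quals is not None and bases:
            quals = rec.quals[t : len(rec.bases) - t]
        kept.append(
            TrimmedRead(
                record=SequenceRecord(rec.id, bases, quals, r.primer_label),
                primer_label=r.primer_label,
                orig_len=r.orig_len,
                trimmed_len=len(bases),
            )
        )
    return kept, {"input": n_in, "kept": len(kept), "dropped": n_in - len(kept)}
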