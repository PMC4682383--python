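"""Species assignment by best local alignment against the reference set.

The longest contig of a confident genus is aligned locally against every
reference sequence (Smith-Waterman-Gotoh with affine gaps; default scores
match +2, mismatch -3, gap open 5, gap extend 2 — the first gap base costs
open + extend).  The best-scoring hit passing the e-value filter assigns
its species when the alignment identity reaches ``id_min_pct`` (97% by
default); identity = 100 * matches / alignment columns, gap columns
included.

E-values use the standard Karlin-Altschul length-scaled form
``E = m * n * 2**(-bit)`` with ``bit = (lambda*S - ln K) / ln 2``; lambda is
solved from the scoring scheme at uniform base composition and K is the
conventional constant 0.41.  The e-value is a coarse filter here — the
identity threshold is the contract.

Alignment traceback prefers, at equal score, a diagonal step, then a gap in
the subject, then a gap in the query (documented tie-break; co-optimal
alignments with different gap placements exist).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import log
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .config import PipelineConfig
from .seq_io import ReferenceDB, SequenceRecord

KARLIN_K = 0.41
DEFAULT_SCORING = (2, -3, 5, 2)  # match, mismatch, gap open, gap extend


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    matches: int
    mismatches: int
    gaps: int
    aligned_columns: int
    score: int
    bit_score: float
    evalue: float
    query_start: int      # 0-based half-open, on the query
    query_end: int
    subject_start: int
    subject_end: int

    @property
    def identity_pct(self) -> float:
        if self.aligned_columns == 0:
            return 0.0
        return 100.0 * self.matches / self.aligned_columns


@dataclass
class SpeciesCall:
    genus: str
    contig_id: str
    species: str              # "unassigned" when no hit qualifies
    identity_pct: float
    subject_id: Optional[str] = None


@lru_cache(maxsize=8)
def _karlin_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 at uniform composition."""

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


@njit(cache=False)
def _gotoh(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = q.size, s.size
    NEG = -10 ** 9
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # gap in query (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # gap in subject (up)
    # traceback: 0 stop, 1 diag, 2 left(E), 3 up(F); e/f: 1 opened from H
    TH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    TE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    TF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    first = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eh = H[i, j - 1] - first
            ee = E[i, j - 1] - gap_extend
            if eh >= ee:
                E[i, j] = eh
                TE[i, j] = 1
            else:
                E[i, j] = ee
                TE[i, j] = 0
            fh = H[i - 1, j] - first
            ff = F[i - 1, j] - gap_extend
            if fh >= ff:
                F[i, j] = fh
                TF[i, j] = 1
            else:
                F[i, j] = ff
                TF[i, j] = 0
            sub = match if q[i - 1] == s[j - 1] else mismatch
            diag = H[i - 1, j - 1] + sub
            h = 0
            t = 0
            if diag >= h:
                h = diag
                t = 1
            if F[i, j] > h:
                h = F[i, j]
                t = 3
            if E[i, j] > h:
                h = E[i, j]
                t = 2
            H[i, j] = h
            TH[i, j] = t
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    matches = 0
    mismatches = 0
    gaps = 0
    i, j = bi, bj
    state = 0  # 0 in H, 2 in E, 3 in F
    while i > 0 and j > 0:
        if state == 0:
            t = TH[i, j]
            if t == 0:
                break
            if t == 1:
                if q[i - 1] == s[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            else:
                state = t
        elif state == 2:
            gaps += 1
            opened = TE[i, j]
            j -= 1
            state = 0 if opened == 1 else 2
        else:
            gaps += 1
            opened = TF[i, j]
            i -= 1
            state = 0 if opened == 1 else 3
    return best, matches, mismatches, gaps, i, j, bi, bj


def align_local(
    query: str | SequenceRecord,
    subject: str | SequenceRecord,
    scoring: tuple[int, int, int, int] = DEFAULT_SCORING,
) -> AlignmentResult:
    """Best local alignment of query vs subject under affine-gap scoring."""
    qid = query.id if isinstance(query, SequenceRecord) else "query"
    sid = subject.id if isinstance(subject, SequenceRecord) else "subject"
    qs = query.bases if isinstance(query, SequenceRecord) else query
    ss = subject.bases if isinstance(subject, SequenceRecord) else subject
    if not qs or not ss:
        raise ValueError("align_local requires non-empty sequences")
    match, mismatch, gopen, gext = scoring
    qa = np.frombuffer(qs.encode("ascii"), dtype=np.uint8)
    sa = np.frombuffer(ss.encode("ascii"), dtype=np.uint8)
    score, matches, mismatches, gaps, qi, sj, qe, se = _gotoh(
        qa, sa, match, mismatch, gopen, gext
    )
    cols = matches + mismatches + gaps
    lam = _karlin_lambda(match, mismatch)
    bit = (lam * score - log(KARLIN_K)) / log(2.0)
    evalue = float(len(qs) * len(ss) * 2.0 ** (-bit))
    return AlignmentResult(
        query_id=qid,
        subject_id=sid,
        matches=int(matches),
        mismatches=int(mismatches),
        gaps=int(gaps),
        aligned_columns=int(cols),
        score=int(score),
        bit_score=float(bit),
        evalue=evalue,
        query_start=int(qi),
        query_end=int(qe),
        subject_start=int(sj),
        subject_end=int(se),
    )


def assign_species(
    contig: str | SequenceRecord,
    refdb: ReferenceDB,
    cfg: PipelineConfig,
    genus: str = "",
) -> tuple[SpeciesCall, Optional[AlignmentResult]]:
    """Best-hit species assignment for one contig.

    The hit with the highest score (ties: higher identity, then subject id
    order) and e-value <= ``cfg.evalue`` assigns its species iff identity
    >= ``cfg.id_min_pct``; otherwise the call is "unassigned".
    """
    cid = contig.id if isinstance(contig, SequenceRecord) else "contig"
    best: Optional[AlignmentResult] = None
    for ref in refdb.records:
        res = align_local(contig, ref)
        res.query_id = cid
        res.subject_id = ref.id
        if res.evalue > cfg.evalue:
            continue
        if best is None or (res.score, res.identity_pct, _neg(res.subject_id)) > (
            best.score, best.identity_pct, _neg(best.subject_id)
        ):
            best = res
    if best is None or best.identity_pct < cfg.id_min_pct:
        return (
            SpeciesCall(genus, cid, "unassigned",
                        0.0 if best is None else best.identity_pct,
                        None if best is None else best.subject_id),
            best,
        )
    species = refdb.species.get(best.subject_id, "unassigned")
    return SpeciesCall(genus, cid, species, best.identity_pct, best.subject_id), best


class _neg(str):
    """Reverse string ordering so that max() prefers the earlier subject id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def blast_outfmt6(results: Sequence[AlignmentResult]) -> str:
    """Tabular report mirroring the familiar 12-column hit table."""
    lines = []
    for r in results:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    r.query_id, r.subject_id, f"{r.identity_pct:.2f}",
                    r.aligned_columns, r.mismatches, r.gaps,
                    r.query_start + 1, r.query_end, r.subject_start + 1,
                    r.subject_end, f"{r.evalue:.2g}", f"{r.bit_score:.1f}",
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
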