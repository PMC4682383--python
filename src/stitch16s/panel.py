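"""Default primer panel and the canonical 16S coordinate anchor.

The pipeline's six-pair panel (A-F) tiles the ~1.5 kb 16S rRNA gene with
overlapping amplicons named by their 1-based positions: 8F-534R, 343F-798R,
517F-926R, 784F-1114R, 917F-1407R and 1099F-1541R, with per-pair expected
insert (product) ranges of 450-550, 350-500, 350-450, 250-350, 450-550 and
350-500 bp respectively.

Primer pair sequences for such panels are sample-dependent configuration, so
they are inputs (TSV/JSON, see :mod:`stitch16s.seq_io`).  The defaults here
are a documented synthetic-but-realistic set: a canonical anchor sequence of
1542 bp is built from conserved blocks seeded with widely used universal 16S
primer motifs (27F, 534R, 517F, 926R, 1392R-family, 1541R, 1492R ...) placed
at their nominal coordinates, with deterministic pseudo-random bases in the
variable regions, and every default primer is read off that anchor (reverse
primers as reverse complements).  This guarantees the panel, the anchor and
the synthetic reference generator agree on coordinates.

The single-pair comparator uses the classic near-full-length primers
27F (AGAGTTTGATCCTGGCTCAG) and 1492R (GGTTACCTTGTTACGACTT).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ._dna import IUPAC_SETS, revcomp
from .seq_io import PrimerPair

ANCHOR_LEN = 1542

# conserved blocks: 1-based start -> sequence (never mutated by the
# synthetic reference generator; primer binding sites live inside them)
CONSERVED_BLOCKS: dict[int, str] = {
    8: "AGAGTTTGATCCTGGCTCAG",
    340: "CCTACGGGAGGCAGCAGTGG",
    515: "GTGCCAGCAGCCGCGGTAATAC",
    784: "AGGATTAGATACCCTGGTAGTCCACGCC",
    909: "ACTCAAAGGAATTGACGGGGGCCCGCACAAGC",
    1086: "CAACGAGCGCAACCCTTGTCCTTAGTTGCCAGCA",
    1390: "TACGGGCGGTGTGTACAAGGC",
    1474: "AAGTCGTAACAAGGTAACC",
    1525: "GGCTGGATCACCTCCTT",
}

# (name, display, fwd_len, rev_len, insert_min, insert_max)
_PANEL_LAYOUT = (
    ("A", "8F-534R", 20, 17, 450, 550),
    ("B", "343F-798R", 15, 15, 350, 500),
    ("C", "517F-926R", 17, 18, 350, 450),
    ("D", "784F-1114R", 20, 17, 250, 350),
    ("E", "917F-1407R", 20, 17, 450, 550),
    ("F", "1099F-1541R", 17, 17, 350, 500),
)

# IUPAC degeneracy introduced into selected default primers, as real
# universal primers carry; (primer name, end, 0-based position) -> code.
# Each code's expansion contains the anchor base at that position.
_DEGENERACY = {
    ("B", "fwd", 4): "R",   # ACGG[R]AGGCAGCAGT
    ("C", "rev", 10): "M",  # CCGTCAATTC[M]TTTGAGT
    ("C", "rev", 14): "R",  # CCGTCAATTCMTTT[R]AGT
}


@lru_cache(maxsize=1)
def canonical_anchor() -> str:
    """The fixed 1542 bp anchor sequence (coordinate reference)."""
    rng = np.random.default_rng(1618)
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=ANCHOR_LEN, p=[0.24, 0.26, 0.26, 0.24]))
    for start, block in CONSERVED_BLOCKS.items():
        seq[start - 1 : start - 1 + len(block)] = list(block)
    return "".join(seq)


def _apply_degeneracy(name: str, end: str, seq: str) -> str:
    out = list(seq)
    for (n, e, pos), code in _DEGENERACY.items():
        if n == name and e == end:
            if out[pos] not in IUPAC_SETS[code]:
                raise AssertionError("degeneracy override incompatible with anchor")
            out[pos] = code
    return "".join(out)


@lru_cache(maxsize=1)
def default_panel() -> tuple[PrimerPair, ...]:
    """The six default primer pairs A-F, derived from the anchor."""
    anchor = canonical_anchor()
    panel = []
    for name, display, flen, rlen, imin, imax in _PANEL_LAYOUT:
        fwd_pos, rev_pos = (int(x[:-1]) for x in display.split("-"))
        fwd = anchor[fwd_pos - 1 : fwd_pos - 1 + flen]
        rev = revcomp(anchor[rev_pos - rlen : rev_pos])
        panel.append(
            PrimerPair(
                name=name,
                display=display,
                fwd_seq=_apply_degeneracy(name, "fwd", fwd),
                rev_seq=_apply_degeneracy(name, "rev", rev),
                insert_min=imin,
                insert_max=imax,
            )
        )
    return tuple(panel)


@lru_cache(maxsize=1)
def full_length_pair() -> PrimerPair:
    """The single near-full-length pair (27F/1492R sequences).

    The display uses this package's naming convention (forward primer named
    by its 5' start): the classic 27F anneals at positions 8-27.
    """
    return PrimerPair(
        name="27F-1492R",
        display="8F-1492R",
        fwd_seq="AGAGTTTGATCCTGGCTCAG",
        rev_seq="GGTTACCTTGTTACGACTT",
        insert_min=1300,
        insert_max=1600,
    )


def fwd_site(pair: PrimerPair) -> tuple[int, int]:
    """0-based half-open anchor coordinates of the forward binding site."""
    return pair.fwd_pos - 1, pair.fwd_pos - 1 + len(pair.fwd_seq)


def rev_site(pair: PrimerPair) -> tuple[int, int]:
    """0-based half-open anchor coordinates of the reverse binding site."""
    return pair.rev_pos - len(pair.rev_seq), pair.rev_pos
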