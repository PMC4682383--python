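"""Primer-bias statistics, composition profiles, and the run summary table.

Percent formatting: text percentages round half-away-from-zero to one
decimal; primer-bias percentages round to whole percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .classify import ConfidentGenusSet, TaxAssignment
from .config import PipelineConfig
from .seq_io import RANKS

SUMMARY_COLUMNS = (
    "Raw reads", "Trimmed reads", "Confident reads", "Total genus",
    "Confident genus", "No. of contigs", "lcl/mrl>=1.5", "lcl/mrl>=2",
    "lc identity>=97%",
)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-away-from-zero to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    raw = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    q = Decimal(1).scaleb(-decimals)
    return float(raw.quantize(q, rounding=ROUND_HALF_UP))


def primer_bias(
    confident_set: ConfidentGenusSet,
    read_labels: dict[str, str],
    primers: Optional[Sequence[str]] = None,
) -> dict[str, int]:
    """Percentage of confident genera each primer would miss on its own.

    A genus is missed by primer p when none of its confident reads carries
    label p.  Percentages are whole percent of the confident-genus count.
    """
    genera = confident_set.by_genus
    if not genera:
        raise ValueError("no confident genera; primer bias is undefined")
    if primers is None:
        primers = sorted({read_labels[r] for ids in genera.values() for r in ids})
    out: dict[str, int] = {}
    for p in primers:
        missed = sum(
            1
            for ids in genera.values()
            if not any(read_labels.get(r) == p for r in ids)
        )
        out[p] = int(percent(missed, len(genera), 0))
    return out


def composition(
    assignments_by_sample: dict[str, Sequence[TaxAssignment]],
    rank: str,
    cfg: PipelineConfig,
    top_n: int = 15,
) -> pd.DataFrame:
    """Stacked composition profile at one taxonomic rank.

    Rows are taxa (the ``top_n`` by cross-sample mean percentage, the rest
    lumped as ``others``), columns are samples; values are percentages of
    each sample's reads that are confidently classified to the taxon.  The
    headroom to 100% in a column is the sample's non-confident share.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    ri = RANKS.index(rank)
    table: dict[str, dict[str, float]] = {}
    for sample, assigns in assignments_by_sample.items():
        total = len(assigns)
        counts: dict[str, int] = {}
        for a in assigns:
            if a.score < cfg.conf_score or len(a.lineage) <= ri:
                continue
            counts[a.lineage[ri]] = counts.get(a.lineage[ri], 0) + 1
        table[sample] = {
            t: (100.0 * n / total if total else 0.0) for t, n in counts.items()
        }
    df = pd.DataFrame(table).fillna(0.0)
    if df.empty:
        return pd.DataFrame(columns=list(assignments_by_sample))
    order = df.mean(axis=1).sort_values(ascending=False)
    top = list(order.index[:top_n])
    rest = [t for t in df.index if t not in top]
    out = df.loc[top]
    if rest:
        out.loc["others"] = df.loc[rest].sum(axis=0)
    return out


@dataclass
class GenusResult:
    """Per-genus outcome needed by the summary table."""

    genus: str
    longest_contig_len: int
    lcl_mrl_ratio: float
    assembled: bool               # longest contig built from >= 2 reads
    species_identity_pct: Optional[float] = None


@dataclass
class SampleRunStats:
    sample: str
    raw_reads: int
    trimmed_reads: int
    confident_reads: int
    total_genus: int
    confident_genus: int
    genus_results: list[GenusResult] = field(default_factory=list)


def summary_table(stats: Sequence[SampleRunStats]) -> pd.DataFrame:
    """One row per sample with the nine pipeline summary columns."""
    rows = []
    for s in stats:
        assembled = [g for g in s.genus_results if g.assembled]
        rows.append(
            {
                "Sample": s.sample,
                "Raw reads": s.raw_reads,
                "Trimmed reads": s.trimmed_reads,
                "Confident reads": s.confident_reads,
                "Total genus": s.total_genus,
                "Confident genus": s.confident_genus,
                "No. of contigs": len(assembled),
                "lcl/mrl>=1.5": sum(1 for g in assembled if g.lcl_mrl_ratio >= 1.5),
                "lcl/mrl>=2": sum(1 for g in assembled if g.lcl_mrl_ratio >= 2.0),
                "lc identity>=97%": sum(
                    1
                    for g in s.genus_results
                    if g.species_identity_pct is not None
                    and g.species_identity_pct >= 97.0
                ),
            }
        )
    return pd.DataFrame(rows).set_index("Sample")
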