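"""Synthetic community and read generator.

Everything the pipeline consumes can be generated here, hermetically:

* :func:`make_refdb` builds a synthetic reference 16S database from the
  canonical anchor: genera diverge from the anchor in the variable regions
  (substitutions plus occasional short indels; conserved primer blocks are
  untouched), species within a genus add ~1% further substitutions.
  Optionally a fraction of references is truncated to a partial span (as
  reference repositories are dominated by partial sequences), and primer
  binding sites are stochastically disrupted with per-primer rates
  emulating the unequal universality of real panels (a disrupted site
  carries 1-4 mismatches; at three or more, in-silico amplification fails).

* :func:`make_community` draws a mixed community of distinct genera with
  uniform, log-normal, or explicit relative abundances.

* :func:`simulate_reads` emulates pooled multi-primer amplicon sequencing
  with pyrosequencing-like errors: each read draws a taxon by abundance
  and a primer by the taxon's amplification-efficiency row, takes the
  amplicon between the taxon's known binding-site coordinates (so the
  simulator never calls the ePCR module it is used to test), sequences
  ~400 bp from either amplicon end with the primer bases attached, and
  applies substitution errors plus homopolymer insertions/deletions.
  A truth table (read id, taxon, primer, orientation, error count)
  accompanies the reads.

The default per-primer amplification-efficiency profiles are deliberately
non-uniform — one taxon follows a strongly skewed single-template pattern
(38.3% of reads from primer C, 3.1% from primer B, the kind of spread seen
in real multi-primer amplifications), and one taxon fails to amplify with
primers E and F, reproducing the situation where a genus's reconstructed
16S stays short.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._dna import revcomp
from .panel import (
    CONSERVED_BLOCKS,
    canonical_anchor,
    default_panel,
    full_length_pair,
    fwd_site,
    rev_site,
)
from .seq_io import PrimerPair, ReferenceDB, SequenceRecord

_BASES = np.array(list("ACGT"))

#: per-pair probability that a reference's binding site is disrupted, for
#: building evaluation databases that emulate the spread of primer
#: universality across a real reference repository (pass to
#: :func:`make_refdb`; the default database applies no disruption so that
#: community templates are amplifiable by the whole panel)
SITE_DISRUPTION_SURVEY = {
    "A": 0.24, "B": 0.25, "C": 0.09, "D": 0.40, "E": 0.18, "F": 0.45,
    "27F-1492R": 0.15,
}


@dataclass
class ErrorModel:
    """Pyrosequencing-style read errors."""

    sub_rate: float = 0.002            # substitutions per base
    homopolymer_indel_rate: float = 0.004  # indels per homopolymer run (>=2)
    read_len_mean: float = 400.0
    read_len_sd: float = 30.0
    read_len_min: int = 150

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.homopolymer_indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")


@dataclass
class RefMeta:
    sites: dict[str, tuple[int, int]]       # pair name -> product interval
    disrupted: set[str] = field(default_factory=set)
    truncated: bool = False


@dataclass
class CommunityTaxon:
    record: SequenceRecord
    lineage: tuple[str, ...]
    species: str
    abundance: float
    sites: dict[str, tuple[int, int]]

    @property
    def genus(self) -> str:
        return self.lineage[-1]


@dataclass
class Community:
    taxa: list[CommunityTaxon]

    def __post_init__(self) -> None:
        total = sum(t.abundance for t in self.taxa)
        if any(t.abundance < 0 for t in self.taxa):
            raise ValueError("abundances must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")


def _conserved_mask() -> np.ndarray:
    anchor = canonical_anchor()
    mask = np.zeros(len(anchor), dtype=bool)
    for start, block in CONSERVED_BLOCKS.items():
        mask[start - 1 : start - 1 + len(block)] = True
    return mask


def _evolve_genus(
    rng: np.random.Generator, sub_p: float, indel_p: float
) -> tuple[str, np.ndarray, np.ndarray]:
    """One genus backbone: (sequence, anchor->new position map, conserved mask)."""
    anchor = canonical_anchor()
    conserved = _conserved_mask()
    out: list[str] = []
    out_conserved: list[bool] = []
    posmap = np.zeros(len(anchor) + 1, dtype=np.int64)
    for i, base in enumerate(anchor):
        posmap[i] = len(out)
        if conserved[i]:
            out.append(base)
            out_conserved.append(True)
            continue
        r = rng.random()
        if r < indel_p / 2:            # deletion
            continue
        if r < indel_p:                # insertion before the base
            out.append(str(rng.choice(_BASES)))
            out_conserved.append(False)
        if rng.random() < sub_p:
            alts = [b for b in "ACGT" if b != base]
            out.append(alts[rng.integers(3)])
        else:
            out.append(base)
        out_conserved.append(False)
    posmap[len(anchor)] = len(out)
    return "".join(out), posmap, np.array(out_conserved, dtype=bool)


def _speciate(seq: str, conserved: np.ndarray, rng: np.random.Generator,
              sub_p: float) -> str:
    arr = np.array(list(seq))
    hit = (~conserved) & (rng.random(arr.size) < sub_p)
    for i in np.nonzero(hit)[0]:
        alts = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alts[rng.integers(3)]
    return "".join(arr)


def _disrupt_site(
    seq: str, site: tuple[int, int], rng: np.random.Generator
) -> str:
    """Inject 1-4 substitutions into a binding site."""
    start, end = site
    k = int(rng.integers(1, 5))
    positions = rng.choice(np.arange(start, end), size=min(k, end - start),
                           replace=False)
    arr = list(seq)
    for p in positions:
        alts = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alts[rng.integers(3)]
    return "".join(arr)


def make_refdb(
    n_genera: int = 8,
    n_species: int = 3,
    seed: int = 0,
    genus_divergence: float = 0.12,
    species_divergence: float = 0.01,
    indel_rate: float = 0.004,
    partial_fraction: float = 0.0,
    site_disruption: Optional[dict[str, float]] = None,
    panel: Optional[Sequence[PrimerPair]] = None,
) -> tuple[ReferenceDB, dict[str, RefMeta]]:
    """Synthetic reference database with known primer-site coordinates.

    Returns the database plus per-reference metadata (site coordinates as
    0-based half-open product intervals, disrupted pairs, truncation).
    """
    rng = np.random.default_rng(seed)
    panel = list(default_panel() if panel is None else panel)
    pairs = panel + [full_length_pair()]
    disruption = {} if site_disruption is None else dict(site_disruption)
    records: list[SequenceRecord] = []
    lineage: dict[str, tuple[str, ...]] = {}
    species_map: dict[str, str] = {}
    meta: dict[str, RefMeta] = {}
    for gi in range(n_genera):
        gseq, posmap, conserved = _evolve_genus(rng, genus_divergence, indel_rate)
        genus = f"Genus{gi:02d}"
        lin = (
            "Bacteria",
            f"Phylum{gi % 4:02d}",
            f"Class{gi % 4:02d}_{gi % 2}",
            f"Order{gi:02d}",
            f"Family{gi:02d}",
            genus,
        )
        base_sites = {}
        for pair in pairs:
            fs = fwd_site(pair)
            rs = rev_site(pair)
            base_sites[pair.name] = (int(posmap[fs[0]]), int(posmap[rs[1]]))
        for sj in range(n_species):
            rid = f"REF_{genus}_sp{sj}"
            seq = _speciate(gseq, conserved, rng, species_divergence)
            m = RefMeta(sites=dict(base_sites))
            for pair in pairs:
                rate = disruption.get(pair.name, 0.0)
                if rng.random() < rate:
                    prod = m.sites[pair.name]
                    if rng.random() < 0.5:
                        site = (prod[0], prod[0] + len(pair.fwd_seq))
                    else:
                        site = (prod[1] - len(pair.rev_seq), prod[1])
                    seq = _disrupt_site(seq, site, rng)
                    m.disrupted.add(pair.name)
            if rng.random() < partial_fraction:
                a = int(rng.integers(0, len(seq) // 3))
                b = int(rng.integers(2 * len(seq) // 3, len(seq) + 1))
                seq = seq[a:b]
                m.truncated = True
                m.sites = {
                    name: (s - a, e - a)
                    for name, (s, e) in m.sites.items()
                    if s >= a and e <= b
                }
            records.append(SequenceRecord(rid, seq))
            lineage[rid] = lin
            species_map[rid] = f"{genus} species{sj}"
            meta[rid] = m
    refdb = ReferenceDB(records=records, lineage=lineage, species=species_map)
    return refdb, meta


def make_community(
    refdb: ReferenceDB,
    n_taxa: int,
    abundance_spec: Union[str, tuple, Sequence[float]] = "uniform",
    seed: int = 0,
    meta: Optional[dict[str, RefMeta]] = None,
    require_intact: bool = True,
) -> Community:
    """Draw a community of distinct genera from the reference database.

    ``abundance_spec``: ``"uniform"``, ``("lognormal", sigma)``, or an
    explicit abundance sequence of length ``n_taxa``.  With
    ``require_intact`` (and metadata available) only full-length references
    with no disrupted primer site are eligible, so every taxon is
    amplifiable by the whole panel.
    """
    rng = np.random.default_rng(seed)
    by_genus = refdb.by_genus()
    eligible: dict[str, SequenceRecord] = {}
    for genus, recs in by_genus.items():
        for rec in recs:
            if meta is not None and require_intact:
                m = meta[rec.id]
                if m.truncated or m.disrupted:
                    continue
            eligible[genus] = rec
            break
    if n_taxa > len(eligible):
        raise ValueError(
            f"requested {n_taxa} taxa but only {len(eligible)} eligible genera"
        )
    genera = list(eligible)
    picked = [genera[i] for i in rng.choice(len(genera), n_taxa, replace=False)]
    if isinstance(abundance_spec, str) and abundance_spec == "uniform":
        ab = np.full(n_taxa, 1.0 / n_taxa)
    elif isinstance(abundance_spec, tuple) and abundance_spec[0] == "lognormal":
        raw = rng.lognormal(0.0, float(abundance_spec[1]), size=n_taxa)
        ab = raw / raw.sum()
    else:
        ab = np.asarray(list(abundance_spec), dtype=float)
        if ab.size != n_taxa:
            raise ValueError("explicit abundances must match n_taxa")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError("explicit abundances must sum to 1")
    taxa = []
    for genus, a in zip(picked, ab):
        rec = eligible[genus]
        sites = meta[rec.id].sites if meta is not None else {}
        taxa.append(
            CommunityTaxon(
                record=rec,
                lineage=refdb.lineage[rec.id],
                species=refdb.species.get(rec.id, ""),
                abundance=float(a),
                sites=sites,
            )
        )
    return Community(taxa)


def default_efficiency_matrix(
    n_taxa: int, n_primers: int = 6, seed: int = 0
) -> np.ndarray:
    """Non-uniform per-taxon amplification efficiencies.

    Row 0 follows the skewed single-template pattern (C 38.3%, B 3.1%);
    the last row (when n_taxa >= 3) drops primers E and F entirely; other
    rows draw from a moderately concentrated Dirichlet.
    """
    rng = np.random.default_rng(seed)
    rows = []
    skewed = np.array([0.147, 0.031, 0.383, 0.147, 0.146, 0.146])[:n_primers]
    for i in range(n_taxa):
        if i == 0:
            rows.append(skewed / skewed.sum())
        elif i == n_taxa - 1 and n_taxa >= 3:
            weak = np.array([0.35, 0.30, 0.20, 0.15, 0.0, 0.0])[:n_primers]
            rows.append(weak / weak.sum())
        else:
            rows.append(rng.dirichlet(np.full(n_primers, 5.0)))
    return np.vstack(rows)


def _apply_errors(
    seq: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, int]:
    n_err = 0
    # homopolymer indels: one event per run of length >= 2
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= 2 and rng.random() < model.homopolymer_indel_rate:
            n_err += 1
            run = run + seq[i] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        i = j
    arr = list("".join(out))
    hits = np.nonzero(rng.random(len(arr)) < model.sub_rate)[0]
    for p in hits:
        alts = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alts[rng.integers(3)]
    n_err += hits.size
    return "".join(arr), n_err


def _qualities(n: int, rng: np.random.Generator) -> list[int]:
    base = 38.0 - 18.0 * np.arange(n) / max(1, n)
    q = base + rng.normal(0.0, 2.0, size=n)
    return [int(x) for x in np.clip(np.round(q), 2, 40)]


def simulate_reads(
    community: Community,
    panel: Sequence[PrimerPair],
    efficiency_matrix: np.ndarray,
    error_model: ErrorModel,
    n_reads: int,
    seed: int = 0,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate a pooled multi-primer amplicon run.

    Returns FASTQ-style records (primer bases attached at the 5' end,
    position-decaying qualities) and a truth table with one row per read.
    """
    rng = np.random.default_rng(seed)
    eff = np.asarray(efficiency_matrix, dtype=float).copy()
    if eff.shape != (len(community.taxa), len(panel)):
        raise ValueError(
            f"efficiency matrix shape {eff.shape} != "
            f"({len(community.taxa)}, {len(panel)})"
        )
    if np.any(eff < 0):
        raise ValueError("efficiencies must be non-negative")
    for ti, taxon in enumerate(community.taxa):
        for pi, pair in enumerate(panel):
            if pair.name not in taxon.sites:
                eff[ti, pi] = 0.0
        if eff[ti].sum() == 0:
            raise ValueError(
                f"taxon {taxon.record.id}: no primer can amplify it"
            )
    abundances = np.array([t.abundance for t in community.taxa])
    reads: list[SequenceRecord] = []
    truth_rows = []
    for ri in range(n_reads):
        ti = int(rng.choice(len(community.taxa), p=abundances / abundances.sum()))
        taxon = community.taxa[ti]
        w = eff[ti] / eff[ti].sum()
        pi = int(rng.choice(len(panel), p=w))
        pair = panel[pi]
        s, e = taxon.sites[pair.name]
        amplicon = taxon.record.bases[s:e]
        forward = bool(rng.random() < 0.5)
        if not forward:
            amplicon = revcomp(amplicon)
        L = int(
            np.clip(
                round(rng.normal(error_model.read_len_mean, error_model.read_len_sd)),
                error_model.read_len_min,
                len(amplicon),
            )
        )
        bases, n_err = _apply_errors(amplicon[:L], error_model, rng)
        rid = f"read{ri:06d}"
        reads.append(SequenceRecord(rid, bases, _qualities(len(bases), rng)))
        truth_rows.append(
            {
                "read_id": rid,
                "taxon": taxon.record.id,
                "genus": taxon.genus,
                "primer": pair.name,
                "orientation": "fwd" if forward else "rev",
                "n_errors": n_err,
            }
        )
    return reads, pd.DataFrame(truth_rows)
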