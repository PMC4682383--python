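"""Pipeline-wide thresholds.

Every threshold the pipeline applies is collected here so that a run report
can state exactly what was used.  The defaults are the pipeline's published
operating point:

* reads are trimmed by 25 bp at both ends (primer removal) and kept only if
  the trimmed length reaches 200 bp;
* a read is "confident" when its genus-level bootstrap score is >= 80, and a
  genus is "confident" with >= 10 confident reads;
* per-genus assembly requires overlaps of >= 100 bp at >= 98% identity;
* a bubble branch is discarded below a mean read coverage of 10; a minor
  nucleotide column is flagged at count >= 10 and a sequence pattern is kept
  at count >= 10;
* species are assigned at >= 97% alignment identity with an e-value cutoff
  of 0.01;
* in-silico PCR uses word size 3, at most 2 mismatches per primer, and
  per-pair insert-size ranges; amplified segments are stitched when they
  overlap by >= 10 bp and an assembly is called long at >= 1000 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class PipelineConfig:
    trim_len: int = 25            # bp removed from each read end
    min_read_len: int = 200       # post-trim length filter, bp
    conf_score: int = 80          # bootstrap score for a confident read
    min_conf_reads: int = 10      # confident reads for a confident genus
    asm_min_ovl: int = 100        # assembly minimum overlap, bp
    asm_min_id: float = 0.98      # assembly minimum overlap identity
    branch_min_cov: float = 10.0  # bubble branch mean coverage cutoff
    minor_min: int = 10           # minor-nucleotide column count
    pattern_min: int = 10         # sequence-pattern support count
    id_min_pct: float = 97.0      # species-call identity floor, %
    evalue: float = 0.01          # species-call e-value ceiling
    epcr_word: int = 3            # in-silico PCR hash word size
    epcr_mm: int = 2              # max mismatches per primer in ePCR
    stitch_min_ovl: int = 10      # amplicon stitching overlap, bp
    long_len: int = 1000          # "long assembly" threshold, bp
    bootstrap_n: int = 100        # bootstrap trials per read
    word_k: int = 8               # classifier word size
    edge_min_ovl: int = 40        # contig-graph adjacency overlap, bp
    edge_min_id: float = 0.95     # contig-graph adjacency identity
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("asm_min_id", "edge_min_id"):
                if not (0.0 < v <= 1.0):
                    raise ValueError(f"{f.name} must be in (0, 1], got {v}")
            elif f.name == "rng_seed":
                continue
            elif v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
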