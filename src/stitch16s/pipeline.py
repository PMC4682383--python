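"""End-to-end pipeline driver.

Wires the stages: demultiplex -> trim/filter -> classify -> per-genus
assembly -> bubble/variant post-processing -> species assignment ->
summary and bias metrics.  Every threshold comes from one
:class:`~stitch16s.config.PipelineConfig`; the run report records the
configuration, the seed, and read counts in and out of each stage, so a
rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import assemble, classify, identify, metrics, postprocess, preprocess
from .assemble import Contig
from .config import PipelineConfig
from .identify import SpeciesCall
from .metrics import GenusResult, SampleRunStats
from .seq_io import (
    PrimerPair,
    ReferenceDB,
    SequenceRecord,
    write_fasta,
)

log = logging.getLogger(__name__)


@dataclass
class GenusOutput:
    genus: str
    contigs: list[Contig]
    longest: Contig
    lcl: int
    mrl: float
    ratio: float
    species_call: Optional[SpeciesCall] = None


@dataclass
class RunResult:
    sample: str
    cfg: PipelineConfig
    seed: int
    stats: SampleRunStats
    genus_outputs: dict[str, GenusOutput]
    bias: dict[str, int]
    assignments: list[classify.TaxAssignment]
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    reads: Sequence[SequenceRecord],
    panel: Sequence[PrimerPair],
    refdb: ReferenceDB,
    cfg: Optional[PipelineConfig] = None,
    sample: str = "S",
    seed: Optional[int] = None,
    outdir: Optional[str | Path] = None,
) -> RunResult:
    """Run the full pipeline on one sample's reads."""
    cfg = cfg or PipelineConfig()
    seed = cfg.rng_seed if seed is None else seed
    if not reads:
        raise RuntimeError("preprocess: no input reads")
    stage_counts = {"raw_reads": len(reads)}

    try:
        labelled = preprocess.demultiplex(reads, panel)
        trimmed, counts = preprocess.trim_and_filter(labelled, cfg)
    except Exception as exc:
        raise RuntimeError(f"preprocess: {exc}") from exc
    stage_counts.update(
        trimmed_reads=counts["kept"], dropped_reads=counts["dropped"]
    )
    log.info("%s: %d raw -> %d trimmed reads", sample, len(reads), counts["kept"])

    try:
        model = classify.train(refdb, cfg.word_k)
        assignments = classify.classify_reads(model, trimmed, cfg, seed=seed)
        confident = classify.call_confident(assignments, cfg)
    except Exception as exc:
        raise RuntimeError(f"classify: {exc}") from exc
    stage_counts.update(
        confident_reads=confident.n_confident_reads,
        total_genera=confident.n_total_genera,
        confident_genera=len(confident.by_genus),
    )
    log.info(
        "%s: %d confident reads, %d/%d confident genera",
        sample, confident.n_confident_reads, len(confident.by_genus),
        confident.n_total_genera,
    )

    reads_by_id = {t.record.id: t for t in trimmed}
    read_labels = {t.record.id: t.primer_label for t in trimmed}
    genus_outputs: dict[str, GenusOutput] = {}
    genus_results: list[GenusResult] = []
    for genus in sorted(confident.by_genus):
        members = [reads_by_id[r] for r in confident.by_genus[genus]]
        try:
            graph = assemble.assemble_genus(members, cfg)
            contigs = postprocess.postprocess_genus(graph, cfg)
        except Exception as exc:
            raise RuntimeError(f"assemble[{genus}]: {exc}") from exc
        lcl, mrl, ratio = assemble.contig_stats(contigs, members)
        longest = max(contigs, key=lambda c: (len(c), c.id))
        try:
            call, _ = identify.assign_species(
                SequenceRecord(f"{sample}_{genus}_longest", longest.consensus),
                refdb, cfg, genus=genus,
            )
        except Exception as exc:
            raise RuntimeError(f"identify[{genus}]: {exc}") from exc
        out = GenusOutput(genus, contigs, longest, lcl, mrl, ratio, call)
        genus_outputs[genus] = out
        genus_results.append(
            GenusResult(
                genus=genus,
                longest_contig_len=lcl,
                lcl_mrl_ratio=ratio,
                assembled=len(longest.members) >= 2,
                species_identity_pct=call.identity_pct,
            )
        )

    stats = SampleRunStats(
        sample=sample,
        raw_reads=len(reads),
        trimmed_reads=counts["kept"],
        confident_reads=confident.n_confident_reads,
        total_genus=confident.n_total_genera,
        confident_genus=len(confident.by_genus),
        genus_results=genus_results,
    )
    try:
        bias = metrics.primer_bias(
            confident, read_labels, [p.name for p in panel]
        ) if confident.by_genus else {}
    except Exception as exc:
        raise RuntimeError(f"metrics: {exc}") from exc

    result = RunResult(
        sample=sample, cfg=cfg, seed=seed, stats=stats,
        genus_outputs=genus_outputs, bias=bias, assignments=assignments,
        stage_counts=stage_counts,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for genus, out in sorted(result.genus_outputs.items()):
        write_fasta(
            [
                SequenceRecord(f"{result.sample}_{genus}_{c.id}", c.consensus)
                for c in out.contigs
            ],
            outdir / f"{genus}.contigs.fasta",
        )
    with open(outdir / "species.tsv", "w") as fh:
        fh.write("genus\tcontig_len\tspecies\tidentity_pct\tsubject\n")
        for genus, out in sorted(result.genus_outputs.items()):
            c = out.species_call
            fh.write(
                f"{genus}\t{out.lcl}\t{c.species}\t{c.identity_pct:.1f}"
                f"\t{c.subject_id or '-'}\n"
            )
    metrics.summary_table([result.stats]).to_csv(outdir / "summary.tsv", sep="\t")
    with open(outdir / "bias.tsv", "w") as fh:
        fh.write("primer\tpct_missed\n")
        for p, v in sorted(result.bias.items()):
            fh.write(f"{p}\t{v}\n")
    with open(outdir / "classifications.tsv", "w") as fh:
        fh.write("read_id\tlineage\tscore\tprimer\n")
        for a in result.assignments:
            fh.write(
                f"{a.read_id}\t{';'.join(a.lineage)}\t{a.score}"
                f"\t{a.primer_label or '-'}\n"
            )
    report = {
        "sample": result.sample,
        "seed": result.seed,
        "config": result.cfg.to_dict(),
        "stage_counts": result.stage_counts,
    }
    with open(outdir / "run.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
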