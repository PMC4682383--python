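"""Word-based naive-Bayes taxonomy classification with bootstrap confidence.

The classifier follows the standard published estimator for k-mer naive
Bayes taxonomy assignment (Wang-style): with N training sequences of which
n(w) contain word w, the word prior is

    P(w) = (n(w) + 0.5) / (N + 1)

and for a genus with M sequences of which m(w) contain w, the
genus-conditional probability is

    P(w | G) = (m(w) + P(w)) / (M + 1).

A read is assigned to the genus maximising the joint log likelihood of its
distinct words (k = 8 by default).  Confidence is the percentage of
bootstrap trials agreeing with that assignment, each trial resampling
ceil(W / k) of the read's W words with replacement.  Reads scoring >= 80
are "confident"; genera with >= 10 confident reads are "confident genera".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional, Sequence

import numpy as np

from ._dna import kmer_codes
from .config import PipelineConfig
from .preprocess import TrimmedRead
from .seq_io import ReferenceDB

UNCLASSIFIED = "unclassified"


@dataclass
class ClassifierModel:
    word_k: int
    genera: list[str]
    log_cond: np.ndarray          # (n_genera, 4**word_k) log P(w|G)
    lineages: dict[str, tuple[str, ...]]

    def genus_index(self, genus: str) -> int:
        return self.genera.index(genus)


@dataclass
class TaxAssignment:
    read_id: str
    lineage: tuple[str, ...]
    score: int                    # bootstrap % agreeing at genus, 0-100
    primer_label: Optional[str] = None

    @property
    def genus(self) -> str:
        return self.lineage[-1]

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 100:
            raise ValueError(f"score {self.score} outside 0-100")


@dataclass
class ConfidentGenusSet:
    by_genus: dict[str, list[str]]   # genus -> confident read ids
    n_total_genera: int              # distinct genera among all assignments
    n_confident_reads: int           # reads passing the score filter
    n_assigned_reads: int            # all classified reads

    @property
    def genera(self) -> list[str]:
        return list(self.by_genus)


def train(refdb: ReferenceDB, word_k: int = 8) -> ClassifierModel:
    """Train the word model from a reference database (deterministic)."""
    if not refdb.records:
        raise ValueError("reference database is empty")
    vocab = 4 ** word_k
    groups = refdb.by_genus()
    genera = list(groups)
    n_total = len(refdb.records)

    # n(w): number of training sequences containing w
    n_w = np.zeros(vocab, dtype=np.float64)
    seq_words: dict[str, np.ndarray] = {}
    for rec in refdb.records:
        codes = kmer_codes(rec.bases, word_k)
        words = np.unique(codes[codes >= 0])
        if words.size == 0:
            raise ValueError(f"reference {rec.id} yields no usable {word_k}-mers")
        seq_words[rec.id] = words
        n_w[words] += 1.0
    prior = (n_w + 0.5) / (n_total + 1.0)

    log_cond = np.empty((len(genera), vocab), dtype=np.float32)
    for gi, genus in enumerate(genera):
        members = groups[genus]
        m_w = np.zeros(vocab, dtype=np.float64)
        for rec in members:
            m_w[seq_words[rec.id]] += 1.0
        log_cond[gi] = np.log((m_w + prior) / (len(members) + 1.0))

    lineages = {}
    for genus, members in groups.items():
        lineages[genus] = refdb.lineage[members[0].id]
    return ClassifierModel(word_k, genera, log_cond, lineages)


def classify_read(
    model: ClassifierModel,
    read: TrimmedRead,
    n_bootstrap: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> TaxAssignment:
    """Assign a read to a genus with a bootstrap confidence score.

    Reads shorter than the word size (or with no valid words) come back
    unclassified with score 0.  With the same generator state the output is
    identical run to run.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rec = read.record
    codes = kmer_codes(rec.bases, model.word_k)
    words = np.unique(codes[codes >= 0])
    if words.size == 0:
        return TaxAssignment(
            rec.id, (UNCLASSIFIED,), 0, primer_label=read.primer_label
        )
    L = model.log_cond[:, words].astype(np.float64)   # (G, W)
    full = L.sum(axis=1)
    gi = int(np.argmax(full))
    n_sub = ceil(words.size / model.word_k)
    idx = rng.integers(0, words.size, size=(n_bootstrap, n_sub))
    boot = L[:, idx].sum(axis=2)                      # (G, n_bootstrap)
    agree = int(np.sum(np.argmax(boot, axis=0) == gi))
    score = round(100.0 * agree / n_bootstrap)
    genus = model.genera[gi]
    return TaxAssignment(
        rec.id, model.lineages[genus], score, primer_label=read.primer_label
    )


def classify_reads(
    model: ClassifierModel,
    reads: Sequence[TrimmedRead],
    cfg: PipelineConfig,
    seed: Optional[int] = None,
) -> list[TaxAssignment]:
    """Classify a batch of reads with one seeded generator."""
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    return [classify_read(model, r, cfg.bootstrap_n, rng) for r in reads]


def call_confident(
    assignments: Sequence[TaxAssignment], cfg: PipelineConfig
) -> ConfidentGenusSet:
    """Apply the confident-read and confident-genus filters."""
    classified = [a for a in assignments if a.genus != UNCLASSIFIED]
    total_genera = {a.genus for a in classified}
    confident = [a for a in classified if a.score >= cfg.conf_score]
    by_genus: dict[str, list[str]] = {}
    for a in confident:
        by_genus.setdefault(a.genus, []).append(a.read_id)
    by_genus = {
        g: ids for g, ids in by_genus.items() if len(ids) >= cfg.min_conf_reads
    }
    return ConfidentGenusSet(
        by_genus=by_genus,
        n_total_genera=len(total_genera),
        n_confident_reads=len(confident),
        n_assigned_reads=len(classified),
    )
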