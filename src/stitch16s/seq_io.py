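"""Sequence, taxonomy and primer-panel input/output.

Canonical internal records:

* :class:`SequenceRecord` — one read or reference sequence.
* :class:`PrimerPair` — one panel member, named by its 1-based positions on
  the canonical 16S coordinate system (e.g. ``8F-534R``).
* :class:`ReferenceDB` — reference 16S sequences with lineages down to genus
  and optional species names.

FASTA/FASTQ parsing is delegated to Biopython; this module only normalises
records (upper case, U->T) and enforces the package's invariants (unique
ids, quality length == sequence length).

Coordinate convention: primer *names* and all printed reports are 1-based
inclusive; internal slicing is 0-based half-open.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from ._dna import IUPAC_SETS

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

_DISPLAY_RE = re.compile(r"^(\d+)F-(\d+)R$")


@dataclass
class SequenceRecord:
    """One read or reference sequence."""

    id: str
    bases: str
    quals: Optional[list[int]] = None
    primer_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"{self.id}: quality length {len(self.quals)} != "
                f"sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class PrimerPair:
    """A named primer pair with positions parsed from its display name.

    ``fwd_pos``/``rev_pos`` are 1-based inclusive coordinates of the
    *outermost* bases of the two binding sites, so the expected product
    span is ``rev_pos - fwd_pos + 1``.
    """

    name: str
    display: str
    fwd_seq: str
    rev_seq: str
    insert_min: int
    insert_max: int
    fwd_pos: int = field(init=False)
    rev_pos: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.fwd_seq or not self.rev_seq:
            raise ValueError(f"primer {self.name}: empty sequence")
        for s in (self.fwd_seq, self.rev_seq):
            bad = set(s.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"primer {self.name}: non-IUPAC bases {bad}")
        self.fwd_seq = self.fwd_seq.upper()
        self.rev_seq = self.rev_seq.upper()
        m = _DISPLAY_RE.match(self.display)
        if not m:
            raise ValueError(
                f"primer display {self.display!r} does not match '<int>F-<int>R'"
            )
        self.fwd_pos = int(m.group(1))
        self.rev_pos = int(m.group(2))
        if self.fwd_pos >= self.rev_pos:
            raise ValueError(
                f"primer {self.display}: forward position must precede reverse"
            )
        if self.insert_min > self.insert_max:
            raise ValueError(f"primer {self.name}: insert_min > insert_max")


@dataclass
class ReferenceDB:
    """Reference sequences plus genus-level lineages and optional species."""

    records: list[SequenceRecord]
    lineage: dict[str, tuple[str, ...]]
    species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.id not in self.lineage:
                raise ValueError(f"reference {rec.id} has no lineage entry")
            lin = self.lineage[rec.id]
            if not lin or any(not r for r in lin):
                raise ValueError(f"reference {rec.id}: empty lineage rank")

    def genus_of(self, ref_id: str) -> str:
        return self.lineage[ref_id][-1]

    @property
    def genera(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(self.genus_of(rec.id), None)
        return list(seen)

    def by_genus(self) -> dict[str, list[SequenceRecord]]:
        out: dict[str, list[SequenceRecord]] = {}
        for rec in self.records:
            out.setdefault(self.genus_of(rec.id), []).append(rec)
        return out


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_sequences(path: str | Path, fmt: Optional[str] = None) -> list[SequenceRecord]:
    """Read FASTA or FASTQ into :class:`SequenceRecord` list.

    The format is inferred from the file suffix when not given.  Bases are
    upper-cased and U is mapped to T; record order is preserved; duplicate
    ids raise.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), fmt):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            quals = None
            if fmt == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            out.append(SequenceRecord(rec.id, _normalise(str(rec.seq)), quals))
    except ValueError:
        raise
    except Exception as exc:  # Biopython raises assorted parse errors
        raise ValueError(f"{path}: malformed {fmt} record ({exc})") from exc
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quals is None:
                raise ValueError(f"{rec.id}: cannot write FASTQ without qualities")
            q = "".join(chr(min(93, max(0, s)) + 33) for s in rec.quals)
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{q}\n")


# ---------------------------------------------------------------------------
# primer panel

_PANEL_COLS = ("name", "display", "fwd_seq", "rev_seq", "insert_min", "insert_max")


def load_primer_panel(path: str | Path) -> list[PrimerPair]:
    """Load a primer panel from TSV (with header) or JSON (list of objects).

    Required fields: name, display, fwd_seq, rev_seq, insert_min, insert_max.
    Panel order is preserved.
    """
    path = Path(path)
    rows: list[dict]
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
        header = lines[0].split("\t")
        missing = set(_PANEL_COLS) - set(header)
        if missing:
            raise ValueError(f"{path}: panel missing columns {sorted(missing)}")
        rows = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
    panel = [
        PrimerPair(
            name=str(r["name"]),
            display=str(r["display"]),
            fwd_seq=str(r["fwd_seq"]),
            rev_seq=str(r["rev_seq"]),
            insert_min=int(r["insert_min"]),
            insert_max=int(r["insert_max"]),
        )
        for r in rows
    ]
    names = [p.name for p in panel]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate panel member names")
    return panel


def write_primer_panel(panel: Iterable[PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PANEL_COLS) + "\n")
        for p in panel:
            fh.write(
                f"{p.name}\t{p.display}\t{p.fwd_seq}\t{p.rev_seq}"
                f"\t{p.insert_min}\t{p.insert_max}\n"
            )


# ---------------------------------------------------------------------------
# taxonomy

def load_taxonomy(path: str | Path) -> tuple[dict[str, tuple[str, ...]], dict[str, str]]:
    """Load a taxonomy TSV: ``id <TAB> k;p;c;o;f;g [<TAB> species]``.

    Returns (lineage map, species map).  Lineages shorter than six ranks are
    rejected; extra ranks beyond genus are ignored.
    """
    lineage: dict[str, tuple[str, ...]] = {}
    species: dict[str, str] = {}
    for n, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{n}: expected 'id<TAB>lineage'")
        sid = parts[0].strip()
        ranks = tuple(r.strip() for r in parts[1].split(";") if r.strip())
        if len(ranks) < len(RANKS):
            raise ValueError(
                f"{path}:{n}: lineage for {sid} has {len(ranks)} ranks, "
                f"need {len(RANKS)} (kingdom..genus)"
            )
        lineage[sid] = ranks[: len(RANKS)]
        if len(parts) > 2 and parts[2].strip():
            species[sid] = parts[2].strip()
    return lineage, species


def load_reference_db(
    fasta_path: str | Path, taxonomy_path: str | Path
) -> ReferenceDB:
    records = read_sequences(fasta_path, "fasta")
    lineage, species = load_taxonomy(taxonomy_path)
    return ReferenceDB(records=records, lineage=lineage, species=species)
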