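"""Reading, validation and QC of species-labeled barcode alignments.

Barcode datasets arrive as aligned FASTA with the species name encoded in
the header.  This module enforces the upstream quality rules applied to
repository sequences before any divergence analysis: selection of the modal
(most frequent) ungapped sequence length, open-reading-frame / stop-codon
screening for protein-coding markers, and codon-position partitioning for
the saturation analysis.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_NUCLEOTIDES = set("ACGTRYSWKMBDHVN")
GAP = "-"
ALPHABET = IUPAC_NUCLEOTIDES | {GAP}

#: Markers treated as protein-coding (reading-frame checks apply).
CODING_MARKERS = {"COI", "Cytb"}

#: NCBI translation table used by default: vertebrate mitochondrial.
DEFAULT_CODE_TABLE = 2


class AlignmentError(ValueError):
    """Raised when records cannot form a valid alignment."""


class ValidationError(ValueError):
    """Raised when a sequence contains illegal characters."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned barcode sequence with its repository species label."""

    id: str
    species: str
    residues: str
    marker: str = "other"

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if not self.residues:
            raise ValidationError(f"{self.id}: residues must be non-empty")
        up = self.residues.upper()
        for pos, ch in enumerate(up, start=1):
            if ch not in ALPHABET:
                raise ValidationError(
                    f"{self.id}: illegal character {ch!r} at column {pos}"
                )
        object.__setattr__(self, "residues", up)

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)


@dataclass
class BarcodeAlignment:
    """Equal-length, species-labeled sequences for one marker."""

    records: list[SequenceRecord]
    marker: str = "other"

    def __post_init__(self):
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        ids = [r.id for r in self.records]
        dupes = [i for i, c in collections.Counter(ids).items() if c > 1]
        if dupes:
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        length = len(self.records[0].residues)
        bad = [r.id for r in self.records if len(r.residues) != length]
        if bad:
            raise AlignmentError(
                f"records with length != {length}: {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species_of(self) -> dict[str, str]:
        return {r.id: r.species for r in self.records}

    def species(self) -> list[str]:
        """Distinct species labels in input order."""
        seen = dict.fromkeys(r.species for r in self.records)
        return list(seen)

    def subset_columns(self, columns: list[int]) -> "BarcodeAlignment":
        """New alignment restricted to the given 1-based columns."""
        idx = [c - 1 for c in columns]
        recs = [
            replace(r, residues="".join(r.residues[i] for i in idx))
            for r in self.records
        ]
        return BarcodeAlignment(records=recs, marker=self.marker)


@dataclass(frozen=True)
class CodonPartition:
    """A set of 1-based alignment columns for one codon-position class."""

    frame_offset: int
    partition: str  # whole | pos12 | pos3
    column_indices: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        cols = tuple(self.column_indices)
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("column_indices must be strictly increasing")
        object.__setattr__(self, "column_indices", cols)


def default_label_rule(header: str) -> str:
    """Species = token after the first '|', else the full header."""
    if "|" in header:
        return header.split("|", 1)[1].strip()
    return header.strip()


def read_alignment(path, marker: str = "other", label_rule=None) -> BarcodeAlignment:
    """Read an aligned FASTA file into a validated :class:`BarcodeAlignment`.

    ``label_rule`` maps the full FASTA description to a species label;
    the default takes the token after the first ``|``.
    """
    label_rule = label_rule or default_label_rule
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.description.split("|", 1)[0].split()[0]
                if rec.description
                else rec.id,
                species=label_rule(rec.description),
                residues=str(rec.seq),
                marker=marker,
            )
        )
    if len(records) < 2:
        raise AlignmentError(f"{path}: fewer than 2 FASTA records")
    return BarcodeAlignment(records=records, marker=marker)


def write_alignment(aln: BarcodeAlignment, path) -> None:
    """Write FASTA with ``id|species`` headers (round-trips with reading)."""
    recs = [
        SeqRecord(Seq(r.residues), id=f"{r.id}|{r.species}", description="")
        for r in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def select_modal_length(records):
    """Keep records whose ungapped length is the modal length.

    Repository barcode fragments come in several lengths; only the most
    frequently occurring length is retained for analysis.  Ties are broken
    toward the longer length (retains more signal).

    Returns ``(kept, discarded)`` where ``discarded`` is a list of
    ``(record, ungapped_length)`` pairs.
    """
    if not records:
        return [], []
    counts = collections.Counter(r.ungapped_length for r in records)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
    kept = [r for r in records if r.ungapped_length == best]
    discarded = [
        (r, r.ungapped_length) for r in records if r.ungapped_length != best
    ]
    return kept, discarded


def check_reading_frame(
    aln: BarcodeAlignment,
    code: int = DEFAULT_CODE_TABLE,
    frame_offset: int = 0,
):
    """Scan protein-coding sequences for internal stop codons.

    Codons containing a gap or any ambiguity code are skipped (gapped
    repository sequences are deliberately retained upstream).  Returns a
    list of ``(record_id, codon_index)`` violations, 1-based codon index;
    an empty list means every record passes.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    if aln.marker not in CODING_MARKERS:
        raise ValueError(
            f"reading-frame check applies to coding markers, not {aln.marker!r}"
        )
    stops = set(CodonTable.unambiguous_dna_by_id[code].stop_codons)
    violations = []
    for rec in aln.records:
        seq = rec.residues
        codon_no = 0
        for start in range(frame_offset, len(seq) - 2, 3):
            codon_no += 1
            codon = seq[start : start + 3]
            if any(ch not in "ACGT" for ch in codon):
                continue  # gap/ambiguity: skipped, never a violation
            if codon in stops:
                violations.append((rec.id, codon_no))
    return violations


def codon_partition_columns(length: int, frame_offset: int):
    """1-based coding columns split into (pos12, pos3) for a frame."""
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    pos12, pos3 = [], []
    for col in range(frame_offset + 1, length + 1):
        if (col - frame_offset) % 3 == 0:
            pos3.append(col)
        else:
            pos12.append(col)
    return pos12, pos3


def partition_codon_positions(aln: BarcodeAlignment, frame_offset: int = 0):
    """Split a coding alignment into codon positions 1+2 and position 3."""
    if aln.marker not in CODING_MARKERS:
        raise ValueError(
            f"codon partitioning applies to coding markers, not {aln.marker!r}"
        )
    pos12, pos3 = codon_partition_columns(aln.length, frame_offset)
    return aln.subset_columns(pos12), aln.subset_columns(pos3)


def qc_report(aln: BarcodeAlignment, frame_offset: int = 0,
              code: int = DEFAULT_CODE_TABLE):
    """Per-record QC table as a list of dicts (TSV-ready)."""
    kept, discarded = select_modal_length(aln.records)
    kept_ids = {r.id for r in kept}
    stop_hits: dict[str, list[int]] = {}
    if aln.marker in CODING_MARKERS:
        for rid, codon in check_reading_frame(aln, code, frame_offset):
            stop_hits.setdefault(rid, []).append(codon)
    rows = []
    for r in aln.records:
        rows.append(
            {
                "id": r.id,
                "species": r.species,
                "ungapped_length": r.ungapped_length,
                "kept": r.id in kept_ids,
                "stop_codon_violations": ",".join(
                    str(c) for c in stop_hits.get(r.id, [])
                ),
            }
        )
    return rows
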