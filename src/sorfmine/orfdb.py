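"""Three-frame sORF enumeration and microprotein database construction.

Transcripts are handled in 0-based half-open transcript coordinates, 5'->3'.
An emitted sORF spans ``[start, end)`` where the final codon is the stop codon;
the translated product excludes the stop and applies the initiator-methionine
convention (position 1 is Met even for near-cognate starts such as CTG/GTG).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG", "CTG", "GTG"})
DEFAULT_MIN_AA = 7
DEFAULT_MAX_AA = 200

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in _STANDARD_TABLE.stop_codons})

_DNA_RE = re.compile(r"^[ACGTN]*$")
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


class IntegrityError(ValueError):
    """Raised when merged databases carry inconsistent accessions."""


@dataclass(frozen=True)
class Transcript:
    """A transcript sequence with minimal annotation.

    ``cds`` is a 0-based half-open ``(cds_start, cds_end)`` interval in
    transcript coordinates; it must be present iff ``biotype == "coding"``.
    """

    transcript_id: str
    biotype: str
    sequence: str
    gene_id: str | None = None
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.biotype not in ("coding", "noncoding", "novel"):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not self.sequence:
            raise ValueError("transcript sequence must be non-empty")
        if self.sequence != self.sequence.upper() or not _DNA_RE.match(self.sequence):
            raise ValueError("sequence must be uppercase over {A,C,G,T,N}")
        if (self.biotype == "coding") != (self.cds is not None):
            raise ValueError("cds must be present iff biotype is 'coding'")
        if self.cds is not None:
            cs, ce = self.cds
            if not (0 <= cs < ce <= len(self.sequence)):
                raise ValueError(f"cds {self.cds} out of bounds for {self.transcript_id}")
            if (ce - cs) % 3 != 0 or (ce - cs) < 6:
                raise ValueError("cds length must be a multiple of 3 and >= 6")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SORF:
    """A small ORF on a transcript; ``[start, end)`` includes the stop codon."""

    sorf_id: str
    transcript_id: str
    start: int
    end: int
    frame: int
    start_codon: str
    aa_sequence: str
    category: str | None = None

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("sORF span must be a multiple of 3")
        if self.frame != self.start % 3:
            raise ValueError("frame must equal start mod 3")
        if len(self.aa_sequence) != (self.end - self.start) // 3 - 1:
            raise ValueError("aa_sequence length inconsistent with coordinates")

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)


@dataclass
class DatabaseEntry:
    """One searchable protein entry of the merged microprotein database."""

    accession: str
    aa_sequence: str
    source: str = "rnaseq_3frame"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.aa_sequence or not _AA_RE.match(self.aa_sequence):
            raise ValueError(
                f"entry {self.accession}: aa_sequence must be non-empty over the "
                "20-letter alphabet plus X"
            )


def translate(dna: str, init_met: bool = False) -> str:
    """Translate ``dna`` with the standard codon table.

    Codons containing N yield X; stop codons yield ``*`` (truncation is the
    caller's concern). With ``init_met`` the first residue is forced to M
    regardless of codon (near-cognate start convention).
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not a multiple of 3")
    if not _DNA_RE.match(dna):
        raise ValueError("sequence must be uppercase over {A,C,G,T,N}")
    residues = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        residues.append(_CODON_TO_AA.get(codon, "X"))
    if init_met and residues:
        residues[0] = "M"
    return "".join(residues)


def find_sorfs(
    transcript: Transcript,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    min_aa: int = DEFAULT_MIN_AA,
    max_aa: int = DEFAULT_MAX_AA,
    emit_all_starts: bool = False,
) -> list[SORF]:
    """Enumerate sORFs in all three reading frames of ``transcript``.

    Each sORF starts at a codon in ``start_codons`` and runs to the first
    in-frame stop. With ``emit_all_starts=False`` only the most upstream
    qualifying start per (frame, stop) pair is emitted. ORFs whose stop lies
    beyond the transcript 3' end are discarded. Output is sorted by
    ``(start, end)``.
    """
    starts = frozenset(start_codons)
    if not starts:
        raise ValueError("start_codons must be non-empty")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = transcript.sequence
    out: list[SORF] = []
    for frame in range(3):
        pending: list[int] = []  # candidate start positions since last stop
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                end = pos + 3
                chosen = pending if emit_all_starts else pending[:1]
                for start in chosen:
                    aa_len = (end - start) // 3 - 1
                    if not (min_aa <= aa_len <= max_aa):
                        continue
                    aa = translate(seq[start : end - 3], init_met=True)
                    out.append(
                        SORF(
                            sorf_id=f"{transcript.transcript_id}:{start}-{end}:{start % 3}",
                            transcript_id=transcript.transcript_id,
                            start=start,
                            end=end,
                            frame=start % 3,
                            start_codon=seq[start : start + 3],
                            aa_sequence=aa,
                        )
                    )
                pending = []
            elif codon in starts:
                pending.append(pos)
        # pending starts with no in-frame stop are dropped (unverifiable 3' end)
    out.sort(key=lambda s: (s.start, s.end))
    return out


def build_database(
    transcripts: Sequence[Transcript],
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    min_aa: int = DEFAULT_MIN_AA,
    max_aa: int = DEFAULT_MAX_AA,
    emit_all_starts: bool = False,
) -> list[DatabaseEntry]:
    """Three-frame-translate all transcripts into database entries."""
    ids = [t.transcript_id for t in transcripts]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript_id(s): {dupes}")
    entries: list[DatabaseEntry] = []
    for transcript in transcripts:
        for sorf in find_sorfs(
            transcript,
            start_codons=start_codons,
            min_aa=min_aa,
            max_aa=max_aa,
            emit_all_starts=emit_all_starts,
        ):
            entries.append(
                DatabaseEntry(
                    accession=sorf.sorf_id,
                    aa_sequence=sorf.aa_sequence,
                    source="rnaseq_3frame",
                    metadata={
                        "transcript_id": sorf.transcript_id,
                        "start": sorf.start,
                        "end": sorf.end,
                        "frame": sorf.frame,
                        "start_codon": sorf.start_codon,
                    },
                )
            )
    return entries


def merge_databases(
    sets: Sequence[Sequence[DatabaseEntry]], dedup: bool = True
) -> list[DatabaseEntry]:
    """Concatenate entry sets; with ``dedup`` keep one entry per aa_sequence.

    The first-seen accession is retained and the sources of collapsed
    duplicates are recorded under ``metadata["sources"]``. Distinct sequences
    sharing an accession raise :class:`IntegrityError`.
    """
    seen_acc: dict[str, str] = {}
    merged: list[DatabaseEntry] = []
    by_seq: dict[str, DatabaseEntry] = {}
    for entry_set in sets:
        for entry in entry_set:
            prior = seen_acc.get(entry.accession)
            if prior is not None and prior != entry.aa_sequence:
                raise IntegrityError(
                    f"accession {entry.accession} maps to conflicting sequences"
                )
            seen_acc[entry.accession] = entry.aa_sequence
            if not dedup:
                merged.append(entry)
                continue
            kept = by_seq.get(entry.aa_sequence)
            if kept is None:
                kept = DatabaseEntry(
                    accession=entry.accession,
                    aa_sequence=entry.aa_sequence,
                    source=entry.source,
                    metadata={**entry.metadata, "sources": [entry.source]},
                )
                by_seq[entry.aa_sequence] = kept
                merged.append(kept)
            elif entry.source not in kept.metadata["sources"]:
                kept.metadata["sources"].append(entry.source)
    return merged


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_database_fasta(entries: Sequence[DatabaseEntry], path: str | Path) -> None:
    """Write entries with structured headers acc|transcript|span|frame|codon|source."""
    records = []
    for e in entries:
        m = e.metadata
        header = "|".join(
            [
                e.accession,
                str(m.get("transcript_id", "-")),
                f"{m.get('start', '-')}-{m.get('end', '-')}",
                str(m.get("frame", "-")),
                str(m.get("start_codon", "-")),
                e.source,
            ]
        )
        records.append(SeqRecord(Seq(e.aa_sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_database_fasta(path: str | Path, source: str | None = None) -> list[DatabaseEntry]:
    """Read a protein FASTA; structured sorfmine headers are decoded, plain
    headers become entries with ``source`` (default ``public_external``)."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) == 6:
            acc, tid, span, frame, codon, src = fields
            start_s, _, end_s = span.partition("-")
            meta: dict = {"transcript_id": tid, "start_codon": codon}
            if start_s.isdigit() and end_s.isdigit():
                meta["start"], meta["end"] = int(start_s), int(end_s)
            if frame.isdigit():
                meta["frame"] = int(frame)
            entries.append(
                DatabaseEntry(accession=acc, aa_sequence=str(rec.seq), source=src, metadata=meta)
            )
        else:
            entries.append(
                DatabaseEntry(
                    accession=rec.id,
                    aa_sequence=str(rec.seq),
                    source=source or "public_external",
                )
            )
    return entries


def read_transcripts(fasta_path: str | Path, annotation_path: str | Path) -> list[Transcript]:
    """Load transcripts from FASTA plus a TSV annotation.

    The annotation carries columns transcript_id, gene_id, biotype,
    cds_start, cds_end (cds columns empty for non-coding biotypes).
    """
    import pandas as pd

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"transcript_id": str})
    by_id: Mapping[str, str] = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    transcripts = []
    for row in ann.itertuples(index=False):
        tid = row.transcript_id
        if tid not in by_id:
            raise ValueError(f"transcript {tid} annotated but absent from FASTA")
        cds = None
        if row.biotype == "coding":
            cds = (int(row.cds_start), int(row.cds_end))
        gene = getattr(row, "gene_id", None)
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=None if gene in (None, "") or gene != gene else str(gene),
                biotype=str(row.biotype),
                sequence=by_id[tid],
                cds=cds,
            )
        )
    return transcripts


def write_transcripts(
    transcripts: Sequence[Transcript], fasta_path: str | Path, annotation_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    lines = ["transcript_id\tgene_id\tbiotype\tcds_start\tcds_end"]
    for t in transcripts:
        cs, ce = t.cds if t.cds else ("", "")
        lines.append(f"{t.transcript_id}\t{t.gene_id or ''}\t{t.biotype}\t{cs}\t{ce}")
    Path(annotation_path).write_text("\n".join(lines) + "\n")
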