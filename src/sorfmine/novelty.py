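"""Two-stage novel-peptide filtering and peptide-to-entry assignment.

Stage 1 removes peptides occurring verbatim (optionally with I/L collapsed)
inside any reference protein. Stage 2 removes peptides whose best local
alignment against any known protein exceeds the similarity cutoff, so that
isoforms and point mutations of known proteins are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .orfdb import DatabaseEntry

DEFAULT_SIMILARITY_CUTOFF = 80.0


@dataclass
class PeptideRecord:
    """A peptide-level identification with per-sample intensities."""

    sequence: str
    accessions: list[str] = field(default_factory=list)
    intensities: dict[str, float] = field(default_factory=dict)
    qvalue: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for sample, value in self.intensities.items():
            if value < 0:
                raise ValueError(f"negative intensity for sample {sample}")
        if self.qvalue is not None and not 0 <= self.qvalue <= 1:
            raise ValueError("qvalue must lie in [0, 1]")


@dataclass(frozen=True)
class NoveltyVerdict:
    peptide: str
    stage: str  # refprot_hit | similar_known | novel
    max_similarity: float
    best_hit: str | None = None


@dataclass(frozen=True)
class Assignment:
    accessions: tuple[str, ...]
    unique: bool
    unassigned: bool = False


def collapse_il(sequence: str) -> str:
    return sequence.replace("I", "L")


def reference_substring_filter(
    peptides: Sequence[str],
    reference: Sequence[DatabaseEntry],
    il_equivalent: bool = True,
) -> tuple[list[str], list[str]]:
    """Partition peptides into (removed, retained) by exact substring presence
    in any reference protein. I and L are treated as identical when
    ``il_equivalent`` (they are mass-indistinguishable in MS)."""
    if not reference:
        raise ValueError("reference must be non-empty")
    for pep in peptides:
        if not pep:
            raise ValueError("empty peptide string")
    ref_seqs = [e.aa_sequence for e in reference]
    if il_equivalent:
        ref_seqs = [collapse_il(s) for s in ref_seqs]
    # one joined haystack with an out-of-alphabet separator: Python's substring
    # search is C-level and cannot match across '|'
    haystack = "|".join(ref_seqs)
    removed, retained = [], []
    for pep in peptides:
        needle = collapse_il(pep) if il_equivalent else pep
        (removed if needle in haystack else retained).append(pep)
    return removed, retained


def local_alignment_identity(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
) -> int:
    """Maximum identity count over all best-scoring local alignments.

    Smith-Waterman with linear gap penalty. Cells track (score, matches)
    lexicographically; since no prefix of a score-optimal local alignment can
    have a negative partial sum (the suffix alone would score higher), the
    clamped DP visits every optimal alignment, and the tie-break yields the
    maximum identity count over all of them.
    """
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return 0
    prev_h = [0] * (m + 1)
    prev_c = [0] * (m + 1)
    best = 0
    best_c = 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        cur_h = [0] * (m + 1)
        cur_c = [0] * (m + 1)
        row_h = prev_h
        row_c = prev_c
        for j in range(1, m + 1):
            is_match = qi == target[j - 1]
            diag = row_h[j - 1] + (match if is_match else mismatch)
            diag_c = row_c[j - 1] + (1 if is_match else 0)
            h, c = 0, 0
            if diag > h or (diag == h and diag_c > c):
                h, c = diag, diag_c
            up = row_h[j] + gap
            if up > h or (up == h and prev_c[j] > c):
                h, c = up, row_c[j]
            left = cur_h[j - 1] + gap
            if left > h or (left == h and cur_c[j - 1] > c):
                h, c = left, cur_c[j - 1]
            cur_h[j] = h
            cur_c[j] = c
            if h > best or (h == best and c > best_c):
                best, best_c = h, c
        prev_h, prev_c = cur_h, cur_c
    return best_c


def max_similarity_to_known(
    peptide: str,
    known: Sequence[DatabaseEntry],
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
    il_equivalent: bool = False,
) -> tuple[float, str | None]:
    """Best percent identity of ``peptide`` against any known protein.

    percent = 100 * (identity count of the best local alignment) / len(peptide);
    ties between proteins resolve to the lexicographically smallest accession.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    if not known:
        return 0.0, None
    query = collapse_il(peptide) if il_equivalent else peptide
    best_pct = -1.0
    best_hit: str | None = None
    for entry in sorted(known, key=lambda e: e.accession):
        target = collapse_il(entry.aa_sequence) if il_equivalent else entry.aa_sequence
        ident = local_alignment_identity(query, target, match=match, mismatch=mismatch, gap=gap)
        pct = 100.0 * ident / len(peptide)
        if pct > best_pct:
            best_pct, best_hit = pct, entry.accession
    return best_pct, best_hit


def filter_novel(
    peptides: Sequence[str],
    reference: Sequence[DatabaseEntry],
    known: Sequence[DatabaseEntry],
    cutoff: float = DEFAULT_SIMILARITY_CUTOFF,
    il_stage1: bool = True,
    il_stage2: bool = False,
) -> tuple[list[str], list[NoveltyVerdict]]:
    """Run the substring filter then the similarity filter.

    A peptide is novel iff it is absent from every reference protein and its
    best identity against the known set is <= ``cutoff`` percent ("no more
    than 80%" is retained; strictly greater is excluded).
    """
    if not 0 < cutoff <= 100:
        raise ValueError("cutoff must lie in (0, 100]")
    removed, retained = reference_substring_filter(
        peptides, reference, il_equivalent=il_stage1
    )
    verdicts: dict[str, NoveltyVerdict] = {}
    for pep in removed:
        verdicts[pep] = NoveltyVerdict(peptide=pep, stage="refprot_hit", max_similarity=100.0)
    novel: list[str] = []
    for pep in retained:
        pct, hit = max_similarity_to_known(pep, known, il_equivalent=il_stage2)
        if pct > cutoff:
            verdicts[pep] = NoveltyVerdict(
                peptide=pep, stage="similar_known", max_similarity=pct, best_hit=hit
            )
        else:
            verdicts[pep] = NoveltyVerdict(
                peptide=pep, stage="novel", max_similarity=pct, best_hit=hit
            )
            novel.append(pep)
    ordered = [verdicts[p] for p in peptides]
    return novel, ordered


def assign_and_flag_unique(
    peptides: Sequence[str],
    database: Sequence[DatabaseEntry],
    il_equivalent: bool = True,
) -> dict[str, Assignment]:
    """Map each peptide to every database entry containing it as a substring.

    ``unique`` means exactly one matching entry (the quantifiable case).
    Peptides matching nothing are flagged ``unassigned`` — they signal an
    identification table inconsistent with the database.
    """
    collapsed = [
        (e.accession, collapse_il(e.aa_sequence) if il_equivalent else e.aa_sequence)
        for e in database
    ]
    out: dict[str, Assignment] = {}
    for pep in peptides:
        needle = collapse_il(pep) if il_equivalent else pep
        hits = tuple(acc for acc, seq in collapsed if needle in seq)
        out[pep] = Assignment(
            accessions=hits, unique=len(hits) == 1, unassigned=len(hits) == 0
        )
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_peptide_table(path) -> list[PeptideRecord]:
    """Read a peptide TSV: columns peptide, accessions (';'-joined), optional
    qvalue, and one intensity column per sample. Empty cells mean unobserved."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    special = {"peptide", "accessions", "qvalue"}
    sample_cols = [c for c in df.columns if c not in special]
    records = []
    for _, row in df.iterrows():
        intensities = {
            c: float(row[c]) for c in sample_cols if pd.notna(row[c])
        }
        accs = row.get("accessions")
        accessions = str(accs).split(";") if pd.notna(accs) and str(accs) else []
        q = row.get("qvalue")
        records.append(
            PeptideRecord(
                sequence=str(row["peptide"]),
                accessions=accessions,
                intensities=intensities,
                qvalue=float(q) if q is not None and pd.notna(q) else None,
            )
        )
    return records


def write_verdicts(verdicts: Sequence[NoveltyVerdict], path) -> None:
    lines = ["peptide\tstage\tmax_similarity\tbest_hit"]
    for v in verdicts:
        lines.append(
            f"{v.peptide}\t{v.stage}\t{v.max_similarity:.4f}\t{v.best_hit or ''}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
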