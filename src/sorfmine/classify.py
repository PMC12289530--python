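"""Seven-category genomic-context classification of sORFs.

Categories: lncRNA, uORF, uoORF, intORF, dORF, doORF, novel. Boundaries are
0-based half-open in transcript coordinates; an sORF abutting the CDS start is
a uORF (not uoORF), mirrored at the 3' end. Internal in-frame sORFs on coding
transcripts are not one of the seven — they are canonical-frame fragments and
should already have been removed by the novelty filter.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from .orfdb import SORF, Transcript


class CategoryLabel(str, Enum):
    LNCRNA = "lncRNA"
    UORF = "uORF"
    UOORF = "uoORF"
    INTORF = "intORF"
    DORF = "dORF"
    DOORF = "doORF"
    NOVEL = "novel"


class CanonicalFrameError(ValueError):
    """An internal, canonical-frame sORF on a coding transcript surfaced.

    Such sequences are fragments of the annotated protein and must have been
    removed upstream; seeing one indicates a filtering fault."""


def classify_sorf(sorf: SORF, transcript: Transcript) -> CategoryLabel:
    """Assign one of the seven genomic-context categories."""
    if sorf.transcript_id != transcript.transcript_id:
        raise ValueError(
            f"sORF {sorf.sorf_id} does not belong to transcript {transcript.transcript_id}"
        )
    if transcript.biotype == "novel":
        return CategoryLabel.NOVEL
    if transcript.biotype == "noncoding":
        return CategoryLabel.LNCRNA
    cs, ce = transcript.cds  # type: ignore[misc] # coding => cds present
    start, end = sorf.start, sorf.end
    if end <= cs:
        return CategoryLabel.UORF
    if start < cs and end > cs and end <= ce:
        return CategoryLabel.UOORF
    if start >= ce:
        return CategoryLabel.DORF
    if start >= cs and start < ce and end > ce:
        return CategoryLabel.DOORF
    if cs <= start and end <= ce:
        if (start - cs) % 3 != 0:
            return CategoryLabel.INTORF
        raise CanonicalFrameError(
            f"sORF {sorf.sorf_id} is an in-frame fragment of the canonical CDS"
        )
    # start < cs and end > ce: ORF spanning the whole CDS; upstream overlap
    # takes precedence (same frame is impossible: the CDS stop would end it)
    return CategoryLabel.UOORF


@dataclass(frozen=True)
class SorfSummary:
    category_fractions: Mapping[str, float]
    start_codon_fractions: Mapping[str, float]
    length_median: float
    length_fraction_100_200: float

    def to_dict(self) -> dict:
        return {
            "category_fractions": dict(self.category_fractions),
            "start_codon_fractions": dict(self.start_codon_fractions),
            "length_median": self.length_median,
            "length_fraction_100_200": self.length_fraction_100_200,
        }


def summarize(
    sorfs: Sequence[SORF], transcripts: Mapping[str, Transcript]
) -> SorfSummary:
    """Category/start-codon composition and length statistics of an sORF set.

    The 100-200 aa fraction is inclusive on both ends; the median is the
    standard order statistic (mean of central pair for even n).
    """
    if not sorfs:
        raise ValueError("cannot summarize an empty sORF set")
    n = len(sorfs)
    cat_counts: dict[str, int] = {}
    codon_counts: dict[str, int] = {}
    lengths = []
    for sorf in sorfs:
        label = sorf.category or classify_sorf(sorf, transcripts[sorf.transcript_id]).value
        cat_counts[label] = cat_counts.get(label, 0) + 1
        codon_counts[sorf.start_codon] = codon_counts.get(sorf.start_codon, 0) + 1
        lengths.append(sorf.aa_length)
    return SorfSummary(
        category_fractions={k: v / n for k, v in sorted(cat_counts.items())},
        start_codon_fractions={k: v / n for k, v in sorted(codon_counts.items())},
        length_median=float(statistics.median(lengths)),
        length_fraction_100_200=sum(1 for L in lengths if 100 <= L <= 200) / n,
    )


def write_classified_tsv(sorfs: Sequence[SORF], path: str | Path) -> None:
    lines = ["sorf_id\ttranscript_id\tstart\tend\tframe\tstart_codon\tcategory"]
    for s in sorfs:
        lines.append(
            f"{s.sorf_id}\t{s.transcript_id}\t{s.start}\t{s.end}\t{s.frame}"
            f"\t{s.start_codon}\t{s.category or ''}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_summary_json(summary: SorfSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
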