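"""Seeded synthetic-data generator with a ground-truth table.

Produces every input the pipeline consumes — transcript FASTA + annotation,
reference/known protein FASTA, sample design, peptide intensity tables and
degraded MGF spectra — together with a truth table for recovery tests.

Planting strategy: each requested genomic context gets its own transcript in
which one sORF is constructed by reverse translation (sense codons only, so
the body is stop-free) behind a frame-aligned TAA guard, making the planted
start the most upstream qualifying start for its (frame, stop). Overlapping
contexts (uoORF/doORF/intORF) co-design the shared nucleotides. Every planted
sORF is then re-discovered with :func:`sorfmine.orfdb.find_sorfs` and
re-classified before it enters the truth table; constructions that fail
verification are resampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import CategoryLabel, classify_sorf
from .orfdb import (
    DEFAULT_MAX_AA,
    DEFAULT_MIN_AA,
    DEFAULT_START_CODONS,
    DatabaseEntry,
    SORF,
    Transcript,
    find_sorfs,
    translate,
)
from .spectra import Peak, Spectrum, theoretical_spectrum

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_SENSE_CODONS: dict[str, list[str]] = {}
for _c1 in "ACGT":
    for _c2 in "ACGT":
        for _c3 in "ACGT":
            _codon = _c1 + _c2 + _c3
            _aa = translate(_codon)
            if _aa != "*":
                _SENSE_CODONS.setdefault(_aa, []).append(_codon)

STOPS = ("TAA", "TAG", "TGA")

ALL_CONTEXTS = ("lncRNA", "uORF", "uoORF", "intORF", "dORF", "doORF", "novel")


class ConfigError(ValueError):
    """Infeasible generator geometry or exhausted construction attempts."""


@dataclass
class TruthTable:
    """Everything planted into one generated dataset."""

    seed: int
    planted_sorfs: list[dict] = field(default_factory=list)
    planted_novel_peptides: list[str] = field(default_factory=list)
    planted_effects: dict[str, dict] = field(default_factory=dict)
    nascent_set: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "planted_sorfs": self.planted_sorfs,
                    "planted_novel_peptides": self.planted_novel_peptides,
                    "planted_effects": self.planted_effects,
                    "nascent_set": self.nascent_set,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        data = json.loads(Path(path).read_text())
        return cls(
            seed=data["seed"],
            planted_sorfs=data["planted_sorfs"],
            planted_novel_peptides=data["planted_novel_peptides"],
            planted_effects=data["planted_effects"],
            nascent_set=data["nascent_set"],
        )


# ---------------------------------------------------------------------------
# sequence-building primitives
# ---------------------------------------------------------------------------

def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))

def _reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(rng.choice(_SENSE_CODONS[aa]) for aa in peptide)

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))

def _sorf_cassette(rng: np.random.Generator, start_codon: str, body_aa: int) -> str:
    """TAA guard + start codon + stop-free body + stop codon (frame-aligned)."""
    body = _reverse_translate(rng, _random_peptide(rng, body_aa))
    return "TAA" + start_codon + body + str(rng.choice(STOPS))


def _pick_start_codon(rng: np.random.Generator, alt_start_prob: float) -> str:
    if rng.random() < alt_start_prob:
        return str(rng.choice(["CTG", "GTG"]))
    return "ATG"


def _coding_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + sense codons + stop; translation is M + random residues."""
    return "ATG" + _reverse_translate(rng, _random_peptide(rng, n_aa - 1)) + str(
        rng.choice(STOPS)
    )


def _build_context_transcript(
    rng: np.random.Generator,
    context: str,
    tid: str,
    body_aa: int,
    start_codon: str,
    cds_aa: int = 50,
    utr: int = 60,
) -> Transcript:
    """Assemble one transcript carrying one planted sORF of ``context``."""
    if context in ("lncRNA", "novel"):
        cassette = _sorf_cassette(rng, start_codon, body_aa)
        seq = _random_dna(rng, utr) + cassette + _random_dna(rng, utr)
        biotype = "noncoding" if context == "lncRNA" else "novel"
        return Transcript(transcript_id=tid, biotype=biotype, sequence=seq)

    if context == "uORF":
        cassette = _sorf_cassette(rng, start_codon, body_aa)
        utr5 = _random_dna(rng, 12) + cassette + _random_dna(rng, 9)
        seq = utr5 + _coding_cds(rng, cds_aa) + _random_dna(rng, utr)
        cds = (len(utr5), len(utr5) + 3 * cds_aa + 3)
    elif context == "dORF":
        cassette = _sorf_cassette(rng, start_codon, body_aa)
        utr5 = _random_dna(rng, utr)
        cds_nt = _coding_cds(rng, cds_aa)
        seq = utr5 + cds_nt + _random_dna(rng, 12) + cassette + _random_dna(rng, 9)
        cds = (len(utr5), len(utr5) + len(cds_nt))
    elif context == "uoORF":
        # sORF ends 4 nt into the CDS; its stop codon TGA is spelled by CDS
        # positions 1-3, so the CDS second codon must start with A (here ACA).
        cds_nt = (
            "ATG" + "ACA" + _reverse_translate(rng, _random_peptide(rng, cds_aa - 3))
            + str(rng.choice(STOPS))
        )
        body = _reverse_translate(rng, _random_peptide(rng, body_aa - 1))
        utr5 = _random_dna(rng, 12) + "TAA" + start_codon + body + "CC"
        seq = utr5 + cds_nt + _random_dna(rng, utr)
        cds = (len(utr5), len(utr5) + len(cds_nt))
    elif context == "doORF":
        # sORF starts 4 nt before the CDS end: its ATG is spelled by the last
        # nt of a GCA codon plus the TG of the CDS TGA stop; the body runs on
        # into the 3' UTR.
        cds_nt = (
            "ATG" + _reverse_translate(rng, _random_peptide(rng, cds_aa - 2))
            + "GCA" + "TGA"
        )
        body = _reverse_translate(rng, _random_peptide(rng, body_aa - 2))
        utr3 = "CC" + body + str(rng.choice(STOPS)) + _random_dna(rng, utr)
        utr5 = _random_dna(rng, utr)
        seq = utr5 + cds_nt + utr3
        cds = (len(utr5), len(utr5) + len(cds_nt))
    elif context == "intORF":
        # frame-shifted cassette embedded inside the CDS; resampled by the
        # caller until the CDS frame stays stop-free
        shift = int(rng.integers(1, 3))
        cassette = _sorf_cassette(rng, start_codon, body_aa)
        pad_pre = _random_dna(rng, 3 * int(rng.integers(2, 5)) + shift)
        pad_post = _random_dna(rng, 3 * int(rng.integers(2, 5)) + (3 - shift) % 3)
        cds_nt = "ATG" + pad_pre + cassette + pad_post + str(rng.choice(STOPS))
        if translate(cds_nt)[:-1].count("*") > 0:
            raise _RetryConstruction
        utr5 = _random_dna(rng, utr)
        seq = utr5 + cds_nt + _random_dna(rng, utr)
        cds = (len(utr5), len(utr5) + len(cds_nt))
    else:
        raise ConfigError(f"unknown context {context!r}")
    return Transcript(transcript_id=tid, biotype="coding", sequence=seq, cds=cds)


class _RetryConstruction(Exception):
    pass


def _verify_planted(
    transcript: Transcript,
    context: str,
    start_codon: str,
    start_codons: frozenset[str],
    min_aa: int,
    max_aa: int,
) -> SORF | None:
    """Re-discover the planted sORF and check its category; None on failure."""
    for sorf in find_sorfs(
        transcript, start_codons=start_codons, min_aa=min_aa, max_aa=max_aa
    ):
        if sorf.start_codon != start_codon:
            continue
        try:
            label = classify_sorf(sorf, transcript)
        except Exception:
            continue
        if label.value == context:
            return sorf
    return None


def generate_transcriptome(
    n_coding: int = 3,
    n_noncoding: int = 2,
    n_novel: int = 1,
    contexts: Sequence[str] = ALL_CONTEXTS,
    body_aa_range: tuple[int, int] = (10, 40),
    alt_start_prob: float = 0.2,
    seed: int = 0,
    max_attempts: int = 200,
) -> tuple[list[Transcript], list[dict]]:
    """Generate a transcriptome with one planted sORF per requested context,
    plus plain coding/noncoding/novel background transcripts.

    Returns the transcripts and the planted-sORF part of the truth table
    (sorf_id, category, start_codon, aa_sequence, transcript_id).
    """
    for n in (n_coding, n_noncoding, n_novel):
        if n < 0:
            raise ConfigError("transcript counts must be >= 0")
    unknown = set(contexts) - set(ALL_CONTEXTS)
    if unknown:
        raise ConfigError(f"unknown contexts {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    planted: list[dict] = []

    for k, context in enumerate(contexts):
        tid = f"TX_{context}_{k:03d}"
        sorf = None
        for _ in range(max_attempts):
            body_aa = int(rng.integers(*body_aa_range))
            # the doORF construction spells its start from the CDS stop, which
            # fixes the codon to ATG
            codon = "ATG" if context == "doORF" else _pick_start_codon(rng, alt_start_prob)
            try:
                transcript = _build_context_transcript(rng, context, tid, body_aa, codon)
            except _RetryConstruction:
                continue
            sorf = _verify_planted(
                transcript, context, codon, frozenset(DEFAULT_START_CODONS),
                DEFAULT_MIN_AA, DEFAULT_MAX_AA,
            )
            if sorf is not None:
                break
        if sorf is None:
            raise ConfigError(f"could not plant a {context} sORF in {max_attempts} tries")
        transcripts.append(transcript)
        planted.append(
            {
                "sorf_id": sorf.sorf_id,
                "transcript_id": tid,
                "category": context,
                "start_codon": sorf.start_codon,
                "aa_sequence": sorf.aa_sequence,
            }
        )

    # background transcripts without planted sORFs
    for i in range(n_coding):
        cds_aa = int(rng.integers(40, 90))
        utr5 = _random_dna(rng, int(rng.integers(30, 90)))
        cds_nt = _coding_cds(rng, cds_aa)
        utr3 = _random_dna(rng, int(rng.integers(30, 90)))
        transcripts.append(
            Transcript(
                transcript_id=f"TX_coding_{i:03d}",
                biotype="coding",
                sequence=utr5 + cds_nt + utr3,
                cds=(len(utr5), len(utr5) + len(cds_nt)),
            )
        )
    for i in range(n_noncoding):
        transcripts.append(
            Transcript(
                transcript_id=f"TX_nc_{i:03d}",
                biotype="noncoding",
                sequence=_random_dna(rng, int(rng.integers(150, 400))),
            )
        )
    for i in range(n_novel):
        transcripts.append(
            Transcript(
                transcript_id=f"TX_nov_{i:03d}",
                biotype="novel",
                sequence=_random_dna(rng, int(rng.integers(150, 400))),
            )
        )
    return transcripts, planted


def generate_reference_proteome(
    transcripts: Sequence[Transcript],
    variant_of: Sequence[str] = (),
    seed: int = 0,
) -> list[DatabaseEntry]:
    """One canonical protein per coding CDS, plus optional 1-residue variants
    of supplied microprotein sequences (to exercise the similarity stage)."""
    coding = [t for t in transcripts if t.biotype == "coding"]
    if not coding:
        raise ConfigError("no coding transcripts to derive a reference proteome from")
    rng = np.random.default_rng(seed)
    entries = []
    for t in coding:
        cs, ce = t.cds  # type: ignore[misc]
        protein = translate(t.sequence[cs : ce - 3], init_met=True)
        if "*" in protein:
            raise ConfigError(f"CDS of {t.transcript_id} contains an internal stop")
        entries.append(
            DatabaseEntry(
                accession=f"REF_{t.transcript_id}",
                aa_sequence=protein,
                source="public_external",
            )
        )
    for i, seq in enumerate(variant_of):
        pos = int(rng.integers(0, len(seq)))
        alternatives = [a for a in AA20 if a != seq[pos]]
        variant = seq[:pos] + str(rng.choice(alternatives)) + seq[pos + 1 :]
        entries.append(
            DatabaseEntry(
                accession=f"REFVAR_{i:03d}", aa_sequence=variant, source="public_external"
            )
        )
    return entries


def tryptic_digest(
    protein: str, max_missed: int = 2, min_len: int = 7, max_len: int = 30
) -> list[str]:
    """In-silico trypsin digest: cleave after K/R except before P; emit all
    peptides with at most ``max_missed`` internal missed cleavages and length
    within [min_len, max_len], in N->C order."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cuts = [0]
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    fragments = [protein[cuts[i] : cuts[i + 1]] for i in range(len(cuts) - 1)]
    peptides = []
    for i in range(len(fragments)):
        for j in range(i, min(i + max_missed + 1, len(fragments))):
            pep = "".join(fragments[i : j + 1])
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
    return peptides


def simulate_intensities(
    design: Sequence,
    protein_peptides: Mapping[str, Sequence[str]],
    effects: Mapping[str, Mapping[str, float]] | None = None,
    assay_effects: Mapping[str, Mapping[str, float]] | None = None,
    sigma_log2: float = 0.3,
    donor_sd: float = 0.2,
    baseline_log2: tuple[float, float] = (12.0, 16.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a peptide intensity table over ``design``.

    log2 intensity = protein baseline + peptide offset + donor effect
    + log2(condition fold change) + log2(assay multiplier) + Normal(0, sigma).
    ``effects`` maps protein -> {condition: linear fold change} (reference
    conditions implicitly 1); ``assay_effects`` likewise per assay. Returns a
    DataFrame with columns peptide, accessions and one column per sample.
    """
    if sigma_log2 <= 0:
        raise ValueError("sigma_log2 must be > 0")
    rng = np.random.default_rng(seed)
    effects = effects or {}
    assay_effects = assay_effects or {}
    donors = sorted({s.donor for s in design})
    rows = []
    for acc in sorted(protein_peptides):
        base = rng.uniform(*baseline_log2)
        donor_eff = {d: rng.normal(0.0, donor_sd) for d in donors}
        cond_eff = {c: np.log2(f) for c, f in effects.get(acc, {}).items()}
        assay_eff = {a: np.log2(f) for a, f in assay_effects.get(acc, {}).items()}
        for pep in protein_peptides[acc]:
            pep_offset = rng.normal(0.0, 0.5)
            row: dict = {"peptide": pep, "accessions": acc}
            for s in design:
                log2i = (
                    base
                    + pep_offset
                    + donor_eff[s.donor]
                    + cond_eff.get(s.condition, 0.0)
                    + assay_eff.get(s.assay, 0.0)
                    + rng.normal(0.0, sigma_log2)
                )
                row[s.sample_id] = float(2.0 ** log2i)
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_spectra(
    peptides: Sequence[str],
    dropout_p: float = 0.1,
    jitter_sd_da: float = 0.005,
    n_noise_peaks: int = 3,
    seed: int = 0,
    fragment_charges: Sequence[int] = (1,),
) -> list[Spectrum]:
    """Degrade theoretical spectra into synthetic experimental ones.

    Each theoretical peak is dropped with probability ``dropout_p``, retained
    m/z values are jittered by Normal(0, jitter_sd_da), and uniform noise
    peaks are added over the observed m/z range.
    """
    if not 0 <= dropout_p < 1:
        raise ValueError("dropout_p must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for pep in peptides:
        theo = theoretical_spectrum(pep, fragment_charges=fragment_charges)
        lo, hi = theo.peaks[0].mz, theo.peaks[-1].mz
        peaks = []
        for p in theo.peaks:
            if rng.random() < dropout_p:
                continue
            mz = p.mz + rng.normal(0.0, jitter_sd_da)
            peaks.append(Peak(mz=max(mz, 1e-6), intensity=p.intensity))
        for _ in range(n_noise_peaks):
            peaks.append(Peak(mz=rng.uniform(lo, hi), intensity=rng.uniform(0.05, 0.4)))
        out.append(Spectrum(peaks=peaks, peptide=pep))
    return out


# ---------------------------------------------------------------------------
# full dataset emission (what `sorfmine simulate` writes)
# ---------------------------------------------------------------------------

def default_design(
    donors: Sequence[str] = ("D1", "D2", "D3"),
    conditions: Sequence[str] = ("unstim", "PMA_Iono", "CD3_CD28"),
    replicates: int = 1,
    nascent: bool = True,
) -> list:
    """3 donors x 3 conditions global design, plus OPP / CHX+OPP assays."""
    from .quant import SampleDesign

    design = []
    for d in donors:
        for c in conditions:
            for r in range(1, replicates + 1):
                design.append(
                    SampleDesign(
                        sample_id=f"{d}_{c}_g{r}", donor=d, condition=c,
                        assay="global", replicate=r,
                    )
                )
            if nascent:
                design.append(
                    SampleDesign(
                        sample_id=f"{d}_{c}_opp", donor=d, condition=c,
                        assay="nascent_OPP", replicate=1,
                    )
                )
                design.append(
                    SampleDesign(
                        sample_id=f"{d}_{c}_chx", donor=d, condition=c,
                        assay="nascent_CHX_OPP", replicate=1,
                    )
                )
    return design


def generate_dataset(
    out_dir: str | Path,
    seed: int = 0,
    n_coding: int = 3,
    n_noncoding: int = 2,
    n_novel: int = 1,
    contexts: Sequence[str] = ALL_CONTEXTS,
    replicates: int = 3,
    planted_fc: float = 3.0,
    n_upregulated: int = 2,
    n_variant_spikes: int = 1,
    sigma_log2: float = 0.3,
    donor_sd: float = 0.2,
    dropout_p: float = 0.1,
    jitter_sd_da: float = 0.005,
    n_noise_peaks: int = 3,
) -> TruthTable:
    """Emit a complete synthetic dataset under ``out_dir``; return the truth.

    Writes transcripts.fasta, transcripts.tsv, refprot.fasta, known.fasta,
    design.tsv, peptides.tsv, spectra.mgf and truth.json.
    """
    from . import novelty, orfdb, quant

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    transcripts, planted = generate_transcriptome(
        n_coding=n_coding, n_noncoding=n_noncoding, n_novel=n_novel,
        contexts=contexts, seed=int(rng.integers(2**31)),
    )
    orfdb.write_transcripts(transcripts, out / "transcripts.fasta", out / "transcripts.tsv")

    micro_seqs = {p["sorf_id"]: p["aa_sequence"] for p in planted}
    spike_targets = [p["aa_sequence"] for p in planted[:n_variant_spikes]]
    reference = generate_reference_proteome(
        transcripts, variant_of=spike_targets, seed=int(rng.integers(2**31))
    )
    orfdb.write_database_fasta(reference, out / "refprot.fasta")
    orfdb.write_database_fasta(reference, out / "known.fasta")

    # peptides: canonical proteins + planted microproteins
    protein_peptides: dict[str, list[str]] = {}
    classes: dict[str, str] = {}
    canonical = [e for e in reference if e.accession.startswith("REF_")]
    for e in canonical:
        peps = tryptic_digest(e.aa_sequence)
        if peps:
            protein_peptides[e.accession] = peps[: min(len(peps), 6)]
            classes[e.accession] = "canonical"
    for sorf_id, seq in micro_seqs.items():
        peps = tryptic_digest(seq)
        if peps:
            protein_peptides[sorf_id] = peps[: min(len(peps), 3)]
            classes[sorf_id] = "microprotein"

    # planted novelty truth: microprotein peptides that genuinely pass both
    # filter stages against the emitted reference
    planted_novel: list[str] = []
    for sorf_id in sorted(micro_seqs):
        if sorf_id not in protein_peptides:
            continue
        novel, _ = novelty.filter_novel(protein_peptides[sorf_id], reference, reference)
        planted_novel.extend(novel)

    # planted differential effects on microproteins that carry novel peptides
    quantifiable = [s for s in sorted(micro_seqs) if s in protein_peptides]
    up_ids = quantifiable[: min(n_upregulated, len(quantifiable))]
    effects: dict[str, dict[str, float]] = {
        acc: {"PMA_Iono": planted_fc, "CD3_CD28": planted_fc} for acc in up_ids
    }
    # nascent truth: alternate microproteins; nascent ones keep full OPP signal
    # while CHX+OPP is suppressed, pre-existing ones show no OPP enrichment
    nascent_ids = quantifiable[::2]
    assay_effects: dict[str, dict[str, float]] = {}
    for acc in quantifiable:
        if acc in nascent_ids:
            assay_effects[acc] = {"nascent_OPP": 1.0, "nascent_CHX_OPP": 0.2}
        else:
            assay_effects[acc] = {"nascent_OPP": 1.0, "nascent_CHX_OPP": 1.0}

    design = default_design(replicates=replicates)
    quant.write_design(design, out / "design.tsv")
    table = simulate_intensities(
        design, protein_peptides, effects=effects, assay_effects=assay_effects,
        sigma_log2=sigma_log2, donor_sd=donor_sd, seed=int(rng.integers(2**31)),
    )
    table.to_csv(out / "peptides.tsv", sep="\t", index=False)

    all_peps = sorted({p for peps in protein_peptides.values() for p in peps})
    spectra = simulate_spectra(
        all_peps, dropout_p=dropout_p, jitter_sd_da=jitter_sd_da,
        n_noise_peaks=n_noise_peaks, seed=int(rng.integers(2**31)),
    )
    from .spectra import write_mgf

    write_mgf(spectra, out / "spectra.mgf")

    truth = TruthTable(
        seed=seed,
        planted_sorfs=planted,
        planted_novel_peptides=sorted(set(planted_novel)),
        planted_effects={
            acc: {"contrasts": sorted(eff), "fold_change": planted_fc}
            for acc, eff in effects.items()
        },
        nascent_set=sorted(nascent_ids),
    )
    truth.to_json(out / "truth.json")
    return truth
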