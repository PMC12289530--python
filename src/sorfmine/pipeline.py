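"""End-to-end orchestration: database -> novelty -> classification ->
spectral QC -> quantification -> differential expression -> nascent labeling
-> candidate selection, with a machine-readable report."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

from . import classify as classify_mod
from . import novelty as novelty_mod
from . import orfdb, quant, spectra
from .config import PipelineConfig

logger = logging.getLogger(__name__)

CONTRASTS = (("PMA_Iono", "unstim"), ("CD3_CD28", "unstim"))

#: Minimal structural schema of the run report: key -> required sub-keys.
REPORT_SCHEMA: dict[str, tuple[str, ...]] = {
    "meta": ("config_hash", "seed"),
    "database": ("n_transcripts", "n_three_frame_entries", "n_external_entries", "n_merged"),
    "novelty": ("input", "removed_refprot", "removed_similar", "retained"),
    "assignment": ("input", "unique", "shared", "unassigned"),
    "classification": ("n_sorfs", "category_fractions", "start_codon_fractions",
                       "length_median", "length_fraction_100_200"),
    "spectra_qc": ("n_spectra", "fractions_above"),
    "quantification": ("n_proteins", "n_canonical", "n_microproteins"),
    "differential_expression": (),
    "nascent": ("nascent", "pre_existing"),
    "candidates": ("n_evaluated", "n_pass", "passing"),
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_report(report: Mapping) -> None:
    """Raise ValueError if the report deviates from the bundled schema."""
    for section, keys in REPORT_SCHEMA.items():
        if section not in report:
            raise ValueError(f"report missing section {section!r}")
        for key in keys:
            if key not in report[section]:
                raise ValueError(f"report section {section!r} missing key {key!r}")
    nov = report["novelty"]
    if nov["removed_refprot"] + nov["removed_similar"] + nov["retained"] != nov["input"]:
        raise ValueError("novelty stage counts are not conservative")
    asg = report["assignment"]
    if asg["unique"] + asg["shared"] + asg["unassigned"] != asg["input"]:
        raise ValueError("assignment stage counts are not conservative")


def _attribution_rank(transcript: orfdb.Transcript) -> tuple[int, str]:
    order = {"coding": 0, "noncoding": 1, "novel": 2}
    return order[transcript.biotype], transcript.transcript_id


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on the configured inputs; returns the report dict and
    writes all stage outputs plus report.json under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"meta": {"config_hash": config.config_hash(), "seed": config.seed}}

    # -- stage: database construction -------------------------------------
    stage = "database"
    try:
        transcripts = orfdb.read_transcripts(config.transcripts_fasta, config.transcripts_tsv)
        by_tid = {t.transcript_id: t for t in transcripts}
        three_frame = orfdb.build_database(
            transcripts,
            start_codons=config.start_codons,
            min_aa=config.min_aa,
            max_aa=config.max_aa,
            emit_all_starts=config.emit_all_starts,
        )
        external: list[orfdb.DatabaseEntry] = []
        for path in config.external_dbs:
            external.extend(orfdb.read_database_fasta(path, source="riboseq_external"))
        database = orfdb.merge_databases([three_frame, external], dedup=True)
        orfdb.write_database_fasta(database, out / "database.fasta")
        report[stage] = {
            "n_transcripts": len(transcripts),
            "n_three_frame_entries": len(three_frame),
            "n_external_entries": len(external),
            "n_merged": len(database),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # -- stage: novelty filtering -----------------------------------------
    stage = "novelty"
    try:
        reference = orfdb.read_database_fasta(config.refprot_fasta)
        known = orfdb.read_database_fasta(config.known_fasta)
        peptide_records = novelty_mod.read_peptide_table(config.peptides_tsv)
        sequences = [p.sequence for p in peptide_records]
        novel_peps, verdicts = novelty_mod.filter_novel(
            sequences, reference, known,
            cutoff=config.similarity_cutoff,
            il_stage1=config.il_stage1,
            il_stage2=config.il_stage2,
        )
        novelty_mod.write_verdicts(verdicts, out / "novelty.tsv")
        by_stage = {"refprot_hit": 0, "similar_known": 0, "novel": 0}
        for v in verdicts:
            by_stage[v.stage] += 1
        report[stage] = {
            "input": len(sequences),
            "removed_refprot": by_stage["refprot_hit"],
            "removed_similar": by_stage["similar_known"],
            "retained": by_stage["novel"],
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: assignment -------------------------------------------------
    stage = "assignment"
    try:
        micro_assign = novelty_mod.assign_and_flag_unique(
            novel_peps, database, il_equivalent=config.il_stage1
        )
        canonical_peps = [v.peptide for v in verdicts if v.stage == "refprot_hit"]
        canon_assign = novelty_mod.assign_and_flag_unique(
            canonical_peps, reference, il_equivalent=config.il_stage1
        )
        assignments = {**canon_assign, **micro_assign}
        counted = list(micro_assign.values()) + list(canon_assign.values())
        report[stage] = {
            "input": len(counted),
            "unique": sum(1 for a in counted if a.unique),
            "shared": sum(1 for a in counted if not a.unique and not a.unassigned),
            "unassigned": sum(1 for a in counted if a.unassigned),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: classification --------------------------------------------
    stage = "classification"
    try:
        entry_by_acc = {e.accession: e for e in database}
        supported: dict[str, orfdb.SORF] = {}
        for pep in novel_peps:
            for acc in micro_assign[pep].accessions:
                entry = entry_by_acc[acc]
                meta = entry.metadata
                if "start" not in meta or meta.get("transcript_id") not in by_tid:
                    continue  # external entry without transcript coordinates
                if acc not in supported:
                    supported[acc] = orfdb.SORF(
                        sorf_id=acc,
                        transcript_id=meta["transcript_id"],
                        start=meta["start"],
                        end=meta["end"],
                        frame=meta["frame"],
                        start_codon=meta["start_codon"],
                        aa_sequence=entry.aa_sequence,
                    )
        classified = []
        for acc in sorted(supported):
            sorf = supported[acc]
            label = classify_mod.classify_sorf(sorf, by_tid[sorf.transcript_id])
            classified.append(
                orfdb.SORF(
                    sorf_id=sorf.sorf_id, transcript_id=sorf.transcript_id,
                    start=sorf.start, end=sorf.end, frame=sorf.frame,
                    start_codon=sorf.start_codon, aa_sequence=sorf.aa_sequence,
                    category=label.value,
                )
            )
        classify_mod.write_classified_tsv(classified, out / "sorfs_classified.tsv")
        if classified:
            summary = classify_mod.summarize(classified, by_tid)
            classify_mod.write_summary_json(summary, out / "sorf_summary.json")
            report[stage] = {"n_sorfs": len(classified), **summary.to_dict()}
        else:
            report[stage] = {
                "n_sorfs": 0, "category_fractions": {}, "start_codon_fractions": {},
                "length_median": None, "length_fraction_100_200": None,
            }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: spectral QC -------------------------------------------------
    stage = "spectra_qc"
    try:
        protein_similarity: dict[str, float] = {}
        scores: list[float] = []
        score_rows = []
        if config.spectra_mgf and Path(config.spectra_mgf).exists():
            for spec in spectra.read_mgf(config.spectra_mgf):
                if not spec.peptide:
                    continue
                theo = spectra.theoretical_spectrum(spec.peptide)
                res = spectra.similarity(spec, theo, tolerance_da=config.fragment_tolerance_da)
                scores.append(res.score)
                score_rows.append((spec.peptide, res))
                assignment = assignments.get(spec.peptide)
                if assignment is None:
                    continue
                for acc in assignment.accessions:
                    protein_similarity[acc] = max(protein_similarity.get(acc, 0.0), res.score)
            spectra.write_scores_tsv(score_rows, out / "spectral_scores.tsv")
        fractions = (
            spectra.similarity_fractions(scores, config.spectral_thresholds)
            if scores else {}
        )
        report[stage] = {
            "n_spectra": len(scores),
            "fractions_above": {str(t): f for t, f in fractions.items()},
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: quantification ----------------------------------------------
    stage = "quantification"
    try:
        design = quant.read_design(config.design_tsv)
        classes: dict[str, str] = {e.accession: "canonical" for e in reference}
        classes.update({e.accession: "microprotein" for e in database})
        # similarity-excluded peptides carry no assignment and are not quantified
        quantifiable = [p for p in peptide_records if p.sequence in assignments]
        quants = quant.aggregate(quantifiable, assignments, classes)
        report[stage] = {
            "n_proteins": len(quants),
            "n_canonical": sum(1 for q in quants if q.protein_class == "canonical"),
            "n_microproteins": sum(1 for q in quants if q.protein_class == "microprotein"),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: differential expression -------------------------------------
    stage = "differential_expression"
    try:
        de_report: dict = {}
        micro_results: dict[str, list[quant.DEResult]] = {}
        for cond_a, cond_b in CONTRASTS:
            name = f"{cond_a}_vs_{cond_b}"
            results = quant.differential_expression(
                quants, design, (cond_a, cond_b), equal_var=config.equal_var
            )
            deps = quant.call_deps(
                results, fc_up=config.dep_fc_up, fc_down=config.dep_fc_down,
                alpha=config.dep_alpha,
            )
            quant.write_de_results(results, deps, out / f"de_{name}.tsv")
            micro_ids = {q.protein_id for q in quants if q.protein_class == "microprotein"}
            micro_results[name] = [r for r in results if r.protein_id in micro_ids]
            de_report[name] = {
                "n_tested": sum(1 for r in results if r.p == r.p),
                "n_up": len(deps["up"]),
                "n_down": len(deps["down"]),
            }
        report[stage] = de_report
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: nascent labeling ---------------------------------------------
    stage = "nascent"
    try:
        opp_samples = [s.sample_id for s in design if s.assay == "nascent_OPP"]
        chx_samples = [s.sample_id for s in design if s.assay == "nascent_CHX_OPP"]
        global_samples = [s.sample_id for s in design if s.assay == "global"]
        labels: dict[str, str] = {}
        for q in quants:
            if q.protein_class != "microprotein":
                continue
            labels[q.protein_id] = quant.label_nascent(
                q.protein_id,
                [q.intensities[s] for s in opp_samples if s in q.intensities],
                [q.intensities[s] for s in chx_samples if s in q.intensities],
                min_ratio=config.nascent_min_ratio,
                detected_in_global=any(s in q.intensities for s in global_samples),
            )
        (out / "nascent_labels.tsv").write_text(
            "protein_id\tlabel\n"
            + "".join(f"{p}\t{label}\n" for p, label in sorted(labels.items()))
        )
        report[stage] = {
            "nascent": sum(1 for v in labels.values() if v == "nascent"),
            "pre_existing": sum(1 for v in labels.values() if v == "pre_existing"),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: candidate selection -------------------------------------------
    stage = "candidates"
    try:
        calls = quant.select_candidates(
            micro_results,
            protein_similarity,
            sim_threshold=config.candidate_sim_threshold,
            fc_threshold=config.candidate_fc_threshold,
            min_donors=config.candidate_min_donors,
        )
        quant.write_candidates(calls, out / "candidates.tsv")
        report[stage] = {
            "n_evaluated": len(calls),
            "n_pass": sum(1 for c in calls if c.passes),
            "passing": sorted(c.protein_id for c in calls if c.passes),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    validate_report(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: config %s seed %d", config.config_hash(), config.seed)
    return report
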