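# sorfmine

Proteogenomic discovery pipeline for sORF-encoded microproteins. From
transcript sequences with minimal annotation, sorfmine:

1. **builds a searchable microprotein database** by three-frame translation
   (near-cognate starts CTG/GTG supported, initiator-Met convention) and
   merges it with external Ribo-seq / public FASTA databases (`orfdb`);
2. **separates novel microprotein peptides from canonical proteins** with a
   two-stage filter — exact substring matching against a reference proteome
   (I/L collapsed), then local-alignment similarity against known proteins
   with an 80% identity cutoff (`novelty`);
3. **classifies each peptide-supported sORF** into one of seven genomic
   contexts (lncRNA, uORF, uoORF, intORF, dORF, doORF, novel) and summarizes
   lengths, categories and start-codon usage (`classify`);
4. **scores identification confidence** by comparing experimental MGF spectra
   to theoretical b/y fragment spectra (cosine on sqrt intensities, 0.02 Da
   tolerance) (`spectra`);
5. **quantifies and tests** protein abundance (≥2 unique peptides for
   canonical proteins, ≥1 for microproteins; Student's t on log2 intensities
   with Benjamini–Hochberg adjustment; DEP calling at FC > 2 / < 0.5 and
   adj. p < 0.05), labels nascent vs pre-existing proteins via the OPP /
   CHX+OPP assay contrast, and selects candidate microproteins (spectral
   similarity > 0.75 and fold change > 1.50 in ≥ 2 of 3 donors) (`quant`);
6. ships a **seeded synthetic-data generator** that emits every input format
   the pipeline reads, together with a ground-truth table for recovery tests
   (`synthetic`).

## Quick start

```bash
# generate a synthetic dataset (FASTA, TSVs, MGF, truth.json)
sorfmine simulate --out-dir demo --seed 7

# run the full pipeline from a YAML config
cat > demo/config.yaml <<EOF
transcripts_fasta: demo/transcripts.fasta
transcripts_tsv: demo/transcripts.tsv
refprot_fasta: demo/refprot.fasta
known_fasta: demo/known.fasta
peptides_tsv: demo/peptides.tsv
design_tsv: demo/design.tsv
spectra_mgf: demo/spectra.mgf
out_dir: demo/out
seed: 7
EOF
sorfmine run-all --config demo/config.yaml
```

`demo/out/report.json` holds per-stage counts (conservation is enforced:
retained + removed = input at every stage), category/start-codon fractions,
spectral-similarity fractions above 0.5/0.7/0.75, DEP counts per contrast and
the candidate list. Stage-wise subcommands (`build-db`, `filter`, `classify`,
`spectra-qc`, `quantify`, `candidates`) operate on the same files; every
threshold is a config key with CLI overrides.

## Tests

```bash
python -m pytest -q tests/
```

Unit tests per module sit next to independent brute-force oracles
(exhaustive per-codon ORF scan, naive substring scan, a Pareto-frontier
alignment enumerator, closed-form BH, exhaustive peak assignment);
`tests/test_acceptance.py` runs the acceptance criteria (oracle equivalence,
two-sided novelty recovery, seven-label classification recovery, spectral
degradation monotonicity, null type-I error calibration and end-to-end
candidate recovery at 200-protein scale).

## Layout

```
src/sorfmine/
  orfdb.py      three-frame sORF enumeration, database build/merge, FASTA IO
  novelty.py    substring + similarity filtering, uniqueness assignment
  classify.py   seven-category classification, summaries
  spectra.py    b/y theoretical spectra, peak matching, similarity, MGF IO
  quant.py      aggregation, fold changes, t-test + BH, DEP/nascent/candidates
  synthetic.py  seeded generator for all pipeline inputs + truth table
  config.py     PipelineConfig (YAML, validated, hashed)
  pipeline.py   run_all orchestration + report schema
  cli.py        click CLI (simulate, build-db, filter, ..., run-all)
```
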