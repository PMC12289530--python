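"""Protein quantification, differential expression and candidate selection.

Quantification follows the class-specific unique-peptide rule (>=2 unique
peptides for canonical proteins, >=1 for microproteins); fold changes use
means of observed intensities after log2 transformation; p-values come from a
two-sided two-sample t test with Benjamini-Hochberg adjustment across the
contrast. Candidate microproteins require spectral similarity > 0.75 and
fold change > 1.50 in at least two of three donors in an activation contrast.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .novelty import Assignment, PeptideRecord

logger = logging.getLogger(__name__)

CONDITIONS = ("unstim", "PMA_Iono", "CD3_CD28")
ASSAYS = ("global", "nascent_OPP", "nascent_CHX_OPP")


class UndefinedFoldChange(ValueError):
    """A contrast group has no observed intensities for this protein."""


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    donor: str
    condition: str
    assay: str = "global"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass
class ProteinQuant:
    protein_id: str
    protein_class: str  # canonical | microprotein
    n_unique_peptides: int
    intensities: dict[str, float] = field(default_factory=dict)


@dataclass
class DEResult:
    protein_id: str
    log2fc: float
    p: float
    adj_p: float
    donor_fold_changes: dict[str, float] = field(default_factory=dict)


@dataclass
class CandidateCall:
    protein_id: str
    max_spectral_similarity: float
    n_supporting_donors: int
    passes: bool
    reasons: list[str] = field(default_factory=list)


def aggregate(
    peptides: Sequence[PeptideRecord],
    assignments: Mapping[str, Assignment],
    classes: Mapping[str, str],
) -> list[ProteinQuant]:
    """Roll unique peptides up to proteins and apply the unique-peptide rule.

    A protein's per-sample intensity is the sum of its unique peptides'
    intensities; samples where no peptide was observed stay absent (no zero
    imputation). Canonical proteins need >=2 unique peptides, microproteins
    >=1; failures are dropped and logged.
    """
    per_protein: dict[str, list[PeptideRecord]] = {}
    for pep in peptides:
        assignment = assignments.get(pep.sequence)
        if assignment is None:
            raise ValueError(f"no assignment for peptide {pep.sequence}")
        if not assignment.unique:
            continue
        per_protein.setdefault(assignment.accessions[0], []).append(pep)
    out: list[ProteinQuant] = []
    for protein_id in sorted(per_protein):
        peps = per_protein[protein_id]
        protein_class = classes.get(protein_id, "canonical")
        required = 1 if protein_class == "microprotein" else 2
        if len(peps) < required:
            logger.info(
                "dropping %s (%s): %d unique peptide(s) < %d required",
                protein_id, protein_class, len(peps), required,
            )
            continue
        intensities: dict[str, float] = {}
        for pep in peps:
            for sample, value in pep.intensities.items():
                intensities[sample] = intensities.get(sample, 0.0) + value
        out.append(
            ProteinQuant(
                protein_id=protein_id,
                protein_class=protein_class,
                n_unique_peptides=len(peps),
                intensities=intensities,
            )
        )
    return out


def log2_fold_change(
    quant: ProteinQuant, group_a: Iterable[str], group_b: Iterable[str]
) -> float:
    """log2 of the ratio of mean observed intensities, group_a over group_b."""
    obs_a = [quant.intensities[s] for s in group_a if s in quant.intensities]
    obs_b = [quant.intensities[s] for s in group_b if s in quant.intensities]
    if not obs_a or not obs_b:
        raise UndefinedFoldChange(
            f"{quant.protein_id}: no observed intensity in one contrast group"
        )
    return math.log2((sum(obs_a) / len(obs_a)) / (sum(obs_b) / len(obs_b)))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order.

    q_(i) = p_(i) * m / i on the ascending-sorted p's, made monotone
    non-decreasing from the largest rank down and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p)


def differential_expression(
    quants: Sequence[ProteinQuant],
    design: Sequence[SampleDesign],
    contrast: tuple[str, str],
    equal_var: bool = True,
    min_per_group: int = 2,
    assay: str = "global",
) -> list[DEResult]:
    """Per-protein t test on log2 intensities for condition_a vs condition_b.

    Proteins observed in fewer than ``min_per_group`` samples of either group
    are reported with fold change only (p and adj_p are NaN); proteins with a
    fully missing group are skipped. Donor fold changes are within-donor
    ratios of raw mean intensities (a over b).
    """
    cond_a, cond_b = contrast
    group_a = [s.sample_id for s in design if s.condition == cond_a and s.assay == assay]
    group_b = [s.sample_id for s in design if s.condition == cond_b and s.assay == assay]
    if not group_a or not group_b:
        raise ValueError(f"contrast {contrast} has an empty sample group")
    donors = sorted({s.donor for s in design if s.assay == assay})
    results: list[DEResult] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for quant in quants:
        obs_a = np.array([quant.intensities[s] for s in group_a if s in quant.intensities])
        obs_b = np.array([quant.intensities[s] for s in group_b if s in quant.intensities])
        if obs_a.size == 0 or obs_b.size == 0:
            logger.info("skipping %s: contrast group fully missing", quant.protein_id)
            continue
        log2fc = math.log2(obs_a.mean() / obs_b.mean())
        donor_fcs: dict[str, float] = {}
        for donor in donors:
            da = [
                quant.intensities[s.sample_id]
                for s in design
                if s.donor == donor and s.condition == cond_a and s.assay == assay
                and s.sample_id in quant.intensities
            ]
            db = [
                quant.intensities[s.sample_id]
                for s in design
                if s.donor == donor and s.condition == cond_b and s.assay == assay
                and s.sample_id in quant.intensities
            ]
            if da and db:
                donor_fcs[donor] = (sum(da) / len(da)) / (sum(db) / len(db))
        result = DEResult(
            protein_id=quant.protein_id,
            log2fc=log2fc,
            p=float("nan"),
            adj_p=float("nan"),
            donor_fold_changes=donor_fcs,
        )
        if obs_a.size >= min_per_group and obs_b.size >= min_per_group:
            result.p = _two_sample_t(np.log2(obs_a), np.log2(obs_b), equal_var)
            tested_idx.append(len(results))
            pvals.append(result.p)
        results.append(result)
    for idx, q in zip(tested_idx, bh_adjust(pvals)):
        results[idx].adj_p = q
    return results


def call_deps(
    results: Sequence[DEResult],
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
) -> dict[str, set[str]]:
    """Strict-threshold DEP calling: up if FC > fc_up, down if FC < fc_down,
    both requiring adj_p < alpha (FC = 2**log2fc)."""
    up, down = set(), set()
    for r in results:
        if math.isnan(r.adj_p):
            continue
        fc = 2.0 ** r.log2fc
        if fc > fc_up and r.adj_p < alpha:
            up.add(r.protein_id)
        elif fc < fc_down and r.adj_p < alpha:
            down.add(r.protein_id)
    return {"up": up, "down": down}


def label_nascent(
    protein_id: str,
    opp_intensities: Sequence[float],
    chx_opp_intensities: Sequence[float],
    min_ratio: float = 2.0,
    detection_floor: float = 1.0,
    detected_in_global: bool = True,
) -> str:
    """Label a protein nascent or pre_existing from the OPP / CHX+OPP assays.

    Nascent requires detection in an OPP-enriched sample with mean OPP
    intensity exceeding ``min_ratio`` times the mean CHX+OPP intensity (the
    reduced-translation control); an absent CHX signal is scored at the
    detection floor. Proteins seen only in the global assay are pre_existing.
    """
    opp = [v for v in opp_intensities if v > 0]
    chx = [v for v in chx_opp_intensities if v > 0]
    if not opp and not chx and not detected_in_global:
        raise ValueError(f"{protein_id}: absent from all assays")
    if not opp:
        return "pre_existing"
    chx_mean = sum(chx) / len(chx) if chx else detection_floor
    return "nascent" if sum(opp) / len(opp) > min_ratio * chx_mean else "pre_existing"


def select_candidates(
    micro_results: Mapping[str, Sequence[DEResult]],
    similarity: Mapping[str, float],
    sim_threshold: float = 0.75,
    fc_threshold: float = 1.50,
    min_donors: int = 2,
) -> list[CandidateCall]:
    """Candidate microprotein selection.

    ``micro_results`` maps contrast name -> DE results for the microprotein
    class (one entry per activation contrast). A protein passes iff its best
    spectral similarity is strictly above ``sim_threshold`` AND, in at least
    one contrast, at least ``min_donors`` donors show a raw fold change
    strictly above ``fc_threshold``.
    """
    support: dict[str, int] = {}
    for results in micro_results.values():
        for r in results:
            n = sum(1 for fc in r.donor_fold_changes.values() if fc > fc_threshold)
            support[r.protein_id] = max(support.get(r.protein_id, 0), n)
    calls: list[CandidateCall] = []
    for protein_id in sorted(support):
        sim = similarity.get(protein_id, 0.0)
        n_donors = support[protein_id]
        reasons: list[str] = []
        if not sim > sim_threshold:
            reasons.append(
                f"spectral similarity {sim:.3f} not above {sim_threshold}"
            )
        if n_donors < min_donors:
            reasons.append(
                f"fold change > {fc_threshold} in only {n_donors} donor(s); "
                f"{min_donors} required"
            )
        calls.append(
            CandidateCall(
                protein_id=protein_id,
                max_spectral_similarity=sim,
                n_supporting_donors=n_donors,
                passes=not reasons,
                reasons=reasons,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_design(path) -> list[SampleDesign]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        SampleDesign(
            sample_id=str(r.sample_id),
            donor=str(r.donor),
            condition=str(r.condition),
            assay=str(r.assay),
            replicate=int(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]


def write_design(design: Sequence[SampleDesign], path) -> None:
    from pathlib import Path

    lines = ["sample_id\tdonor\tcondition\tassay\treplicate"]
    for s in design:
        lines.append(f"{s.sample_id}\t{s.donor}\t{s.condition}\t{s.assay}\t{s.replicate}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_de_results(
    results: Sequence[DEResult], deps: dict[str, set[str]], path
) -> None:
    from pathlib import Path

    donors = sorted({d for r in results for d in r.donor_fold_changes})
    header = ["protein_id", "log2fc", "p", "adj_p"] + [f"fc_{d}" for d in donors] + ["dep"]
    lines = ["\t".join(header)]
    for r in results:
        flag = "up" if r.protein_id in deps["up"] else (
            "down" if r.protein_id in deps["down"] else ""
        )
        row = [r.protein_id, f"{r.log2fc:.4f}", f"{r.p:.6g}", f"{r.adj_p:.6g}"]
        row += [
            f"{r.donor_fold_changes[d]:.4f}" if d in r.donor_fold_changes else ""
            for d in donors
        ]
        row.append(flag)
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_candidates(calls: Sequence[CandidateCall], path) -> None:
    from pathlib import Path

    lines = ["protein_id\tmax_spectral_similarity\tn_supporting_donors\tpasses\treasons"]
    for c in calls:
        lines.append(
            f"{c.protein_id}\t{c.max_spectral_similarity:.4f}\t{c.n_supporting_donors}"
            f"\t{str(c.passes).lower()}\t{'; '.join(c.reasons)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
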