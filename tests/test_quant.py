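"""quant: aggregation rules, fold changes, BH adjustment, the t test,
DEP calling, nascent labeling and candidate selection."""

import math

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sorfmine.novelty import Assignment, PeptideRecord
from sorfmine.quant import (
    DEResult,
    ProteinQuant,
    SampleDesign,
    UndefinedFoldChange,
    aggregate,
    bh_adjust,
    call_deps,
    differential_expression,
    label_nascent,
    log2_fold_change,
    select_candidates,
)


def assignments_for(mapping):
    return {
        pep: Assignment(accessions=(acc,), unique=True) for pep, acc in mapping.items()
    }


# ---------------------------------------------------------------------------
# aggregate
# ---------------------------------------------------------------------------

def test_canonical_single_peptide_excluded():
    peps = [PeptideRecord("AAAAAAK", intensities={"s1": 10.0})]
    out = aggregate(peps, assignments_for({"AAAAAAK": "P1"}), {"P1": "canonical"})
    assert out == []


def test_microprotein_single_peptide_included():
    peps = [PeptideRecord("AAAAAAK", intensities={"s1": 10.0})]
    (q,) = aggregate(peps, assignments_for({"AAAAAAK": "M1"}), {"M1": "microprotein"})
    assert q.intensities == {"s1": 10.0} and q.n_unique_peptides == 1


def test_intensity_summation():
    peps = [
        PeptideRecord("AAAAAAK", intensities={"s1": 3.0}),
        PeptideRecord("CCCCCCK", intensities={"s1": 5.0, "s2": 2.0}),
    ]
    (q,) = aggregate(
        peps,
        assignments_for({"AAAAAAK": "P1", "CCCCCCK": "P1"}),
        {"P1": "canonical"},
    )
    assert q.intensities == {"s1": 8.0, "s2": 2.0}  # missing values stay absent


def test_shared_peptides_not_quantified():
    peps = [
        PeptideRecord("AAAAAAK", intensities={"s1": 3.0}),
        PeptideRecord("CCCCCCK", intensities={"s1": 5.0}),
    ]
    assignments = {
        "AAAAAAK": Assignment(accessions=("P1", "P2"), unique=False),
        "CCCCCCK": Assignment(accessions=("P1",), unique=True),
    }
    out = aggregate(peps, assignments, {"P1": "microprotein"})
    assert len(out) == 1 and out[0].intensities == {"s1": 5.0}


# ---------------------------------------------------------------------------
# log2 fold change
# ---------------------------------------------------------------------------

def _quant(intensities):
    return ProteinQuant("P", "microprotein", 1, intensities)


def test_log2fc_examples():
    q = _quant({"a1": 4.0, "a2": 4.0, "b1": 2.0})
    assert log2_fold_change(q, ["a1", "a2"], ["b1"]) == pytest.approx(1.0)
    q2 = _quant({"a1": 5.0, "b1": 5.0})
    assert log2_fold_change(q2, ["a1"], ["b1"]) == 0.0


def test_log2fc_missing_group_raises():
    q = _quant({"a1": 4.0})
    with pytest.raises(UndefinedFoldChange):
        log2_fold_change(q, ["a1"], ["b1"])


def test_log2fc_matches_arithmetic_oracle(rng):
    for _ in range(50):
        a = rng.uniform(1, 100, size=4)
        b = rng.uniform(1, 100, size=3)
        q = _quant(
            {f"a{i}": float(v) for i, v in enumerate(a)}
            | {f"b{i}": float(v) for i, v in enumerate(b)}
        )
        got = log2_fold_change(q, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(3)])
        assert got == pytest.approx(math.log2(a.mean() / b.mean()))


# ---------------------------------------------------------------------------
# bh_adjust
# ---------------------------------------------------------------------------

def closed_form_bh(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_top)
        q[i] = min(running_min, 1.0)
    return q


def test_bh_worked_example():
    # q_i = p_i * 4 / i, then monotone from the top: all collapse to 0.04
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_single_p_unchanged():
    assert bh_adjust([0.123]) == pytest.approx([0.123])


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_bh_matches_closed_form_and_statsmodels(rng):
    for _ in range(200):
        m = int(rng.integers(1, 40))
        p = rng.uniform(0, 1, size=m).tolist()
        got = bh_adjust(p)
        assert got == pytest.approx(closed_form_bh(p), abs=1e-12)
        sm = multipletests(p, method="fdr_bh")[1]
        assert got == pytest.approx(sm.tolist(), abs=1e-12)


def test_bh_monotone_and_dominates_p(rng):
    p = rng.uniform(0, 1, size=30).tolist()
    q = bh_adjust(p)
    assert all(qi >= pi for qi, pi in zip(q, p))
    order = np.argsort(p)
    qs = np.array(q)[order]
    assert all(qs[i] <= qs[i + 1] + 1e-12 for i in range(len(qs) - 1))


def test_bh_null_fdr_control(rng):
    # on uniform nulls the expected fraction with q < 0.05 is <= 0.05
    rejected = 0
    total = 0
    for _ in range(100):
        p = rng.uniform(0, 1, size=100)
        rejected += int((np.array(bh_adjust(p.tolist())) < 0.05).sum())
        total += 100
    assert rejected / total <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / total)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def make_design(replicates=3, conditions=("unstim", "PMA_Iono")):
    design = []
    for d in ("D1", "D2", "D3"):
        for c in conditions:
            for r in range(1, replicates + 1):
                design.append(
                    SampleDesign(sample_id=f"{d}_{c}_{r}", donor=d, condition=c,
                                 assay="global", replicate=r)
                )
    return design


def test_de_identical_constants():
    design = make_design(replicates=2)
    intensities = {s.sample_id: 8.0 for s in design}
    q = ProteinQuant("P", "microprotein", 1, intensities)
    (r,) = differential_expression([q], design, ("PMA_Iono", "unstim"))
    assert r.log2fc == 0.0 and r.p == 1.0 and r.adj_p == 1.0
    assert all(fc == pytest.approx(1.0) for fc in r.donor_fold_changes.values())


def test_de_p_matches_scipy(rng):
    design = make_design(replicates=3)
    a = [s.sample_id for s in design if s.condition == "PMA_Iono"]
    b = [s.sample_id for s in design if s.condition == "unstim"]
    vals = {s.sample_id: float(rng.uniform(50, 200)) for s in design}
    q = ProteinQuant("P", "microprotein", 1, vals)
    (r,) = differential_expression([q], design, ("PMA_Iono", "unstim"))
    expected = stats.ttest_ind(
        np.log2([vals[s] for s in a]), np.log2([vals[s] for s in b]), equal_var=True
    )
    assert r.p == pytest.approx(expected.pvalue)


def test_de_type_one_error_near_alpha(rng):
    # null simulation: log-normal intensities, no effect; 300 replicates
    design = make_design(replicates=3)
    n_sig = 0
    n_rep = 300
    for _ in range(n_rep):
        vals = {s.sample_id: float(2 ** rng.normal(14, 0.3)) for s in design}
        q = ProteinQuant("P", "microprotein", 1, vals)
        (r,) = differential_expression([q], design, ("PMA_Iono", "unstim"))
        if r.p < 0.05:
            n_sig += 1
    se = math.sqrt(0.05 * 0.95 / n_rep)
    assert abs(n_sig / n_rep - 0.05) < 4 * se


def test_de_effect_recovery(rng):
    # planted log2fc = 1.58 recovered within +-0.2 on average over 200 runs
    design = make_design(replicates=3)
    a = {s.sample_id for s in design if s.condition == "PMA_Iono"}
    estimates = []
    for _ in range(200):
        vals = {}
        for s in design:
            mu = 14 + (1.58 if s.sample_id in a else 0.0)
            vals[s.sample_id] = float(2 ** rng.normal(mu, 0.3))
        q = ProteinQuant("P", "microprotein", 1, vals)
        (r,) = differential_expression([q], design, ("PMA_Iono", "unstim"))
        estimates.append(r.log2fc)
    assert abs(float(np.mean(estimates)) - 1.58) < 0.2


def test_de_power_increases_with_effect(rng):
    design = make_design(replicates=3)
    a = {s.sample_id for s in design if s.condition == "PMA_Iono"}
    power = []
    for effect in (0.0, 0.5, 1.5):
        hits = 0
        for _ in range(120):
            vals = {
                s.sample_id: float(2 ** rng.normal(14 + (effect if s.sample_id in a else 0), 0.3))
                for s in design
            }
            q = ProteinQuant("P", "microprotein", 1, vals)
            (r,) = differential_expression([q], design, ("PMA_Iono", "unstim"))
            hits += r.p < 0.05
        power.append(hits)
    assert power[0] < power[2] and power[1] <= power[2]


def test_de_underobserved_protein_fc_only():
    design = make_design(replicates=3)
    a = [s.sample_id for s in design if s.condition == "PMA_Iono"]
    b = [s.sample_id for s in design if s.condition == "unstim"]
    vals = {a[0]: 10.0, b[0]: 5.0, b[1]: 5.0}
    q = ProteinQuant("P", "microprotein", 1, vals)
    (r,) = differential_expression([q], design, ("PMA_Iono", "unstim"))
    assert r.log2fc == pytest.approx(1.0)
    assert math.isnan(r.p) and math.isnan(r.adj_p)


def test_de_fully_missing_group_skipped():
    design = make_design(replicates=2)
    vals = {s.sample_id: 5.0 for s in design if s.condition == "unstim"}
    q = ProteinQuant("P", "microprotein", 1, vals)
    assert differential_expression([q], design, ("PMA_Iono", "unstim")) == []


# ---------------------------------------------------------------------------
# call_deps
# ---------------------------------------------------------------------------

def _res(pid, log2fc, adj_p):
    return DEResult(protein_id=pid, log2fc=log2fc, p=adj_p, adj_p=adj_p)


def test_call_deps_examples_and_boundary():
    results = [
        _res("up", math.log2(2.5), 0.01),
        _res("edge", 1.0, 0.01),          # FC exactly 2.0: excluded
        _res("down", math.log2(0.4), 0.01),
        _res("ns", math.log2(3.0), 0.2),  # not significant
    ]
    deps = call_deps(results)
    assert deps["up"] == {"up"} and deps["down"] == {"down"}


def test_call_deps_matches_comprehension_oracle(rng):
    results = [
        _res(f"p{i}", float(rng.normal(0, 1.5)), float(rng.uniform(0, 0.2)))
        for i in range(200)
    ]
    deps = call_deps(results)
    up = {r.protein_id for r in results if 2 ** r.log2fc > 2 and r.adj_p < 0.05}
    down = {r.protein_id for r in results if 2 ** r.log2fc < 0.5 and r.adj_p < 0.05}
    assert deps["up"] == up and deps["down"] == down
    assert not (deps["up"] & deps["down"])


# ---------------------------------------------------------------------------
# label_nascent
# ---------------------------------------------------------------------------

def test_nascent_opp_only():
    assert label_nascent("P", [100.0], []) == "nascent"


def test_nascent_ratio_rule():
    assert label_nascent("P", [100.0], [90.0], min_ratio=2.0) == "pre_existing"
    assert label_nascent("P", [100.0], [40.0], min_ratio=2.0) == "nascent"


def test_global_only_pre_existing():
    assert label_nascent("P", [], [], detected_in_global=True) == "pre_existing"


def test_absent_everywhere_rejected():
    with pytest.raises(ValueError):
        label_nascent("P", [], [], detected_in_global=False)


# ---------------------------------------------------------------------------
# select_candidates
# ---------------------------------------------------------------------------

def _de(pid, fcs):
    return DEResult(
        protein_id=pid, log2fc=0.0, p=0.5, adj_p=0.5,
        donor_fold_changes={f"D{i + 1}": fc for i, fc in enumerate(fcs)},
    )


def test_candidate_passes():
    results = {"PMA_Iono_vs_unstim": [_de("P", [1.6, 1.7, 1.2])],
               "CD3_CD28_vs_unstim": [_de("P", [1.0, 1.0, 1.0])]}
    (call,) = select_candidates(results, {"P": 0.80})
    assert call.passes and call.n_supporting_donors == 2 and call.reasons == []


def test_candidate_one_donor_fails():
    results = {"PMA_Iono_vs_unstim": [_de("P", [1.6, 1.2, 1.1])],
               "CD3_CD28_vs_unstim": [_de("P", [1.6, 1.2, 1.1])]}
    (call,) = select_candidates(results, {"P": 0.80})
    assert not call.passes
    assert any("donor" in r for r in call.reasons)


def test_candidate_similarity_boundary():
    results = {"PMA_Iono_vs_unstim": [_de("P", [2.0, 2.0, 2.0])]}
    (call,) = select_candidates(results, {"P": 0.75})
    assert not call.passes  # strictly above 0.75 required
    assert any("similarity" in r for r in call.reasons)


def test_candidate_fc_boundary():
    results = {"PMA_Iono_vs_unstim": [_de("P", [1.50, 1.50, 1.50])]}
    (call,) = select_candidates(results, {"P": 0.9})
    assert call.n_supporting_donors == 0 and not call.passes


def test_candidate_either_contrast_suffices():
    results = {"PMA_Iono_vs_unstim": [_de("P", [1.0, 1.0, 1.0])],
               "CD3_CD28_vs_unstim": [_de("P", [1.8, 1.9, 1.1])]}
    (call,) = select_candidates(results, {"P": 0.9})
    assert call.passes


def test_candidate_invariant():
    results = {"PMA_Iono_vs_unstim": [_de("P", [1.6, 1.7, 1.8])]}
    (call,) = select_candidates(results, {"P": 0.9})
    if call.passes:
        assert call.max_spectral_similarity > 0.75 and call.n_supporting_donors >= 2
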