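"""Spearman correlation, qPCR folds, reporter folds, interval overlap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nbprox.quant_stats import (
    GenomicInterval,
    correlate_groups,
    dual_reporter_fold,
    interval_intersection,
    interval_to_bed,
    qpcr_relative_quantity,
    spearman,
)


# ---------------------------------------------------------------------------
# spearman

def test_monotone_and_antimonotone():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).rho == pytest.approx(-1.0)


def test_single_swap_matches_rank_difference_formula():
    # classical no-tie formula: rho = 1 - 6*sum(d^2)/(n(n^2-1))
    out = spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
    assert out.rho == pytest.approx(1 - 6 * 2 / (5 * 24))  # = 0.9
    # exact permutation p at n=5: enumerate the 120 orderings
    count = 0
    for perm in itertools.permutations(range(1, 6)):
        d2 = sum((r - s) ** 2 for r, s in zip((1, 2, 3, 4, 5), perm))
        if abs(1 - 6 * d2 / (5 * 24)) >= 0.9 - 1e-12:
            count += 1
    assert out.p_value == pytest.approx(count / 120)


def test_matches_scipy_with_ties(rng):
    x = rng.integers(0, 5, size=40).astype(float)  # ties guaranteed
    y = x + rng.normal(0, 1, size=40)
    ours = spearman(x, y)
    ref = sps.spearmanr(x, y)
    assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)
    assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_two_samples_have_defined_rho_undefined_p():
    out = spearman([1.0, 2.0], [5.0, 3.0])
    assert out.rho == pytest.approx(-1.0)
    assert math.isnan(out.p_value)


def test_constant_input_is_undefined():
    out = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert math.isnan(out.rho) and math.isnan(out.p_value)


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [1, 2])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_invariant_under_increasing_transform_and_antisymmetric(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base = spearman(x, y).rho
    assert spearman(np.exp(x), y**3 + 5 * y).rho == pytest.approx(base, abs=1e-12)
    assert spearman(x, -y).rho == pytest.approx(-base, abs=1e-12)


# ---------------------------------------------------------------------------
# correlate_groups

def _expression_table():
    return pd.DataFrame({
        "group": ["lung"] * 6 + ["solo"] + ["pair"] * 2,
        "PML":   [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 1.0, 1.0, 2.0],
        "DDIT4": [1.1, 2.2, 2.9, 4.4, 5.5, 5.9, 2.0, 3.0, 7.0],
    })


def test_groups_include_pooled_and_degenerate_rows():
    results = {r.group: r for r in correlate_groups(_expression_table(), "PML", "DDIT4")}
    assert set(results) == {"All", "lung", "solo", "pair"}
    assert math.isnan(results["solo"].rho) and results["solo"].n == 1
    # two distinct samples: perfectly ranked, p undefined
    assert results["pair"].rho == pytest.approx(1.0)
    assert math.isnan(results["pair"].p_value)
    assert results["All"].n == 9


def test_mean_estimate_unbiased_at_panel_scale():
    # Gaussian copula with true rank correlation 0.35 at n = 174:
    # the mean of 500 replicate estimates recovers the truth
    rho_s = 0.35
    pearson = 2 * np.sin(np.pi * rho_s / 6)
    rng = np.random.default_rng(42)
    cov = np.array([[1.0, pearson], [pearson, 1.0]])
    estimates = []
    for _ in range(500):
        xy = rng.multivariate_normal([0, 0], cov, size=174)
        estimates.append(spearman(xy[:, 0], xy[:, 1]).rho)
    assert np.mean(estimates) == pytest.approx(rho_s, abs=0.02)


def test_gene_correlated_with_itself_is_one():
    table = _expression_table()
    for r in correlate_groups(table, "PML", "PML"):
        if r.n >= 2:
            assert r.rho == pytest.approx(1.0)


def test_unknown_gene_raises():
    with pytest.raises(KeyError):
        correlate_groups(_expression_table(), "PML", "NOPE")


def test_missing_values_dropped_pairwise():
    table = _expression_table()
    table.loc[0, "DDIT4"] = np.nan
    results = {r.group: r for r in correlate_groups(table, "PML", "DDIT4")}
    assert results["lung"].n == 5


# ---------------------------------------------------------------------------
# qPCR

def _cq_table(shift_target=0.0, shift_all=0.0, ref_shifts=(0.0, 0.0)):
    rows = []
    for cond, base in (("ctrl", 0.0), ("treated", 1.0)):
        for rep in range(3):
            rows.append(("s", cond, "DDIT4", rep, 20.0 - shift_target * (base) + shift_all))
            rows.append(("s", cond, "HMBS", rep, 22.0 - ref_shifts[0] * base + shift_all))
            rows.append(("s", cond, "RAC1", rep, 21.0 - ref_shifts[1] * base + shift_all))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "replicate", "cq"])


def test_identical_cq_gives_unit_folds():
    out = qpcr_relative_quantity(_cq_table(), "ctrl", ["HMBS", "RAC1"])
    for r in out:
        assert r.fold_change == pytest.approx(1.0)


def test_one_cycle_drop_doubles_fold():
    out = qpcr_relative_quantity(_cq_table(shift_target=1.0), "ctrl", ["HMBS", "RAC1"])
    folds = {(r.gene, r.condition): r.fold_change for r in out}
    assert folds[("DDIT4", "treated")] == pytest.approx(2.0)
    assert folds[("DDIT4", "ctrl")] == pytest.approx(1.0)


def test_opposite_reference_shifts_cancel_by_geometric_mean():
    out = qpcr_relative_quantity(
        _cq_table(ref_shifts=(1.0, -1.0)), "ctrl", ["HMBS", "RAC1"]
    )
    folds = {(r.gene, r.condition): r.fold_change for r in out}
    assert folds[("DDIT4", "treated")] == pytest.approx(1.0)


def test_fold_invariant_to_global_cq_offset():
    a = qpcr_relative_quantity(_cq_table(shift_target=1.3), "ctrl", ["HMBS", "RAC1"])
    b = qpcr_relative_quantity(
        _cq_table(shift_target=1.3, shift_all=2.5), "ctrl", ["HMBS", "RAC1"]
    )
    for ra, rb in zip(a, b):
        assert ra.fold_change == pytest.approx(rb.fold_change, rel=1e-12)


def test_missing_reference_gene_raises():
    table = _cq_table()
    table = table[~((table.gene == "HMBS") & (table.condition == "treated"))]
    with pytest.raises(ValueError, match="HMBS"):
        qpcr_relative_quantity(table, "ctrl", ["HMBS", "RAC1"])


# ---------------------------------------------------------------------------
# dual reporter

def test_control_fold_is_one_and_ratio_invariance(rng):
    base = pd.DataFrame({
        "construct": ["pLuc", "pLuc-promoter"],
        "firefly": [10.0, 3000.0],
        "renilla": [5.0, 5.0],
    })
    out = dual_reporter_fold(base, "pLuc").set_index("construct")["fold"]
    assert out["pLuc"] == pytest.approx(1.0)
    assert out["pLuc-promoter"] == pytest.approx(300.0)
    # doubling both signals (transfection efficiency) changes nothing
    doubled = base.assign(firefly=base.firefly * 2, renilla=base.renilla * 2)
    out2 = dual_reporter_fold(doubled, "pLuc").set_index("construct")["fold"]
    assert out2["pLuc-promoter"] == pytest.approx(300.0)


def test_reporter_matches_independent_two_step_computation(rng):
    n = 8
    table = pd.DataFrame({
        "construct": [f"c{i}" for i in range(n)],
        "firefly": rng.uniform(1, 100, n),
        "renilla": rng.uniform(1, 10, n),
    })
    out = dual_reporter_fold(table, "c0").set_index("construct")["fold"]
    control_ratio = table.firefly[0] / table.renilla[0]
    for i in range(n):
        expected = (table.firefly[i] / table.renilla[i]) / control_ratio
        assert out[f"c{i}"] == pytest.approx(expected, rel=1e-12)


def test_zero_renilla_raises():
    table = pd.DataFrame(
        {"construct": ["a"], "firefly": [1.0], "renilla": [0.0]}
    )
    with pytest.raises(ValueError, match="renilla"):
        dual_reporter_fold(table, "a")


# ---------------------------------------------------------------------------
# intervals

def test_disjoint_intervals_have_empty_intersection():
    a = GenomicInterval("a", 0, 1)
    b = GenomicInterval("b", 5, 6)
    assert interval_intersection(a, b) is None


def test_intersection_commutative_and_idempotent():
    a = GenomicInterval("promoter", -1561, 122)
    b = GenomicInterval("peak", -193, 316)
    ab = interval_intersection(a, b)
    ba = interval_intersection(b, a)
    assert (ab.start, ab.end) == (ba.start, ba.end)
    aa = interval_intersection(a, a)
    assert (aa.start, aa.end) == (a.start, a.end)


def test_invalid_interval_rejected():
    with pytest.raises(ValueError):
        GenomicInterval("bad", 5, 4)


def test_bed_conversion_is_zero_based_half_open():
    iv = GenomicInterval("x", -10, 9)  # 20 bases
    chrom, start, end = interval_to_bed(iv, "chr10", 1000)
    assert (chrom, start, end) == ("chr10", 990, 1010)
    assert end - start == iv.length
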