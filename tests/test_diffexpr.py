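"""Fold change, exact test, Bonferroni, run_de and trend classification."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avimir.diffexpr import (
    Comparison,
    DEParams,
    bonferroni,
    classify_trends,
    fisher_exact_2x2,
    fold_change,
    null_familywise_rate,
    run_de,
    standard_comparisons,
)
from avimir.quantify import CountTable


# ---------------------------------------------------------------------------
# fold_change
# ---------------------------------------------------------------------------

def test_fold_change_twofold_is_one():
    assert fold_change(30.0, 15.0, 1e-12) == pytest.approx(1.0, abs=1e-9)


def test_fold_change_equal_is_zero():
    assert fold_change(8.25, 8.25, 0.5) == 0.0


def test_fold_change_zero_with_pseudocount():
    # log2(0.5 / 10.5) = -log2(21)
    assert fold_change(0.0, 10.0, 0.5) == pytest.approx(-math.log2(21), abs=1e-12)
    assert fold_change(0.0, 10.0, 0.5) == pytest.approx(-4.392, abs=5e-4)


@given(st.floats(0, 1e6, allow_nan=False), st.floats(0, 1e6, allow_nan=False))
def test_fold_change_exact_antisymmetry(a, b):
    assert fold_change(a, b, 0.5) == -fold_change(b, a, 0.5)


def test_fold_change_validates_inputs():
    with pytest.raises(ValueError):
        fold_change(-1.0, 2.0, 0.5)
    with pytest.raises(ValueError):
        fold_change(1.0, 2.0, 0.0)


# ---------------------------------------------------------------------------
# fisher_exact_2x2 (with an exact-fraction enumeration oracle)
# ---------------------------------------------------------------------------

def oracle_fisher(x_a, n_a, x_b, n_b):
    """Exact-arithmetic enumeration over all tables with fixed margins."""
    s = x_a + x_b
    obs = math.comb(n_a, x_a) * math.comb(n_b, x_b)
    total = 0
    for k in range(max(0, s - n_b), min(s, n_a) + 1):
        c = math.comb(n_a, k) * math.comb(n_b, s - k)
        if c <= obs:
            total += c
    return Fraction(total, math.comb(n_a + n_b, s))


def test_fisher_identical_zero_margins():
    assert fisher_exact_2x2(0, 100, 0, 100) == 1.0


def test_fisher_against_enumeration_example():
    p = fisher_exact_2x2(5, 10, 0, 10)
    assert p == pytest.approx(float(oracle_fisher(5, 10, 0, 10)), abs=1e-12)


def test_fisher_symmetry_under_library_swap():
    a = fisher_exact_2x2(7, 40, 2, 35)
    b = fisher_exact_2x2(2, 35, 7, 40)
    assert a == pytest.approx(b, rel=1e-12)


def test_fisher_rejects_empty_library():
    with pytest.raises(ValueError):
        fisher_exact_2x2(0, 0, 1, 10)


def test_fisher_rejects_invalid_cells():
    with pytest.raises(ValueError):
        fisher_exact_2x2(11, 10, 0, 10)


@given(st.integers(1, 30), st.integers(1, 30), st.data())
def test_fisher_matches_oracle(n_a, n_b, data):
    x_a = data.draw(st.integers(0, n_a))
    x_b = data.draw(st.integers(0, n_b))
    p = fisher_exact_2x2(x_a, n_a, x_b, n_b)
    assert p == pytest.approx(float(oracle_fisher(x_a, n_a, x_b, n_b)), abs=1e-9)


def test_fisher_large_margins_stay_sane():
    p = fisher_exact_2x2(500, 1_000_000, 2000, 1_000_000)
    assert 0.0 < p < 1e-100


# ---------------------------------------------------------------------------
# bonferroni
# ---------------------------------------------------------------------------

def test_bonferroni_single_test():
    threshold, flags = bonferroni([0.04], alpha=0.05)
    assert threshold == 0.05 and flags == [True]


def test_bonferroni_ten_tests():
    threshold, flags = bonferroni([0.006] + [0.5] * 9, alpha=0.05)
    assert threshold == pytest.approx(0.005)
    assert flags[0] is False


def test_bonferroni_large_family_threshold():
    threshold, _ = bonferroni([0.5] * 2550, alpha=0.05)
    assert threshold == pytest.approx(1.9608e-05, rel=1e-3)


def test_bonferroni_empty_is_error():
    with pytest.raises(ValueError):
        bonferroni([])


# ---------------------------------------------------------------------------
# run_de
# ---------------------------------------------------------------------------

def _ct(rows, denominators):
    return CountTable(
        counts=pd.DataFrame(rows, index=list(denominators)).T.astype(int),
        denominators=denominators,
        ref_fingerprint="fp",
    )


def test_run_de_planted_fourfold_flagged(small_sim, small_count_table, small_lib_meta):
    _, _, truth, _ = small_sim
    results = run_de(small_count_table, standard_comparisons(small_lib_meta))
    idx = {(r.name, r.comparison): r for r in results}
    for name in truth.planted["de_up"]:
        for sp in ("gga", "apl", "cja"):
            r = idx[(name, f"{sp}:HH25/HH20")]
            assert r.de_flag and r.log2_fc > 0 and r.significant
    for name in truth.planted["de_down"]:
        for sp in ("gga", "apl", "cja"):
            r = idx[(name, f"{sp}:HH25/HH20")]
            assert r.de_flag and r.log2_fc < 0 and r.significant


def test_run_de_identical_pmmr_not_flagged():
    ct = _ct({"m": [100, 100]}, {"A": 1_000_000, "B": 1_000_000})
    comps = [Comparison("A", "B", "species_at_stage", "A/B")]
    (res,) = run_de(ct, comps)
    assert res.log2_fc == 0.0 and not res.de_flag


def test_run_de_below_detection_never_flagged():
    # 10-fold change but both libraries below the 15 PMMR detection threshold
    ct = _ct({"m": [10, 1]}, {"A": 1_000_000, "B": 1_000_000})
    comps = [Comparison("A", "B", "species_at_stage", "A/B")]
    (res,) = run_de(ct, comps)
    assert abs(res.log2_fc) > 1 and not res.detected and not res.de_flag


def test_run_de_unknown_library_rejected(small_count_table):
    with pytest.raises(ValueError, match="unknown library"):
        run_de(small_count_table, [Comparison("nope", "also-nope", "x", "bad")])


def test_de_flag_invariant_to_row_relabeling():
    ct1 = _ct({"a": [400, 100], "b": [100, 100]}, {"A": 1_000_000, "B": 1_000_000})
    ct2 = _ct({"z": [400, 100], "b": [100, 100]}, {"A": 1_000_000, "B": 1_000_000})
    comps = [Comparison("A", "B", "species_at_stage", "A/B")]
    flags1 = {r.name: r.de_flag for r in run_de(ct1, comps)}
    flags2 = {r.name: r.de_flag for r in run_de(ct2, comps)}
    assert flags1["a"] == flags2["z"] and flags1["b"] == flags2["b"]


# ---------------------------------------------------------------------------
# trend classification
# ---------------------------------------------------------------------------

LIB_META = {
    f"{sp}-{stage}": (sp, stage)
    for sp in ("gga", "apl", "cja")
    for stage in ("HH20", "HH25")
}


def _trend_ct(per_mirna):
    """per_mirna: name -> {library id: count}; denominators 1e6 everywhere."""
    rows = {
        name: [cells[lib] for lib in LIB_META]
        for name, cells in per_mirna.items()
    }
    df = pd.DataFrame(rows).T
    df.columns = list(LIB_META)
    return CountTable(counts=df.astype(int),
                      denominators={lib: 1_000_000 for lib in LIB_META})


def _flat(v20, v25=None):
    v25 = v20 if v25 is None else v25
    return {
        "gga-HH20": v20, "gga-HH25": v25,
        "apl-HH20": v20, "apl-HH25": v25,
        "cja-HH20": v20, "cja-HH25": v25,
    }


def _classify(per_mirna):
    ct = _trend_ct(per_mirna)
    results = run_de(ct, standard_comparisons(LIB_META))
    return {t.name: t.trend for t in classify_trends(results, LIB_META)}


def test_trend_up_all3():
    trends = _classify({"m": _flat(100, 400), "flat": _flat(500)})
    assert trends["m"] == "up_all3_HH25"
    assert trends["flat"] == "other"


def test_trend_down_all3():
    trends = _classify({"m": _flat(400, 100)})
    assert trends["m"] == "down_all3_HH25"


def test_trend_up_chicken_quail_only():
    cells = _flat(100, 400)
    cells["apl-HH25"] = 100  # duck stays flat
    assert _classify({"m": cells})["m"] == "up_chicken_quail_only"


def test_trend_duck_high_hh25_only():
    cells = _flat(100)
    cells["apl-HH25"] = 400
    assert _classify({"m": cells})["m"] == "duck_high_HH25_only"


def test_trend_duck_high_both_stages():
    cells = _flat(100)
    cells["apl-HH20"] = 400
    cells["apl-HH25"] = 400
    assert _classify({"m": cells})["m"] == "duck_high_both_stages"


def test_trend_duck_low_both_stages():
    cells = _flat(400)
    cells["apl-HH20"] = 100
    cells["apl-HH25"] = 100
    assert _classify({"m": cells})["m"] == "duck_low_both_stages"


def test_trend_missing_comparison_is_error():
    ct = _trend_ct({"m": _flat(100)})
    comps = standard_comparisons(LIB_META)[:4]
    results = run_de(ct, comps)
    with pytest.raises(ValueError, match="missing comparison"):
        classify_trends(results, LIB_META)


def test_null_familywise_rate_small():
    # quick sanity run; the acceptance suite runs the full 200-run version
    rate = null_familywise_rate(30, 50_000, 50_000, 40, seed=2, alpha=0.05)
    assert rate <= 0.2
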