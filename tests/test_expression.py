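"""Livak quantification, LSD lettering, correlations."""

import numpy as np
import pandas as pd
import pytest
from _oracles import pearson_brute
from scipy import stats

from sodsplice import simulate as sim
from sodsplice.errors import EvidenceError, InputError
from sodsplice.expression import (KARYOGAMY_TABLE, ddct_fold_change,
                                  karyogamy_correlation, lsd_letters,
                                  pearson_correlation)


def _table(rows):
    return pd.DataFrame(rows, columns=["sample", "condition", "gene",
                                       "replicate", "ct"])


def test_ddct_closed_form():
    rows = []
    for cond, tct in (("control", 22.0), ("treated", 20.0)):
        for r in (1, 2, 3):
            rows.append((f"{cond}_r{r}", cond, "gapdh", r, 18.0))
            rows.append((f"{cond}_r{r}", cond, "sod1", r, tct))
    res = ddct_fold_change(_table(rows), "gapdh", "control")
    res = res.set_index("condition")
    assert res.loc["treated", "ddct"] == pytest.approx(-2.0)
    assert res.loc["treated", "fold"] == pytest.approx(4.0)
    assert res.loc["control", "fold"] == pytest.approx(1.0)


def test_calibrator_fold_exactly_one_under_noise():
    for seed in range(5):
        d = sim.CtDesign(genes=("g1", "g2"), conditions=("a", "b"),
                         calibrator="a",
                         fold_changes=(("g1", "b", 3.0),),
                         replicates=4, ct_sd=0.4, seed=seed)
        res = ddct_fold_change(sim.generate_ct_table(d), "gapdh", "a")
        cal = res[res.condition == "a"]
        assert (cal["fold"] == 1.0).all()


def test_missing_reference_names_sample():
    rows = [("a_r1", "a", "sod1", 1, 20.0), ("a_r2", "a", "sod1", 2, 20.0),
            ("a_r1", "a", "gapdh", 1, 18.0)]
    with pytest.raises(EvidenceError, match="replicate 2"):
        ddct_fold_change(_table(rows), "gapdh", "a")


def test_fold_recovery_within_five_percent():
    d = sim.CtDesign(genes=("cuzn",), conditions=("control", "cold"),
                     calibrator="control",
                     fold_changes=(("cuzn", "cold", 5.1),),
                     replicates=4, ct_sd=0.05, seed=1)
    res = ddct_fold_change(sim.generate_ct_table(d), "gapdh", "control")
    fold = float(res[res.condition == "cold"]["fold"].iloc[0])
    assert abs(fold - 5.1) / 5.1 <= 0.05


def test_log_scale_unbiasedness():
    """Across 200 simulated tables (Ct noise sd 0.2) the mean log2 fold
    estimate stays within +/- 0.05 of the truth."""
    true = 3.7
    logs = []
    for seed in range(200):
        d = sim.CtDesign(genes=("g",), conditions=("a", "b"), calibrator="a",
                         fold_changes=(("g", "b", true),),
                         replicates=4, ct_sd=0.2, seed=seed)
        res = ddct_fold_change(sim.generate_ct_table(d), "gapdh", "a")
        logs.append(np.log2(float(res[res.condition == "b"]["fold"].iloc[0])))
    assert abs(np.mean(logs) - np.log2(true)) <= 0.05


# ---------------------------------------------------------------------------
# LSD letters

def test_lsd_well_separated_groups_all_distinct():
    letters, summary = lsd_letters({
        "low": [1.0, 1.1, 0.9], "mid": [10.0, 10.2, 9.8],
        "high": [100.0, 99.0, 101.0]})
    assert len({letters[g] for g in letters}) == 3
    assert letters["high"] == "a"  # highest mean lettered first
    assert summary["p"] < 1e-6


def test_lsd_identical_groups_share_a():
    letters, _ = lsd_letters({"x": [5.0, 5.2, 4.8], "y": [5.1, 4.9, 5.0],
                              "z": [5.0, 5.1, 4.9]})
    assert set(letters.values()) == {"a"}


def test_lsd_two_groups_match_pooled_t():
    a, b = [4.0, 4.3, 3.9, 4.1], [5.0, 5.2, 4.9, 5.3]
    _, summary = lsd_letters({"a": a, "b": b})
    t, p = stats.ttest_ind(a, b, equal_var=True)
    assert summary["pairwise_p"].loc["a", "b"] == pytest.approx(p)


def test_lsd_letters_consistent_with_pairwise():
    rng = np.random.default_rng(77)
    for trial in range(10):
        groups = {f"g{i}": rng.normal(rng.uniform(0, 3), 0.5, 4)
                  for i in range(5)}
        try:
            letters, summary = lsd_letters(groups, alpha=0.05)
        except InputError:
            continue
        p = summary["pairwise_p"]
        for a in groups:
            for b in groups:
                if a >= b:
                    continue
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == (p.loc[a, b] >= 0.05)


def test_lsd_degenerate_variance_raises():
    with pytest.raises(InputError, match="degenerate"):
        lsd_letters({"a": [1.0, 1.0], "b": [2.0, 2.0]})


# ---------------------------------------------------------------------------
# correlations

def test_pearson_examples():
    assert pearson_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)
    assert pearson_correlation([1, 2, 3], [1, 2, 4]) == \
        pytest.approx(0.9820, abs=1e-4)


def test_pearson_affine_invariance():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=10), rng.normal(size=10)
    r = pearson_correlation(x, y)
    assert pearson_correlation(3 * x + 2, y) == pytest.approx(r)
    assert pearson_correlation(x, 0.5 * y - 7) == pytest.approx(r)


def test_pearson_errors():
    with pytest.raises(InputError, match="zero variance"):
        pearson_correlation([1, 1, 1], [1, 2, 3])
    with pytest.raises(InputError, match="length"):
        pearson_correlation([1, 2], [1, 2, 3])


def test_karyogamy_correlation():
    # proportional expression -> r = 1
    expr = {"g": {"egg": 37.5 * 2, "elongation": 60.0, "maturation": 0.2}}
    assert karyogamy_correlation(expr)["g"] == pytest.approx(1.0)
    # closed-form check against an independent implementation
    expr2 = {"g": {"egg": 10.0, "elongation": 8.0, "maturation": 0.2}}
    got = karyogamy_correlation(expr2)["g"]
    want = pearson_brute([10.0, 8.0, 0.2], [37.5, 30.0, 0.1])
    assert got == pytest.approx(want)
    with pytest.raises(InputError):
        karyogamy_correlation({"g": {"egg": 1.0, "elongation": 1.0,
                                     "maturation": 1.0}})
    with pytest.raises(InputError, match="stages"):
        karyogamy_correlation({"g": {"egg": 1.0, "button": 2.0,
                                     "maturation": 3.0}})
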