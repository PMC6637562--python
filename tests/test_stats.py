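"""Core statistics: PR, BC bootstrap, significance calls, FC and RC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosphogel import (DifferentialRecord, PRSummary, UndefinedFoldChangeError,
                        UndefinedPRError, analyze_spot_set, bc_bootstrap_ci,
                        bonferroni_conf, fold_change, phosphorylation_rate,
                        relative_change, reproducibility_filter,
                        scenario_preset, significance_call,
                        generate_spot_table)
from _oracles import bc_bootstrap_ci_enumeration


# ------------------------------------------------------------------------ PR

@pytest.mark.parametrize("p,t,expected", [(0.5, 1.0, 0.5), (0.0, 2.0, 0.0),
                                          (3.0, 3.0, 1.0), (1.2, 0.8, 1.5)])
def test_phosphorylation_rate(p, t, expected):
    assert phosphorylation_rate(p, t) == pytest.approx(expected)


def test_pr_undefined_for_zero_total():
    with pytest.raises(UndefinedPRError):
        phosphorylation_rate(1.0, 0.0)


def test_pr_above_threshold_logs_warning(caplog):
    with caplog.at_level("WARNING"):
        phosphorylation_rate(2.0, 1.0)
    assert "exceeds" in caplog.text


# ------------------------------------------------------------- BC bootstrap

def test_bootstrap_degenerate_input():
    assert bc_bootstrap_ci([0.3, 0.3, 0.3, 0.3]) == (0.3, 0.3)


def test_bootstrap_needs_two_values():
    with pytest.raises(ValueError):
        bc_bootstrap_ci([1.0])


def test_bootstrap_bounds_bracket_within_sample_range():
    vals = [0.2, 0.3, 0.4, 0.5]
    cl, cu = bc_bootstrap_ci(vals, conf=0.95, seed=0)
    assert min(vals) <= cl < cu <= max(vals)


@pytest.mark.parametrize("conf", [0.8, 0.95, 0.99])
def test_bootstrap_matches_enumeration_oracle(conf):
    """Monte-Carlo bounds at n_boot=20000 sit within +-0.015 of the exact
    4^4-resample enumeration for a fixed quadruple."""
    vals = [0.2, 0.3, 0.4, 0.5]
    mc = bc_bootstrap_ci(vals, conf=conf, n_boot=20_000, seed=42)
    exact = bc_bootstrap_ci_enumeration(vals, conf)
    assert mc == pytest.approx(exact, abs=0.015)


def test_bootstrap_converges_to_oracle():
    """The MC-vs-enumeration gap shrinks roughly like 1/sqrt(n_boot)."""
    vals = [0.11, 0.27, 0.45, 0.58]
    exact = bc_bootstrap_ci_enumeration(vals, 0.95)
    gaps = []
    for n_boot in (500, 50_000):
        reps = [bc_bootstrap_ci(vals, 0.95, n_boot=n_boot, seed=s)
                for s in range(20)]
        gaps.append(np.mean([abs(cl - exact[0]) + abs(cu - exact[1])
                             for cl, cu in reps]))
    assert gaps[1] < gaps[0] / 3  # 100x more resamples -> ~10x tighter


def test_bootstrap_coverage_agrees_with_oracle():
    """On N=4 lognormal data the MC interval reproduces the enumeration
    interval dataset by dataset (hence identical coverage behavior), up to
    rare single-atom flips of the discrete bootstrap distribution."""
    from _oracles import bc_bounds_agreement
    rng = np.random.default_rng(5)
    flips = 0
    for _ in range(200):
        vals = rng.lognormal(-1.0, 0.5, size=4)
        mc = bc_bootstrap_ci(vals, 0.95, n_boot=20_000,
                             seed=int(rng.integers(1 << 30)))
        for gap, between in bc_bounds_agreement(vals, mc, 0.95):
            scale = float(np.mean(vals))
            if gap > 0.02 * scale + 0.005:
                assert between <= 1, (vals, mc)
                flips += 1
    assert flips <= 40  # ~5% of 400 bounds in expectation


# ----------------------------------------------------------- Bonferroni conf

@pytest.mark.parametrize("alpha,m,expected", [
    (0.05, 1, 0.95), (0.05, 2, 0.975), (0.05, 59, 1 - 0.05 / 59)])
def test_bonferroni_conf(alpha, m, expected):
    assert bonferroni_conf(alpha, m) == pytest.approx(expected, abs=1e-12)


# -------------------------------------------------------- significance calls

def _summary(spot, lo, hi):
    return PRSummary(spot_id=spot, group="g", pr_values=[lo, hi],
                     mean_pr=(lo + hi) / 2, ci_lower=lo, ci_upper=hi)


def _zero_summary(spot):
    return PRSummary(spot_id=spot, group="g")


@pytest.mark.parametrize("treated,control,expected", [
    (_summary("5", 0.051, 0.108), _summary("5", 0.169, 0.696), "yes"),
    (_summary("1", 0.292, 0.603), _zero_summary("1"), "yes"),
    (_summary("x", 0.1, 0.4), _summary("x", 0.3, 0.6), "no"),
    (_zero_summary("y"), _zero_summary("y"), "not_evaluable"),
    (PRSummary("z", "g", [0.0, 0.1], 0.05, ci_lower=0.0, ci_upper=0.1),
     _zero_summary("z"), "no"),  # lone CI touching zero is not a call
])
def test_significance_call(treated, control, expected):
    assert significance_call(treated, control) == expected


# ----------------------------------------------------------------- FC and RC

@pytest.mark.parametrize("pt,pc,expected", [
    (0.08, 0.36, -4.50), (0.7, 0.7, 1.0), (0.41, 0.0, math.inf),
    (0.0, 0.12, -math.inf), (0.36, 0.08, 4.50)])
def test_fold_change(pt, pc, expected):
    assert fold_change(pt, pc) == pytest.approx(expected)


def test_fold_change_undefined_both_zero():
    with pytest.raises(UndefinedFoldChangeError):
        fold_change(0.0, 0.0)


@given(st.floats(1e-6, 1e3), st.floats(1e-6, 1e3))
def test_fold_change_magnitude_and_antisymmetry(a, b):
    """|FC| >= 1 always, and swapping the groups flips the convention:
    fc(a,b) and fc(b,a) have opposite signs (unless both are +1) and the
    same magnitude of ratio."""
    f, g = fold_change(a, b), fold_change(b, a)
    assert abs(f) >= 1 and abs(g) >= 1
    if a != b:
        assert math.copysign(1, f) == -math.copysign(1, g)
        assert abs(f) == pytest.approx(abs(g), rel=1e-9)


import contextlib


def _no_warning():
    return contextlib.nullcontext()


def _draft(sid, dpr):
    return DifferentialRecord(spot_id=sid, pr_treated=max(dpr, 0.0),
                              pr_control=max(-dpr, 0.0), dpr=dpr, fc=1.0)


def test_relative_change_table_values():
    """RC over the 32-spot reference means: argmax +1, spot 1 at +0.44."""
    from phosphogel import reference, records_from_means
    ref = reference.load_significant_spots()
    recs = records_from_means(ref, "pr_dfd_mean", "pr_c_mean")
    by_id = {r.spot_id: r for r in recs}
    assert max(r.dpr for r in recs) == pytest.approx(0.94)
    assert by_id["54"].rc == pytest.approx(1.00)
    assert by_id["1"].rc == pytest.approx(0.44, abs=0.005)


@given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30))
def test_relative_change_bounds(dprs):
    records = [_draft(f"s{i}", d) for i, d in enumerate(dprs)]
    if all(d == 0 for d in dprs):
        with pytest.warns(UserWarning):
            relative_change(records)
        assert all(r.rc == 0 for r in records)
        return
    with pytest.warns() if abs(max(dprs)) < max(abs(d) for d in dprs) else \
            _no_warning():
        relative_change(records)
    assert all(-1 - 1e-12 <= r.rc <= 1 + 1e-12 for r in records)
    if max(dprs) > 0 and max(dprs) == max(abs(d) for d in dprs):
        argmax = max(records, key=lambda r: r.dpr)
        assert argmax.rc == pytest.approx(1.0)
    assert all(math.copysign(1, r.rc) == math.copysign(1, r.dpr)
               for r in records if r.dpr != 0)


def test_relative_change_zero_dpr_is_zero_rc():
    records = [_draft("a", 0.5), _draft("b", 0.0)]
    relative_change(records)
    assert records[1].rc == 0.0


# ------------------------------------------------------------ orchestration

def test_analyze_noise_free_recovers_truth_exactly():
    cfg = scenario_preset("noise_free", seed=3)
    t, c, truth = generate_spot_table(cfg)
    _, recs = analyze_spot_set(reproducibility_filter(t),
                               reproducibility_filter(c), n_boot=2000, seed=0)
    frac = truth.per_group.pivot(index="spot_id", columns="group",
                                 values="phospho_fraction")
    for r in recs:
        expected = frac.loc[r.spot_id, "DFD"] - frac.loc[r.spot_id, "control"]
        assert r.dpr == pytest.approx(expected, abs=1e-12)
        assert r.significant == "yes"


def test_analyze_deterministic_under_seed():
    cfg = scenario_preset("small_recovery", seed=4)
    t, c, _ = generate_spot_table(cfg)
    t, c = reproducibility_filter(t), reproducibility_filter(c)
    out1 = analyze_spot_set(t, c, n_boot=3000, seed=17)
    out2 = analyze_spot_set(t, c, n_boot=3000, seed=17)
    for s1, s2 in zip(out1[0], out2[0]):
        assert (s1.ci_lower, s1.ci_upper) == (s2.ci_lower, s2.ci_upper)


def test_analyze_requires_common_spots():
    cfg1 = scenario_preset("noise_free", seed=1)
    t, _, _ = generate_spot_table(cfg1)
    other = t.copy()
    other["group"] = "control"
    other["spot_id"] = "Z" + other["spot_id"]
    with pytest.raises(ValueError, match="no spot"):
        analyze_spot_set(t, other, n_boot=100, seed=0)
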