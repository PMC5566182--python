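"""Centering, DLRS, interval scoring, the recursive maximal-interval
search, and call-set integration."""

import numpy as np
import pytest

from exoncgh.panel_io import CnvCall, GenomicInterval, ProbeSignal
from exoncgh.aberration_caller import (
    CallerConfig,
    MODE_GLOBAL,
    MODE_WEIGHTED,
    call_aberrations,
    center_signal,
    copy_number_estimate,
    dlrs,
    find_aberrations,
    integrate_calls,
    score_interval,
)
from conftest import cnv_signals, flat_signals


def _signals_from(values, errors=None, chrom="chr1", spacing=1000):
    errors = errors if errors is not None else [0.2] * len(values)
    return [
        ProbeSignal(f"p{i}", GenomicInterval(chrom, i * spacing, i * spacing + 60),
                    float(v), float(e))
        for i, (v, e) in enumerate(zip(values, errors))
    ]


# ---------------------------------------------------------------------------
# Centering
# ---------------------------------------------------------------------------


def test_center_constant_signal_gives_zeros_and_offset():
    sig = _signals_from([0.7] * 20)
    centered, offset = center_signal(sig)
    assert offset == pytest.approx(0.7, abs=0.01)
    assert all(abs(s.log2_ratio) < 0.01 for s in centered)


def test_center_is_idempotent():
    sig = cnv_signals(500, 100, 130, 3, seed=4)
    once, off1 = center_signal(sig)
    twice, off2 = center_signal(once)
    assert abs(off2) <= 0.01


def test_center_small_cnv_fraction_offset_near_zero():
    # 5 % of probes in a gain; mode centering must not chase them
    sig = cnv_signals(1000, 500, 550, 3, seed=9)
    _, offset = center_signal(sig)
    assert abs(offset) < 0.02


def test_center_requires_ten_probes():
    with pytest.raises(ValueError):
        center_signal(_signals_from([0.0] * 5))


# ---------------------------------------------------------------------------
# DLRS
# ---------------------------------------------------------------------------


def test_dlrs_constant_signal_is_zero():
    assert dlrs(_signals_from([0.3] * 50)) == 0.0


def test_dlrs_recovers_iid_noise_sd():
    sig = flat_signals(10_000, sigma=0.2, seed=12)
    assert dlrs(sig) == pytest.approx(0.2, abs=0.01)


def test_dlrs_alternating_closed_form():
    a = 0.4
    sig = _signals_from([a if i % 2 == 0 else -a for i in range(40)])
    assert dlrs(sig) == pytest.approx(1.4826 * 2 * a / np.sqrt(2))


def test_dlrs_needs_two_probes():
    with pytest.raises(ValueError):
        dlrs(_signals_from([0.1]))


# ---------------------------------------------------------------------------
# Interval score
# ---------------------------------------------------------------------------


def test_score_zero_interval():
    sig = _signals_from([0.0] * 10)
    assert score_interval(sig, 0, 9, MODE_GLOBAL, sigma_hat=0.2) == 0.0


def test_score_hand_arithmetic():
    # nine probes at +1 with sigma_hat 1: S = 9 / (1 * sqrt(9)) = 3
    sig = _signals_from([1.0] * 9)
    assert score_interval(sig, 0, 8, MODE_GLOBAL, sigma_hat=1.0) == pytest.approx(3.0)


def test_weighted_equals_global_when_errors_uniform():
    rng = np.random.default_rng(21)
    values = rng.normal(0, 0.2, 120)
    sigma = 0.2
    sig = _signals_from(values, errors=[sigma] * 120)
    for _ in range(100):
        i, j = sorted(rng.integers(0, 120, 2))
        g = score_interval(sig, i, j, MODE_GLOBAL, sigma_hat=sigma)
        w = score_interval(sig, i, j, MODE_WEIGHTED)
        assert w == pytest.approx(g, rel=1e-9)


def test_score_errors_rejected():
    sig = _signals_from([0.1] * 5)
    with pytest.raises(ValueError):
        score_interval(sig, 0, 4, MODE_GLOBAL, sigma_hat=0.0)


def test_scores_invariant_under_common_scaling():
    rng = np.random.default_rng(3)
    values = rng.normal(0, 0.2, 50)
    sig = _signals_from(values, errors=[0.2] * 50)
    scaled = _signals_from(3.7 * values, errors=[3.7 * 0.2] * 50)
    for i, j in [(0, 49), (5, 20), (30, 31)]:
        assert score_interval(scaled, i, j, MODE_GLOBAL, sigma_hat=3.7 * 0.2) == \
            pytest.approx(score_interval(sig, i, j, MODE_GLOBAL, sigma_hat=0.2))
        assert score_interval(scaled, i, j, MODE_WEIGHTED) == \
            pytest.approx(score_interval(sig, i, j, MODE_WEIGHTED))


# ---------------------------------------------------------------------------
# find_aberrations
# ---------------------------------------------------------------------------


def test_uncentered_input_rejected():
    sig = flat_signals(100, seed=0)
    with pytest.raises(ValueError, match="centered"):
        find_aberrations(sig, CallerConfig())


def test_null_array_yields_no_calls():
    sig = flat_signals(1000, sigma=0.2, seed=42)
    calls, _ = call_aberrations(sig, CallerConfig())
    assert calls == []


def test_injected_gain_detected_with_copy_number_three():
    # 10 probes at mu=+0.58 in 0.2 noise: expected S ~ (0.58/0.2)*sqrt(10) ~ 9.2
    sig = cnv_signals(800, 400, 410, 3, sigma=0.2, seed=6)
    calls, meta = call_aberrations(sig, CallerConfig())
    assert len(calls) == 1
    call = calls[0]
    assert call.cnv_type == "gain"
    assert call.cn_estimate == 3
    assert call.score >= 6.0
    # the called probes are (close to) the injected ones
    assert abs(call.interval.start - sig[400].interval.start) <= 2000
    assert abs(call.interval.stop - sig[409].interval.stop) <= 2000


def test_injected_loss_detected_with_copy_number_one():
    sig = cnv_signals(800, 200, 210, 1, sigma=0.2, seed=6)
    calls, _ = call_aberrations(sig, CallerConfig())
    assert len(calls) == 1
    assert calls[0].cnv_type == "loss"
    assert calls[0].cn_estimate == 1


def test_search_matches_exhaustive_all_pairs_oracle():
    """Top call equals the argmax of a brute-force scorer over every (i,j)."""
    for seed in (1, 2, 3):
        sig = cnv_signals(400, 150, 170, 3, sigma=0.2, seed=seed)
        centered, _ = center_signal(sig)
        sigma_hat = dlrs(centered)
        calls = find_aberrations(
            centered, CallerConfig(), MODE_GLOBAL, sigma_hat, centered=True
        )
        r = np.array([s.log2_ratio for s in centered])
        P = np.concatenate([[0.0], np.cumsum(r)])
        n = len(r)
        sums = P[None, 1:] - P[:-1, None]  # sums[i, j] = r[i..j] (j >= i)
        lengths = np.arange(1, n + 1)[None, :] - np.arange(n)[:, None]
        with np.errstate(invalid="ignore"):
            scores = np.abs(sums) / (sigma_hat * np.sqrt(np.where(lengths > 0, lengths, 1)))
        scores[lengths <= 0] = -1
        i, j = np.unravel_index(np.argmax(scores), scores.shape)
        top = max(calls, key=lambda c: c.score)
        assert top.score == pytest.approx(float(scores[i, j]))
        assert top.interval.start == centered[i].interval.start
        assert top.interval.stop == centered[j].interval.stop


def test_adm1_and_adm2_identical_under_uniform_errors():
    rng = np.random.default_rng(17)
    values = rng.normal(0, 0.2, 600)
    values[100:115] += 0.58
    values[300:310] -= 1.0
    sig = _signals_from(values, errors=[0.2] * 600)
    c1 = find_aberrations(sig, CallerConfig(), MODE_GLOBAL, sigma_hat=0.2, centered=True)
    c2 = find_aberrations(sig, CallerConfig(), MODE_WEIGHTED, centered=True)
    assert [(c.interval, c.cnv_type, c.n_probes) for c in c1] == \
        [(c.interval, c.cnv_type, c.n_probes) for c in c2]
    for a, b in zip(c1, c2):
        assert a.score == pytest.approx(b.score)


def test_calls_within_one_mode_never_overlap():
    rng = np.random.default_rng(23)
    values = rng.normal(0, 0.2, 500)
    values[50:70] += 0.6
    values[80:100] -= 1.0
    values[300:330] += 0.6
    sig = _signals_from(values, errors=[0.2] * 500)
    calls = find_aberrations(sig, CallerConfig(), MODE_GLOBAL, sigma_hat=0.2,
                             centered=True)
    assert len(calls) >= 2
    for a, b in zip(calls, calls[1:]):
        assert a.interval.overlap(b.interval) == 0


def test_isolated_outlier_does_not_mask_a_real_call():
    values = np.zeros(200)
    values[10] = 3.0  # single-probe spike: passes T, fails min_probes
    values[100:110] = -1.0
    sig = _signals_from(values, errors=[0.2] * 200)
    calls = find_aberrations(sig, CallerConfig(), MODE_GLOBAL, sigma_hat=0.2,
                             centered=True)
    assert any(c.cnv_type == "loss" and c.n_probes == 10 for c in calls)


@pytest.mark.parametrize(
    "mean,expected", [(0.58, 3), (-1.0, 1), (0.0, 2), (1.0, 4), (-5.0, 0), (3.0, 8)]
)
def test_copy_number_estimate_mapping(mean, expected):
    assert copy_number_estimate(mean) == expected


# ---------------------------------------------------------------------------
# Detection monotonicity (common random numbers across conditions)
# ---------------------------------------------------------------------------


def test_detection_monotone_in_amplitude_and_length():
    amplitudes = [0.3, 0.6, 1.0]
    lengths = [3, 5, 10]
    n, sigma, reps = 150, 0.2, 200
    rng = np.random.default_rng(2024)
    noise = rng.normal(0, sigma, (reps, n))
    det = np.zeros((3, 3))
    cfg = CallerConfig()
    for ai, amp in enumerate(amplitudes):
        for li, L in enumerate(lengths):
            hits = 0
            for rep in range(reps):
                values = noise[rep].copy()
                values[60 : 60 + L] += amp
                sig = _signals_from(values, errors=[sigma] * n)
                calls = find_aberrations(sig, cfg, MODE_GLOBAL,
                                         sigma_hat=sigma, centered=True)
                hits += bool(calls)
            det[ai, li] = hits / reps
    # non-decreasing across amplitude (rows) and length (columns); the
    # shared noise panel makes the comparison nearly paired
    slack = 0.03
    for li in range(3):
        assert det[0, li] <= det[1, li] + slack <= det[2, li] + 2 * slack
    for ai in range(3):
        assert det[ai, 0] <= det[ai, 1] + slack <= det[ai, 2] + 2 * slack
    assert det[2, 2] > det[0, 0]


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _call(chrom, start, stop, cnv_type, score=8.0, mean=None):
    mean = mean if mean is not None else (0.6 if cnv_type == "gain" else -1.0)
    return CnvCall(
        interval=GenomicInterval(chrom, start, stop), cnv_type=cnv_type,
        n_probes=5, mean_log2=mean, score=score, algorithms=("ADM1-like",),
    )


def test_integrate_identical_lists_all_both():
    calls = [_call("chr1", 0, 1000, "gain"), _call("chr2", 0, 500, "loss")]
    merged = integrate_calls(calls, calls)
    assert len(merged) == 2
    assert all(c.tier == "both" for c in merged)


def test_integrate_retains_single_algorithm_calls():
    # one gain seen by the global algorithm only, one loss seen by both —
    # the single-algorithm gain must survive integration
    adm1 = [_call("chr1", 0, 1000, "gain"), _call("chr17", 0, 700, "loss")]
    adm2 = [_call("chr17", 100, 700, "loss")]
    merged = integrate_calls(adm1, adm2)
    assert len(merged) == 2
    tiers = {c.cnv_type: c.tier for c in merged}
    assert tiers == {"gain": "single-algorithm", "loss": "both"}
    loss = next(c for c in merged if c.cnv_type == "loss")
    assert (loss.interval.start, loss.interval.stop) == (0, 700)  # union


def test_integrate_empty_lists():
    assert integrate_calls([], []) == []


def test_integrate_type_mismatch_never_merges():
    adm1 = [_call("chr1", 0, 1000, "gain")]
    adm2 = [_call("chr1", 0, 1000, "loss")]
    merged = integrate_calls(adm1, adm2)
    assert len(merged) == 2
    assert all(c.tier == "single-algorithm" for c in merged)


def test_integrate_output_bounded_by_input_sizes():
    adm1 = [_call("chr1", i * 10_000, i * 10_000 + 5000, "gain") for i in range(4)]
    adm2 = [_call("chr1", i * 10_000 + 1000, i * 10_000 + 6000, "gain") for i in range(3)]
    merged = integrate_calls(adm1, adm2)
    assert len(merged) <= len(adm1) + len(adm2)
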