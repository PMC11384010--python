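"""Burst search, corrections, photon-HMM likelihood/fitting and validation tools."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from akdyn.fret import (
    BurstSearchConfig,
    HMMModel,
    PhotonBurst,
    PhotonStream,
    burst_search,
    burst_variance_analysis,
    estimate_corrections,
    fret_histogram,
    hmm_fit,
    hmm_likelihood,
    kc_from_model,
    recoloring_test,
    select_double_labeled,
    viterbi,
)
from akdyn.fret.bursts import apply_corrections
from akdyn.simulate import FretSimConfig, simulate_bursts, simulate_photon_stream


def make_stream(times_ns, colors=None, excitation=None):
    t = np.asarray(times_ns, np.int64)
    ch = np.zeros(t.size, np.uint8) if colors is None else np.asarray(colors, np.uint8)
    ex = np.zeros(t.size, np.uint8) if excitation is None else np.asarray(excitation, np.uint8)
    return PhotonStream(t, ch, ex)


# ---------------------------------------------------------------------------
# burst search
# ---------------------------------------------------------------------------

def brute_force_burst_photons(times_ns, window, cutoff_ns):
    """Independent reference segmentation: explicit loops, no vectorization."""
    n = len(times_ns)
    intervals = [times_ns[i] - times_ns[i - 1] for i in range(1, n)]
    smoothed = []
    half = window // 2
    for i in range(len(intervals)):
        lo = max(0, i - half)
        hi = min(len(intervals), i - half + window)
        vals = intervals[lo:hi]
        smoothed.append(sum(vals) / len(vals))
    in_burst = [False] * n
    for i in range(1, n):
        in_burst[i] = smoothed[i - 1] < cutoff_ns
    in_burst[0] = in_burst[1] if n > 1 else False
    # in_burst[0] mirrors the first interval decision
    in_burst[0] = (smoothed[0] < cutoff_ns) if intervals else False
    runs = []
    start = None
    for i, flag in enumerate(in_burst + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    return runs


def test_empty_and_tiny_streams_give_no_bursts():
    assert burst_search(make_stream([])) == []
    assert burst_search(make_stream(np.arange(10) * 1000)) == []


def test_constructed_two_cluster_stream_yields_single_burst():
    """60 photons at 1 us spacing pass the 50-photon cut; the 49-photon cluster
    after a 1 ms gap does not."""
    first = np.arange(60) * 1000
    second = first[-1] + 1_000_000 + np.arange(49) * 1000
    bursts = burst_search(make_stream(np.concatenate([first, second])))
    assert len(bursts) == 1
    assert len(bursts[0]) >= 50


def test_sparse_background_produces_no_bursts():
    rng = np.random.default_rng(3)
    # 1 kHz Poisson background: mean interval 1 ms >> 5 us cut-off
    times = np.cumsum(rng.exponential(1e6, 10_000)).astype(np.int64)
    assert burst_search(make_stream(times)) == []


@pytest.mark.parametrize("seed", range(4))
def test_burst_search_matches_brute_force_oracle(seed):
    """Vectorized segmentation equals an explicit-loop reference on mixed
    burst/background streams."""
    rng = np.random.default_rng(100 + seed)
    segments = []
    t = 0.0
    for _ in range(30):
        t += rng.exponential(3e6)
        n = rng.integers(10, 120)
        seg = t + np.cumsum(rng.exponential(2000.0, n))
        segments.append(seg)
        t = seg[-1]
    times = np.sort(np.concatenate(segments)).astype(np.int64)
    cfg = BurstSearchConfig(smoothing_window=15, cutoff_us=5.0, min_size=50)
    got = burst_search(make_stream(times), cfg)
    expected = [
        (a, b) for a, b in brute_force_burst_photons(list(times), 15, 5000.0)
        if b - a >= 50
    ]
    assert len(got) == len(expected)
    for burst, (a, b) in zip(got, expected):
        np.testing.assert_array_equal(burst.timestamps_ns, times[a:b])


def test_burst_search_is_chunking_invariant():
    cfg = FretSimConfig(n_bursts=50, seed=9, background_rate_donor=500.0,
                        background_rate_acceptor=300.0)
    stream, _ = simulate_photon_stream(cfg)
    whole = burst_search(stream)
    k = len(stream) // 3
    rejoined = PhotonStream.concatenate([
        PhotonStream(stream.timestamps_ns[:k], stream.channel[:k], stream.excitation[:k]),
        PhotonStream(stream.timestamps_ns[k:2 * k], stream.channel[k:2 * k], stream.excitation[k:2 * k]),
        PhotonStream(stream.timestamps_ns[2 * k:], stream.channel[2 * k:], stream.excitation[2 * k:]),
    ])
    again = burst_search(rejoined)
    assert len(whole) == len(again)
    for a, b in zip(whole, again):
        np.testing.assert_array_equal(a.timestamps_ns, b.timestamps_ns)


# ---------------------------------------------------------------------------
# corrections, selection, histogram
# ---------------------------------------------------------------------------

def _mixed_population_bursts(leakage=0.05, direct=0.06, seed=5, n=600):
    cfg = FretSimConfig(
        n_bursts=n, seed=seed, leakage=leakage, direct_excitation=direct,
        donor_only_fraction=0.25, acceptor_only_fraction=0.25,
        photon_rate=5e5, acceptor_exc_rate=5e5,  # bright bursts, well above cut-off
        E_open=0.4, E_closed=0.41, k_open=5e5, k_close=5e5,  # effectively static E~0.4
    )
    stream, _ = simulate_photon_stream(cfg)
    return burst_search(stream)


def test_leakage_and_direct_excitation_recovery():
    bursts = _mixed_population_bursts()
    factors = estimate_corrections(bursts)
    assert factors.leakage == pytest.approx(0.05, abs=0.005)
    assert factors.direct_excitation == pytest.approx(0.06, abs=0.01)


def test_zero_distortion_estimates_are_near_zero():
    bursts = _mixed_population_bursts(leakage=0.0, direct=0.0, seed=6)
    factors = estimate_corrections(bursts)
    assert factors.leakage == pytest.approx(0.0, abs=0.01)
    assert factors.direct_excitation == pytest.approx(0.0, abs=0.01)


def test_corrected_E_recovers_generating_value():
    """Leakage/direct-excitation distortions invert: corrected mean E of the
    double-labeled population equals the configured efficiency within 0.01."""
    bursts = _mixed_population_bursts()
    factors = estimate_corrections(bursts)
    apply_corrections(bursts, factors)
    selected = select_double_labeled(bursts)
    assert len(selected) > 50
    mean_E = np.mean([b.corrected_E for b in selected])
    assert mean_E == pytest.approx(0.405, abs=0.01)


def test_stoichiometry_selection_behaviour():
    bursts = _mixed_population_bursts()
    factors = estimate_corrections(bursts)
    apply_corrections(bursts, factors)
    da = select_double_labeled(bursts)
    # mixture is 50/25/25 DA/DO/AO: roughly half the bursts survive
    assert 0.35 < len(da) / len(bursts) < 0.65
    assert len(select_double_labeled(bursts, s_window=(0.0, 1.0))) == len(bursts)
    # donor-only-like selection from pure high-S bursts is empty
    high_s = [b for b in bursts if b.corrected_S > 0.85]
    assert select_double_labeled(high_s) == []


def test_fret_histogram_normalization_and_apo_shape():
    cfg = FretSimConfig(n_bursts=800, seed=12,
                        k_open=5000 / 1.16, k_close=5000 * 0.16 / 1.16)  # K_C = 0.16
    bursts, _ = simulate_bursts(cfg)
    hist = fret_histogram(bursts, bins=25)
    widths = hist["E_right"] - hist["E_left"]
    assert float((hist["density"] * widths).sum()) == pytest.approx(1.0, rel=1e-9)
    # apo-like: mode near the open-state E ~ 0.4, with a high-E tail
    peak_center = hist.loc[hist["density"].idxmax(), ["E_left", "E_right"]].mean()
    assert 0.3 < peak_center < 0.5
    tail = float((hist["density"] * widths)[hist["E_left"] >= 0.6].sum())
    assert 0.01 < tail < 0.4


def test_single_burst_histogram_is_a_delta():
    colors = np.array([0, 0, 0, 1, 1], np.uint8)  # E = 0.4
    burst = PhotonBurst(np.arange(5, dtype=np.int64) * 1000, colors, np.zeros(5, np.uint8))
    hist = fret_histogram([burst], bins=10)
    nonzero = hist[hist["density"] > 0]
    assert len(nonzero) == 1
    assert nonzero["E_left"].iloc[0] <= 0.4 <= nonzero["E_right"].iloc[0]


# ---------------------------------------------------------------------------
# HMM likelihood against brute-force path enumeration
# ---------------------------------------------------------------------------

def brute_force_loglik(times_s, colors, model: HMMModel) -> float:
    """Exhaustive sum over all 2^N hidden state paths using scipy's expm."""
    K = np.array([[-model.k_close, model.k_close],
                  [model.k_open, -model.k_open]])  # row-generator, state 0=open
    pi = np.array([model.start_p_open, 1.0 - model.start_p_open])
    emis = np.array([[1.0 - model.E_open, model.E_open],
                     [1.0 - model.E_closed, model.E_closed]])
    n = len(times_s)
    total = 0.0
    for path in itertools.product((0, 1), repeat=n):
        prob = pi[path[0]] * emis[path[0], colors[0]]
        for i in range(1, n):
            P = expm(K * (times_s[i] - times_s[i - 1]))
            prob *= P[path[i - 1], path[i]] * emis[path[i], colors[i]]
        total += prob
    return float(np.log(total))


@pytest.mark.parametrize("case", range(25))
def test_forward_likelihood_equals_path_enumeration(case):
    rng = np.random.default_rng(2000 + case)
    n = int(rng.integers(2, 11))
    times_ns = np.sort(rng.integers(0, 2_000_000, n)).astype(np.int64)
    times_ns = np.unique(times_ns)
    n = times_ns.size
    if n < 2:
        times_ns = np.array([0, 1000], np.int64)
        n = 2
    colors = rng.integers(0, 2, n).astype(np.uint8)
    model = HMMModel(
        E_open=float(rng.uniform(0.05, 0.45)),
        E_closed=float(rng.uniform(0.55, 0.95)),
        k_open=float(10 ** rng.uniform(2, 4.5)),
        k_close=float(10 ** rng.uniform(2, 4.5)),
    )
    burst = PhotonBurst(times_ns, colors, np.zeros(n, np.uint8))
    ll = hmm_likelihood(model, burst)
    ll_brute = brute_force_loglik(times_ns * 1e-9, colors, model)
    assert ll == pytest.approx(ll_brute, rel=1e-6, abs=1e-9)


def test_likelihood_with_frozen_states_is_binomial_mixture():
    """Near-zero switching rates decouple the states: the likelihood reduces to
    the stationary-weighted mixture of two per-state binomial path likelihoods."""
    # k ~ 0.01 s^-1 over a ~20 us burst: exp(-lam*dt) = 1 to ~4e-7
    model = HMMModel(E_open=0.3, E_closed=0.8, k_open=0.01, k_close=0.01)
    times = np.arange(20, dtype=np.int64) * 1000
    colors = (np.arange(20) % 3 == 0).astype(np.uint8)
    n_acc = int(colors.sum())
    n_don = colors.size - n_acc
    mix = 0.5 * (0.3 ** n_acc * 0.7 ** n_don) + 0.5 * (0.8 ** n_acc * 0.2 ** n_don)
    assert hmm_likelihood(model, PhotonBurst(times, colors, np.zeros(20, np.uint8))) == \
        pytest.approx(np.log(mix), rel=1e-6)


def test_likelihood_invariant_under_time_shift():
    model = HMMModel(E_open=0.37, E_closed=0.72, k_open=2000.0, k_close=3000.0)
    rng = np.random.default_rng(8)
    times = np.sort(rng.integers(0, 1_000_000, 200)).astype(np.int64)
    colors = rng.integers(0, 2, 200).astype(np.uint8)
    b1 = PhotonBurst(times, colors, np.zeros(200, np.uint8))
    b2 = PhotonBurst(times + 10_000_000_000, colors, np.zeros(200, np.uint8))
    assert hmm_likelihood(model, b1) == pytest.approx(hmm_likelihood(model, b2), rel=1e-12)


# ---------------------------------------------------------------------------
# HMM fitting
# ---------------------------------------------------------------------------

def test_kc_recovery_moderate_sample():
    kc_true = 1.65
    lam = 5000.0
    cfg = FretSimConfig(k_open=lam / (1 + kc_true), k_close=lam * kc_true / (1 + kc_true),
                        n_bursts=500, seed=21)
    bursts, _ = simulate_bursts(cfg)
    res = hmm_fit(bursts, fix_E=(0.37, 0.72), n_restarts=2, seed=21)
    assert kc_from_model(res.models[0]) == pytest.approx(kc_true, rel=0.15)
    assert not res.models[0].degenerate


def test_single_state_data_flagged_degenerate():
    rng = np.random.default_rng(30)
    bursts = []
    for _ in range(200):
        n = rng.poisson(150) + 10
        times = np.sort(rng.integers(0, 1_000_000, n)).astype(np.int64)
        colors = (rng.random(n) < 0.5).astype(np.uint8)
        bursts.append(PhotonBurst(times, colors, np.zeros(n, np.uint8)))
    res = hmm_fit(bursts, n_restarts=2, seed=30)
    assert res.models[0].degenerate


def test_rate_recovery_across_two_decades():
    """Relative K_C error stays modest as generating rates span two decades at
    a fixed photon rate."""
    errors = []
    for i, lam in enumerate((500.0, 5_000.0, 50_000.0)):
        kc_true = 1.0
        cfg = FretSimConfig(k_open=lam / 2, k_close=lam / 2, n_bursts=400, seed=40 + i)
        bursts, _ = simulate_bursts(cfg)
        res = hmm_fit(bursts, fix_E=(0.37, 0.72), n_restarts=2, seed=40 + i)
        errors.append(abs(kc_from_model(res.models[0]) - kc_true))
    assert np.median(errors) < 0.15


def test_kc_estimator_invariances():
    """K_C is unchanged by burst order and by time rescaling combined with
    inverse rate rescaling."""
    cfg = FretSimConfig(k_open=2000.0, k_close=3000.0, n_bursts=300, seed=50)
    bursts, _ = simulate_bursts(cfg)
    res = hmm_fit(bursts, fix_E=(0.37, 0.72), n_restarts=1, seed=50)
    kc1 = kc_from_model(res.models[0])

    rng = np.random.default_rng(1)
    shuffled = [bursts[i] for i in rng.permutation(len(bursts))]
    res2 = hmm_fit(shuffled, fix_E=(0.37, 0.72), n_restarts=1, seed=50)
    # the likelihood is a sum over bursts; the optimum differs only by
    # optimizer termination slack under reordered float accumulation
    assert kc_from_model(res2.models[0]) == pytest.approx(kc1, rel=1e-3)

    stretched = [PhotonBurst(b.timestamps_ns * 10, b.channel, b.excitation) for b in bursts]
    res3 = hmm_fit(stretched, fix_E=(0.37, 0.72), n_restarts=1, seed=50)
    # times x10 -> rates /10 -> identical ratio
    assert kc_from_model(res3.models[0]) == pytest.approx(kc1, rel=1e-3)
    assert res3.models[0].k_open == pytest.approx(res.models[0].k_open / 10, rel=1e-2)


# ---------------------------------------------------------------------------
# Viterbi, dwells, recoloring, BVA
# ---------------------------------------------------------------------------

MODEL = HMMModel(E_open=0.37, E_closed=0.72, k_open=100.0, k_close=100.0)


def test_viterbi_static_high_E_burst_is_single_closed_dwell():
    rng = np.random.default_rng(60)
    n = 300
    times = np.sort(rng.integers(0, 1_500_000, n)).astype(np.int64)
    colors = (rng.random(n) < 0.72).astype(np.uint8)
    record = viterbi(MODEL, PhotonBurst(times, colors, np.zeros(n, np.uint8)))
    assert record.dwell_states.size == 1
    assert record.dwell_states[0] == 1


def test_viterbi_locates_constructed_changepoint():
    rng = np.random.default_rng(61)
    n_half = 5000
    t1 = np.sort(rng.integers(0, 25_000_000, n_half)).astype(np.int64)
    t2 = np.sort(rng.integers(25_000_000, 50_000_000, n_half)).astype(np.int64)
    colors = np.concatenate([
        (rng.random(n_half) < 0.37), (rng.random(n_half) < 0.72)
    ]).astype(np.uint8)
    times = np.concatenate([t1, t2])
    model = HMMModel(E_open=0.37, E_closed=0.72, k_open=20.0, k_close=20.0)
    record = viterbi(model, PhotonBurst(times, colors, np.zeros(2 * n_half, np.uint8)))
    changes = np.flatnonzero(np.diff(record.states))
    assert changes.size == 1
    assert abs(int(changes[0]) + 1 - n_half) <= 20


def test_viterbi_dwell_statistics_match_generating_rates():
    """Mean dwell durations approximate the inverse switching rates, and the
    closed-state time fraction converges to the equilibrium population."""
    kc_true = 1.5
    lam = 2000.0
    cfg = FretSimConfig(E_open=0.25, E_closed=0.75,
                        k_open=lam / (1 + kc_true), k_close=lam * kc_true / (1 + kc_true),
                        n_bursts=6000, seed=62, mean_burst_duration=2e-3)
    bursts, _ = simulate_bursts(cfg)
    model = HMMModel(E_open=0.25, E_closed=0.75, k_open=cfg.k_open, k_close=cfg.k_close)
    open_us, closed_us = [], []
    for b in bursts:
        rec = viterbi(model, b)
        open_us.extend(rec.dwell_durations_us[rec.dwell_states == 0])
        closed_us.extend(rec.dwell_durations_us[rec.dwell_states == 1])
    t_open, t_closed = np.sum(open_us), np.sum(closed_us)
    assert t_closed / t_open == pytest.approx(kc_true, rel=0.05)
    # dwell means: censored by burst edges, compare within 35%
    assert np.mean(closed_us) == pytest.approx(1e6 / cfg.k_open, rel=0.35)
    assert np.mean(open_us) == pytest.approx(1e6 / cfg.k_close, rel=0.35)


def test_recoloring_passes_for_true_model_and_fails_for_misspecification():
    cfg = FretSimConfig(k_open=2000.0, k_close=3000.0, n_bursts=300, seed=70)
    bursts, _ = simulate_bursts(cfg)
    fit = hmm_fit(bursts, fix_E=(0.37, 0.72), n_restarts=1, seed=70)
    ok = recoloring_test(fit.models[0], bursts, n_draws=100, seed=70)
    assert ok.passed

    # three well-separated static populations cannot be recolored by 2 states
    rng = np.random.default_rng(71)
    tri = []
    for i in range(300):
        E = (0.05, 0.5, 0.95)[i % 3]
        n = rng.poisson(200) + 20
        times = np.sort(rng.integers(0, 1_000_000, n)).astype(np.int64)
        colors = (rng.random(n) < E).astype(np.uint8)
        tri.append(PhotonBurst(times, colors, np.zeros(n, np.uint8)))
    fit3 = hmm_fit(tri, n_restarts=2, seed=71)
    bad = recoloring_test(fit3.models[0], tri, n_draws=100, seed=71)
    assert not bad.passed


def test_recoloring_rejects_degenerate_draw_count():
    with pytest.raises(ValueError):
        recoloring_test(MODEL, [], n_draws=0)


def test_bva_static_within_and_dynamic_above_shot_noise():
    static = FretSimConfig(E_open=0.49, E_closed=0.5, k_open=1e6, k_close=1e6,
                           n_bursts=300, seed=80)
    bursts_static, _ = simulate_bursts(static)
    table_s, _ = burst_variance_analysis(bursts_static, window=8)
    # averaged over bursts, the observed variance matches binomial shot noise
    # (RMS comparison: the per-burst sample SD is biased low at few windows)
    rms_obs = np.sqrt((table_s["observed_sd"] ** 2).mean())
    rms_shot = np.sqrt((table_s["shot_noise_sd"] ** 2).mean())
    assert rms_obs == pytest.approx(rms_shot, rel=0.05)

    dynamic = FretSimConfig(E_open=0.1, E_closed=0.9, k_open=700.0, k_close=700.0,
                            n_bursts=300, seed=81)
    bursts_dyn, _ = simulate_bursts(dynamic)
    table_d, _ = burst_variance_analysis(bursts_dyn, window=8)
    assert table_d["observed_sd"].mean() > 1.3 * table_d["shot_noise_sd"].mean()


def test_bva_skips_short_bursts():
    short = PhotonBurst(np.arange(5, dtype=np.int64), np.zeros(5, np.uint8), np.zeros(5, np.uint8))
    table, skipped = burst_variance_analysis([short], window=10)
    assert skipped == 1
    assert table.empty
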