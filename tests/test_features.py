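"""Feature extraction against brute-force oracles and stated conventions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import groomacc as g
from groomacc.features import (
    amplitude_spectrum,
    centred_moving_average,
    dynamic_component,
    pdba,
    pitch_roll,
    psd_peaks,
    static_component,
    summarise_ethogram,
    vedba,
    vedba_smoothed,
)
from groomacc.types import AccelTrace


# ---------------------------------------------------------------------------
# oracles


def brute_force_moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """O(n*w) centred windowed mean; NaN where the window is incomplete."""
    n = len(x)
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = i - w // 2, i - w // 2 + w
        if lo >= 0 and hi <= n:
            out[i] = np.mean(x[lo:hi])
    return out


def brute_force_dft(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DFT by direct summation; one-sided amplitudes for bins 1..n//2."""
    x = x - np.mean(x)
    n = len(x)
    freqs, amps = [], []
    for k in range(1, n // 2 + 1):
        re = sum(x[t] * np.cos(2 * np.pi * k * t / n) for t in range(n))
        im = sum(-x[t] * np.sin(2 * np.pi * k * t / n) for t in range(n))
        scale = 1.0 if (n % 2 == 0 and k == n // 2) else 2.0
        amps.append(scale * np.hypot(re, im) / n)
        freqs.append(k)
    return np.array(freqs, float), np.array(amps)


def brute_force_two_peaks(amp: np.ndarray) -> tuple[float, float]:
    """Largest magnitude and second-largest local maximum by scanning."""
    psd1 = float(amp.max())
    i1 = int(amp.argmax())
    best2 = 0.0
    for i, a in enumerate(amp):
        if i == i1 or a <= 0:
            continue
        left_ok = i == 0 or amp[i - 1] <= a
        right_ok = i == len(amp) - 1 or amp[i + 1] <= a
        if left_ok and right_ok:
            best2 = max(best2, float(a))
    return psd1, best2


# ---------------------------------------------------------------------------
# moving averages


def test_moving_average_matches_oracle_on_random_cases():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(1, 200))
        w = int(rng.integers(1, 140))
        x = rng.normal(size=n)
        if rng.random() < 0.3 and n > 2:  # inject NaNs sometimes
            x[rng.integers(0, n, size=2)] = np.nan
        got = centred_moving_average(x, w)
        want = brute_force_moving_average(x, w)
        np.testing.assert_array_equal(got, want)


def test_static_of_constant_trace_is_constant():
    trace = AccelTrace("A", "2018-08-01", 40, np.tile([0.0, 0.0, 1.0], (400, 1)))
    st = static_component(trace)
    interior = st[40:-40]
    np.testing.assert_allclose(interior, np.tile([0.0, 0.0, 1.0], (len(interior), 1)))


def test_static_of_whole_period_sinusoid_is_near_zero():
    t = np.arange(400) / 40.0
    x = np.column_stack([np.sin(2 * np.pi * 5 * t), np.zeros(400), np.zeros(400)])
    st = static_component(AccelTrace("A", "2018-08-01", 40, x), window_s=2.0)
    interior = st[40:-40, 0]
    assert np.nanmax(np.abs(interior)) < 1e-6


def test_dynamic_component_rules():
    trace = AccelTrace("A", "2018-08-01", 40, np.tile([0.1, 0.2, 0.9], (200, 1)))
    st = static_component(trace)
    dyn = dynamic_component(trace, st)
    defined = ~np.isnan(st).any(axis=1)
    np.testing.assert_allclose(dyn[defined], 0.0, atol=1e-15)
    assert np.isnan(dyn[~defined]).all()  # undefined exactly where static is
    with pytest.raises(ValueError):
        dynamic_component(trace, st[:-1])


def test_vedba_examples_and_symmetry():
    assert vedba(np.array([[0.3, 0.0, 0.4]]))[0] == pytest.approx(0.5)
    assert vedba(np.array([[0.0, 0.0, 0.0]]))[0] == 0.0
    rng = np.random.default_rng(1)
    d = rng.normal(size=(50, 3))
    np.testing.assert_allclose(vedba(d), vedba(d[:, [2, 0, 1]]))


def test_vedba_smoothed_examples():
    assert np.nanmax(vedba_smoothed(np.full(400, 0.7))) == pytest.approx(0.7)
    impulse = np.zeros(400)
    impulse[200] = 1.0
    assert np.nanmax(vedba_smoothed(impulse)) == pytest.approx(1.0 / 120.0)
    rng = np.random.default_rng(2)
    x = rng.normal(size=300)
    np.testing.assert_array_equal(vedba_smoothed(x),
                                  brute_force_moving_average(x, 120))


def test_pitch_roll_conventions():
    pitch, roll = pitch_roll(np.array([[0.0, 0.0, 1.0],
                                       [1.0, 0.0, 0.0],
                                       [0.0, 1.0, 0.0],
                                       [0.0, 0.0, 0.0]]))
    assert pitch[0] == pytest.approx(0.0) and roll[0] == pytest.approx(0.0)
    assert pitch[1] == pytest.approx(90.0)
    assert roll[2] == pytest.approx(90.0)
    assert np.isnan(pitch[3]) and np.isnan(roll[3])


def test_pdba_examples_and_identity():
    np.testing.assert_allclose(pdba(np.array([[-0.2, 0.1, 0.0]])),
                               [[0.2, 0.1, 0.0]])
    rng = np.random.default_rng(3)
    d = rng.normal(size=(80, 3))
    np.testing.assert_allclose((pdba(d) ** 2).sum(axis=1), vedba(d) ** 2)


# ---------------------------------------------------------------------------
# spectral peaks


def test_bin_aligned_sinusoid_peak_normalisation():
    t = np.arange(40) / 40.0
    psd1, f1, psd2, _ = psd_peaks(0.2 * np.sin(2 * np.pi * 5 * t))
    assert psd1 == pytest.approx(0.2, abs=1e-6)
    assert f1 == 5.0
    assert psd2 == pytest.approx(0.0, abs=1e-9)


def test_zero_signal_has_zero_peaks():
    psd1, _, psd2, _ = psd_peaks(np.zeros(40))
    assert psd1 == 0.0 and psd2 == 0.0


def test_spectrum_matches_dft_by_summation_oracle():
    rng = np.random.default_rng(4)
    for _ in range(100):
        x = rng.normal(size=40)
        freqs, amp = amplitude_spectrum(x)
        ofreqs, oamp = brute_force_dft(x)
        np.testing.assert_array_equal(freqs, ofreqs)
        np.testing.assert_allclose(amp, oamp, atol=1e-9)
        psd1, _, psd2, _ = psd_peaks(x)
        o1, o2 = brute_force_two_peaks(oamp)
        assert psd1 == pytest.approx(o1, abs=1e-9)
        assert psd2 == pytest.approx(o2, abs=1e-9)


# ---------------------------------------------------------------------------
# epoch features


def test_epoch_features_has_16_feature_columns():
    assert len(g.FEATURE_COLUMNS) == 16
    trace = AccelTrace("A", "2018-08-01", 40, np.tile([0.0, 0.0, 1.0], (400, 1)))
    feats = g.epoch_features(trace)
    assert [c for c in feats.columns if c in g.FEATURE_COLUMNS] == list(g.FEATURE_COLUMNS)


def test_constant_upright_trace_features():
    trace = AccelTrace("A", "2018-08-01", 40, np.tile([0.0, 0.0, 1.0], (400, 1)))
    feats = g.epoch_features(trace)
    valid = feats.loc[feats["valid"]]
    assert len(valid) > 0
    assert (~feats["valid"]).any()  # smoothing edges are invalid
    np.testing.assert_allclose(valid["stZ"], 1.0)
    for col in ("VeDBA", "VeDBAs", "PDBAx", "PDBAy", "PDBAz",
                "PSD1X", "PSD2X", "pitch", "roll"):
        np.testing.assert_allclose(valid[col], 0.0, atol=1e-12)


def test_missing_span_invalidates_touching_epochs():
    # Sample i depends on raw samples [i-100, i+100): +-40 from the 2 s static
    # window and a further +-60 from the 3 s VeDBAs window on VeDBA.  With one
    # missing second at samples [400, 440) in a 20 s trace, the defined sample
    # range is [100, 300] U [540, 700], so the fully-defined epochs are
    # exactly 3..6 and 14..16.
    samples = np.tile([0.0, 0.0, 1.0], (800, 1))
    samples[400:440] = np.nan
    feats = g.epoch_features(AccelTrace("A", "2018-08-01", 40, samples))
    expect = np.zeros(20, dtype=bool)
    expect[[3, 4, 5, 6, 14, 15, 16]] = True
    np.testing.assert_array_equal(feats["valid"].to_numpy(), expect)


def test_giving_rhythm_raises_psd2x_over_resting():
    configs = g.default_behaviour_configs()
    frames = {}
    for beh in ("giving_grooming", "resting", "receiving_grooming"):
        lab = g.LabelSeries("A", "2018-08-01", np.array([beh] * 600, dtype=object))
        trace = g.synthesize_acceleration(lab, configs, 77)
        f = g.epoch_features(trace)
        frames[beh] = f.loc[f["valid"], "PSD2X"].to_numpy()
    n = min(len(v) for v in frames.values())
    give = frames["giving_grooming"][:n]
    assert (give > frames["resting"][:n]).mean() >= 0.95
    assert (give > frames["receiving_grooming"][:n]).mean() >= 0.95


def test_raw_equals_static_plus_dynamic():
    rng = np.random.default_rng(5)
    trace = AccelTrace("A", "2018-08-01", 40, rng.normal(size=(400, 3)))
    st = static_component(trace)
    dyn = dynamic_component(trace, st)
    defined = ~np.isnan(st).any(axis=1)
    # (raw - st) + st is not bitwise raw in floating point; allow rounding
    np.testing.assert_allclose((st + dyn)[defined], trace.samples[defined],
                               atol=1e-12)


def test_scale_equivariance():
    rng = np.random.default_rng(6)
    samples = np.tile([0.0, 0.0, 1.0], (800, 1)) + 0.05 * rng.normal(size=(800, 3))
    k = 3.0
    f1 = g.epoch_features(AccelTrace("A", "2018-08-01", 40, samples))
    f2 = g.epoch_features(AccelTrace("A", "2018-08-01", 40, k * samples))
    v1, v2 = f1.loc[f1["valid"]], f2.loc[f2["valid"]]
    for col in ("VeDBA", "VeDBAs", "PDBAx", "PDBAy", "PDBAz",
                "PSD1X", "PSD2X", "PSD1Y", "PSD2Y", "PSD1Z", "PSD2Z"):
        np.testing.assert_allclose(v2[col], k * v1[col], atol=1e-12)
    np.testing.assert_allclose(v2["pitch"], v1["pitch"], atol=1e-9)
    np.testing.assert_allclose(v2["roll"], v1["roll"], atol=1e-9)


def test_feature_invariants_on_synthetic_data(small_labelled):
    valid = small_labelled.loc[small_labelled["valid"]]
    for col in ("VeDBA", "VeDBAs", "PDBAx", "PDBAy", "PDBAz",
                "PSD1X", "PSD2X", "PSD1Y", "PSD2Y", "PSD1Z", "PSD2Z"):
        assert (valid[col] >= 0).all()
    for ax in "XYZ":
        assert (valid[f"PSD1{ax}"] >= valid[f"PSD2{ax}"]).all()
    assert valid["pitch"].between(-90, 90).all()
    assert valid["roll"].between(-180, 180).all()


# ---------------------------------------------------------------------------
# label alignment and ethogram summaries


def test_label_align_identical_and_offset_spans():
    trace = AccelTrace("A", "2018-08-01", 40, np.tile([0.0, 0.0, 1.0], (400, 1)))
    feats = g.epoch_features(trace)
    labels = g.LabelSeries("A", "2018-08-01", np.array(["resting"] * 10, dtype=object))
    assert len(g.label_align(feats, labels)) == 10
    offset = g.LabelSeries("A", "2018-08-01 00:00:01",
                           np.array(["resting"] * 10, dtype=object))
    assert len(g.label_align(feats, offset)) == 9
    far = g.LabelSeries("A", "2018-09-01", np.array(["resting"] * 10, dtype=object))
    with pytest.raises(ValueError):
        g.label_align(feats, far)


def test_label_align_matches_dictionary_oracle(small_labelled):
    configs = g.default_behaviour_configs()
    labels = g.generate_behaviour_sequence(configs, 120, 17)
    trace = g.synthesize_acceleration(labels, configs, 18)
    feats = g.epoch_features(trace)
    joined = g.label_align(feats, labels)
    lookup = dict(zip(labels.times(), labels.labels))
    for _, row in joined.iterrows():
        assert row["label"] == lookup.get(pd.Timestamp(row["epoch_time"]), "")


def test_summarise_ethogram_single_epoch_and_quantile_oracle(small_labelled):
    one = small_labelled.loc[small_labelled["valid"]].iloc[[0]]
    summ = summarise_ethogram(one)
    row = summ.loc[summ["feature"] == "VeDBAs"].iloc[0]
    assert row["q1"] == row["median"] == row["q3"]

    summ = summarise_ethogram(small_labelled)
    valid = small_labelled.loc[small_labelled["valid"]]
    for _, row in summ.head(40).iterrows():
        vals = np.sort(valid.loc[valid["label"] == row["behaviour"],
                                 row["feature"]].to_numpy())
        # type-7 (linear interpolation) quantile oracle by sort-and-index
        def q(p):
            h = (len(vals) - 1) * p
            lo = int(np.floor(h))
            return vals[lo] + (h - lo) * (vals[min(lo + 1, len(vals) - 1)] - vals[lo])
        assert row["q1"] == pytest.approx(q(0.25))
        assert row["median"] == pytest.approx(q(0.5))
        assert row["q3"] == pytest.approx(q(0.75))


def test_calibrated_vedbas_ordering(small_labelled):
    summ = summarise_ethogram(small_labelled)
    med = summ.loc[summ["feature"] == "VeDBAs"].set_index("behaviour")["median"]
    order = ["running", "walking", "foraging", "resting", "receiving_grooming"]
    present = [b for b in order if b in med.index]
    vals = [med[b] for b in present]
    assert vals == sorted(vals, reverse=True)
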