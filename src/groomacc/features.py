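"""The 16 per-second acceleration variables.

From a raw 40 Hz tri-axial trace the pipeline derives, per sample:

* static acceleration per axis (centred moving average, default 2 s window) --
  the gravity-dominated posture component;
* dynamic acceleration = raw - static -- the movement component;
* pitch and roll from the static vector;
* VeDBA (vectorial dynamic body acceleration, the Euclidean norm of the
  dynamic triple) and VeDBAs (its 3 s centred moving average);
* PDBA per axis (absolute dynamic acceleration).

Per whole-second epoch the per-sample variables are averaged, and the two
largest spectral peaks of the mean-detrended dynamic signal are extracted per
axis (PSD1/PSD2, amplitudes in g at 1 Hz resolution).  Samples whose smoothing
window overlaps a trace boundary or a missing span are undefined (NaN); an
epoch touching any undefined value is marked invalid and flows through
prediction as unclassified.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .types import BEHAVIOURS, FEATURE_COLUMNS, AccelTrace, LabelSeries

logger = logging.getLogger(__name__)


def centred_moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving average; NaN where the window is incomplete.

    The window at index i covers samples [i - w//2, i + w - w//2); NaN inputs
    propagate to every window containing them.
    """
    x = np.asarray(x, dtype=float)
    w = int(window_samples)
    if w < 1:
        raise ValueError("window must span at least one sample")
    out = np.full(x.shape[0], np.nan)
    if x.shape[0] < w:
        logger.warning("window (%d samples) longer than signal (%d)", w, x.shape[0])
        return out
    means = sliding_window_view(x, w).mean(axis=-1)
    out[w // 2: w // 2 + means.shape[0]] = means
    return out


def static_component(trace: AccelTrace, window_s: float = 2.0) -> np.ndarray:
    """Per-sample static (gravity/posture) triples, shape (n, 3)."""
    w = int(round(window_s * trace.rate_hz))
    return np.column_stack(
        [centred_moving_average(trace.samples[:, a], w) for a in range(3)])


def dynamic_component(trace: AccelTrace, static: np.ndarray) -> np.ndarray:
    """Per-sample dynamic triples: raw minus static."""
    if static.shape != trace.samples.shape:
        raise ValueError("static and raw traces differ in length")
    return trace.samples - static


def vedba(dynamic: np.ndarray) -> np.ndarray:
    """Vectorial dynamic body acceleration per sample (g)."""
    return np.sqrt((np.asarray(dynamic, dtype=float) ** 2).sum(axis=-1))


def vedba_smoothed(vedba_series: np.ndarray, window_s: float = 3.0,
                   rate_hz: int = 40) -> np.ndarray:
    """VeDBAs: centred moving average of VeDBA over ``window_s``."""
    return centred_moving_average(vedba_series, int(round(window_s * rate_hz)))


def pitch_roll(static: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orientation angles (degrees) from the static vector.

    pitch = atan2(stX, hypot(stY, stZ)): elevation of the surge axis, 0 when
    upright (gravity on +Z), +90 when the surge axis points straight up.
    roll = atan2(stY, stZ): rotation about the surge axis, 0 when upright.
    Zero-magnitude static samples are undefined.
    """
    st = np.asarray(static, dtype=float)
    norm = np.linalg.norm(st, axis=-1)
    pitch = np.degrees(np.arctan2(st[..., 0], np.hypot(st[..., 1], st[..., 2])))
    roll = np.degrees(np.arctan2(st[..., 1], st[..., 2]))
    zero = norm == 0
    pitch[zero] = np.nan
    roll[zero] = np.nan
    return pitch, roll


def pdba(dynamic: np.ndarray) -> np.ndarray:
    """Partial dynamic body acceleration: |dynamic| per axis, shape (n, 3)."""
    return np.abs(np.asarray(dynamic, dtype=float))


def amplitude_spectrum(epoch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of a mean-detrended epoch.

    Normalised so a bin-aligned sinusoid of amplitude a yields a peak of a.
    Returns (frequencies Hz, amplitudes g) for bins 1..N/2 (DC excluded).
    """
    x = np.asarray(epoch, dtype=float)
    n = x.shape[-1]
    spec = np.fft.rfft(x - x.mean(axis=-1, keepdims=True), axis=-1)
    amp = 2.0 * np.abs(spec) / n
    if n % 2 == 0:
        amp[..., -1] /= 2.0  # Nyquist bin is not mirrored
    # 1..N/2 cycles per epoch; equals Hz for a 1 s epoch
    freqs = np.arange(1, amp.shape[-1], dtype=float)
    return freqs, amp[..., 1:]


def _two_peaks(amp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Largest magnitude and second-largest local maximum, batched.

    ``amp`` has shape (..., k) over frequency bins.  A bin is a local maximum
    if it is positive and >= its neighbours (single neighbour at the ends).
    Returns (psd1, f1_idx, psd2, f2_idx); psd2 = 0 (f2_idx = -1) if no second
    local maximum exists.
    """
    amp = np.atleast_2d(amp)
    ge_left = np.concatenate(
        [np.ones(amp.shape[:-1] + (1,), bool), amp[..., 1:] >= amp[..., :-1]], axis=-1)
    ge_right = np.concatenate(
        [amp[..., :-1] >= amp[..., 1:], np.ones(amp.shape[:-1] + (1,), bool)], axis=-1)
    is_max = ge_left & ge_right & (amp > 0)
    i1 = amp.argmax(axis=-1)
    psd1 = np.take_along_axis(amp, i1[..., None], axis=-1)[..., 0]
    cand = np.where(is_max, amp, -np.inf)
    np.put_along_axis(cand, i1[..., None], -np.inf, axis=-1)
    i2 = cand.argmax(axis=-1)
    v2 = np.take_along_axis(cand, i2[..., None], axis=-1)[..., 0]
    psd2 = np.where(np.isfinite(v2), v2, 0.0)
    i2 = np.where(np.isfinite(v2), i2, -1)
    return psd1, i1, psd2, i2


def psd_peaks(dynamic_axis: np.ndarray) -> tuple[float, float, float, float]:
    """(PSD1, f1, PSD2, f2) for one fully defined epoch of one axis.

    PSD1 is the largest spectral magnitude, PSD2 the second-largest local
    maximum (0, with f2 = NaN, if none); frequencies in Hz.
    """
    x = np.asarray(dynamic_axis, dtype=float)
    if np.isnan(x).any():
        return (np.nan, np.nan, np.nan, np.nan)
    freqs, amp = amplitude_spectrum(x)
    psd1, i1, psd2, i2 = _two_peaks(amp)
    f2 = freqs[i2[0]] if i2[0] >= 0 else np.nan
    return float(psd1[0]), float(freqs[i1[0]]), float(psd2[0]), float(f2)


def epoch_features(
    trace: AccelTrace,
    static_window_s: float = 2.0,
    vedbas_window_s: float = 3.0,
    labels: LabelSeries | None = None,
) -> pd.DataFrame:
    """Reduce a trace to per-second epochs of the 16 acceleration variables.

    Per whole second: the mean over the 40 samples of each per-sample
    variable, plus the per-epoch spectral peaks of the dynamic signal.
    Returns a DataFrame with columns ``epoch_time``, the 16 features,
    ``valid`` and ``individual_id`` (plus ``label`` when ``labels`` given).
    """
    rate = trace.rate_hz
    n_epochs = trace.n_samples // rate
    cols = ["epoch_time", *FEATURE_COLUMNS, "valid", "individual_id"]
    if n_epochs == 0:
        return pd.DataFrame(columns=cols)
    n = n_epochs * rate

    st_full = static_component(trace, static_window_s)
    dyn_full = dynamic_component(trace, st_full)
    vd_full = vedba(dyn_full)
    st, dyn, vd = st_full[:n], dyn_full[:n], vd_full[:n]
    vds = vedba_smoothed(vd_full, vedbas_window_s, rate)[:n]
    pit, rol = pitch_roll(st)
    pd_abs = pdba(dyn)

    def em(x: np.ndarray) -> np.ndarray:
        return x[:n].reshape(n_epochs, rate).mean(axis=1)

    data: dict[str, np.ndarray] = {
        "stX": em(st[:, 0]), "stY": em(st[:, 1]), "stZ": em(st[:, 2]),
        "pitch": em(pit), "roll": em(rol),
        "VeDBA": em(vd), "VeDBAs": em(vds),
        "PDBAx": em(pd_abs[:, 0]), "PDBAy": em(pd_abs[:, 1]), "PDBAz": em(pd_abs[:, 2]),
    }
    for ax, name in enumerate("XYZ"):
        ep = dyn[:, ax].reshape(n_epochs, rate)
        bad = np.isnan(ep).any(axis=1)
        _, amp = amplitude_spectrum(np.where(np.isnan(ep), 0.0, ep))
        psd1, _, psd2, _ = _two_peaks(amp)
        psd1 = np.where(bad, np.nan, psd1)
        psd2 = np.where(bad, np.nan, psd2)
        data[f"PSD1{name}"] = psd1
        data[f"PSD2{name}"] = psd2

    df = pd.DataFrame({c: data[c] for c in FEATURE_COLUMNS})
    df.insert(0, "epoch_time", trace.start_time.floor("s")
              + pd.to_timedelta(np.arange(n_epochs), unit="s"))
    df["valid"] = df[list(FEATURE_COLUMNS)].notna().all(axis=1)
    df["individual_id"] = trace.individual_id
    if labels is not None:
        df = label_align(df, labels)
    return df


def label_align(features: pd.DataFrame, labels: LabelSeries) -> pd.DataFrame:
    """Attach per-second labels to a feature table over the overlapping span.

    Rows are restricted to the time range covered by both inputs; epochs with
    no label in that range keep an empty label.
    """
    f_times = pd.DatetimeIndex(features["epoch_time"])
    lo = max(f_times.min(), labels.start_time)
    hi = min(f_times.max() + pd.Timedelta(seconds=1),
             labels.start_time + pd.Timedelta(seconds=labels.duration_s))
    if lo >= hi:
        raise ValueError("feature table and label series do not overlap in time")
    out = features.loc[(f_times >= lo) & (f_times < hi)].copy()
    lmap = pd.Series(labels.labels, index=labels.times())
    out["label"] = lmap.reindex(pd.DatetimeIndex(out["epoch_time"])).fillna("").to_numpy()
    return out


def summarise_ethogram(labelled: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of every feature per behaviour (valid epochs).

    Quartiles use linear interpolation (type-7).  Behaviours without valid
    epochs are omitted with a warning.
    """
    rows = []
    present = set(labelled["label"].astype(str))
    for beh in BEHAVIOURS:
        sub = labelled.loc[(labelled["label"] == beh) & labelled["valid"]]
        if sub.empty:
            if beh in present:
                logger.warning("behaviour %s has no valid epochs; omitted", beh)
            continue
        for feat in FEATURE_COLUMNS:
            q1, med, q3 = np.quantile(sub[feat].to_numpy(), [0.25, 0.5, 0.75])
            rows.append({"behaviour": beh, "feature": feat,
                         "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows, columns=["behaviour", "feature", "q1", "median", "q3"])
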