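"""Activity budgets, bout statistics and day/night summaries.

A trained classifier applied to continuous collar data yields one predicted
behaviour per second (or "unclassified" where features are undefined).  This
module reduces such a stream to:

* per-individual activity budgets -- seconds and proportions per behaviour
  within clock-time windows (full day, the 07:00-17:00 direct-observation
  window, and its night complement); unclassified seconds are reported but
  excluded from the proportion denominator;
* independent-event counts -- maximal runs of one state behaviour, with brief
  interruptions by non-state labels (up to a configurable merge gap) absorbed
  into the surrounding event;
* day versus night feature summaries, including an interquartile-range
  overlap coefficient between behaviour pairs (length of the IQR intersection
  over the length of the IQR union; 1 for identical IQRs, 0 for disjoint).
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .types import BEHAVIOURS, UNCLASSIFIED, LabelSeries, label_runs
from .model import TrainedClassifier, predict

logger = logging.getLogger(__name__)

#: Default clock windows: full day, direct-observation hours, and night.
DEFAULT_WINDOWS: dict[str, tuple[str, str] | None] = {
    "24h": None,
    "day_07_17": ("07:00", "17:00"),
    "night": ("17:00", "07:00"),
}


def classify_continuous(clf: TrainedClassifier, features: pd.DataFrame) -> LabelSeries:
    """One prediction per epoch over a continuous feature stream.

    Invalid epochs come out as "unclassified"; output is contiguous from the
    first epoch.
    """
    times = pd.DatetimeIndex(features["epoch_time"])
    if len(times) > 1 and not (times[1:] - times[:-1] == pd.Timedelta(seconds=1)).all():
        raise ValueError("feature stream must be contiguous at 1 s spacing")
    labels = predict(clf, features)
    individual = str(features["individual_id"].iloc[0]) if "individual_id" in features \
        else "unknown"
    return LabelSeries(individual, times[0], labels)


def _clock_mask(times: pd.DatetimeIndex, window: tuple[str, str] | None) -> np.ndarray:
    """Boolean mask of timestamps within a clock window; wraps midnight."""
    if window is None:
        return np.ones(len(times), dtype=bool)
    start = dt.time.fromisoformat(window[0])
    end = dt.time.fromisoformat(window[1])
    tod = times.time
    if start <= end:
        return np.array([(start <= t) & (t < end) for t in tod])
    return np.array([(t >= start) | (t < end) for t in tod])


def budget(
    predicted: LabelSeries,
    windows: dict[str, tuple[str, str] | None] | None = None,
) -> pd.DataFrame:
    """Seconds and proportions per behaviour per clock window.

    Proportions are over the six state behaviours only; per (individual,
    window) they sum to 1.  Unclassified seconds appear as their own rows
    with NaN proportion.
    """
    if windows is None:
        windows = DEFAULT_WINDOWS
    times = predicted.times()
    labels = predicted.labels.astype(str)
    rows = []
    for name, win in windows.items():
        mask = _clock_mask(times, win)
        if not mask.any():
            logger.warning("window %s contains no epochs; omitted", name)
            continue
        sub = labels[mask]
        classified = int(np.isin(sub, BEHAVIOURS).sum())
        for beh in BEHAVIOURS:
            sec = int((sub == beh).sum())
            rows.append({"individual_id": predicted.individual_id, "window": name,
                         "behaviour": beh, "seconds": sec,
                         "proportion": sec / classified if classified else np.nan})
        rows.append({"individual_id": predicted.individual_id, "window": name,
                     "behaviour": UNCLASSIFIED,
                     "seconds": int(len(sub) - classified), "proportion": np.nan})
    return pd.DataFrame(rows)


def unclassified_share(n_unclassified: int, n_total: int) -> float:
    """Percentage of a dataset that could not be assigned a behaviour."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_unclassified / n_total


def count_events(
    labels: LabelSeries | np.ndarray,
    merge_gap_s: int = 0,
    states: tuple[str, ...] = BEHAVIOURS,
) -> pd.DataFrame:
    """Seconds, independent events and mean bout length per behaviour.

    An independent event is a maximal run of one state behaviour; an
    interruption by non-state labels of at most ``merge_gap_s`` seconds
    between two runs of the same behaviour is absorbed into a single event
    (a change to another state behaviour always ends the event).  Interruption
    seconds are not counted toward the behaviour's seconds.
    """
    if merge_gap_s < 0:
        raise ValueError("merge_gap_s must be non-negative")
    arr = labels.labels if isinstance(labels, LabelSeries) else np.asarray(labels, dtype=object)
    seconds = {b: 0 for b in states}
    events = {b: 0 for b in states}
    last_state: str | None = None
    gap = 0
    for start, stop, lab in label_runs(arr):
        length = stop - start
        if lab in states:
            if lab == last_state and gap <= merge_gap_s:
                pass  # continuation of the current event
            else:
                events[lab] += 1
            seconds[lab] += length
            last_state = lab
            gap = 0
        else:
            gap += length
    out = pd.DataFrame({"seconds": pd.Series(seconds), "events": pd.Series(events)})
    with np.errstate(invalid="ignore", divide="ignore"):
        out["mean_bout_s"] = np.where(out["events"] > 0,
                                      out["seconds"] / out["events"], np.nan)
    out.index.name = "behaviour"
    return out


def iqr_overlap(q1a: float, q3a: float, q1b: float, q3b: float) -> float:
    """Length of the IQR intersection over the length of the IQR union."""
    inter = max(0.0, min(q3a, q3b) - max(q1a, q1b))
    union = max(q3a, q3b) - min(q1a, q1b)
    if union == 0:
        return 1.0 if (q1a, q3a) == (q1b, q3b) else 0.0
    return inter / union


def day_night_summary(
    features: pd.DataFrame,
    label_col: str = "label",
    day_window: tuple[str, str] = ("07:00", "17:00"),
    feature: str = "VeDBAs",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median/quartiles of a feature per behaviour, split day versus night.

    Returns (summary, overlap): per-behaviour quartiles per window, and the
    IQR-overlap coefficient for every behaviour pair within each window.
    """
    times = pd.DatetimeIndex(features["epoch_time"])
    day = _clock_mask(times, day_window)
    valid = features["valid"].to_numpy(bool) if "valid" in features \
        else np.ones(len(features), bool)
    rows = []
    for win_name, mask in [("day", day & valid), ("night", ~day & valid)]:
        if not mask.any():
            logger.warning("window %s contains no valid epochs; omitted", win_name)
            continue
        sub = features.loc[mask]
        for beh in BEHAVIOURS:
            vals = sub.loc[sub[label_col] == beh, feature].to_numpy(float)
            if vals.size == 0:
                continue
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append({"behaviour": beh, "window": win_name,
                         "q1": q1, "median": med, "q3": q3, "n": vals.size})
    summary = pd.DataFrame(rows)
    pairs = []
    for win_name, grp in summary.groupby("window"):
        by_beh = grp.set_index("behaviour")
        present = list(by_beh.index)
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                pairs.append({
                    "window": win_name, "behaviour_a": a, "behaviour_b": b,
                    "iqr_overlap": iqr_overlap(
                        by_beh.loc[a, "q1"], by_beh.loc[a, "q3"],
                        by_beh.loc[b, "q1"], by_beh.loc[b, "q3"])})
    return summary, pd.DataFrame(pairs)
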