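"""File formats and pipeline configuration.

Everything on disk is plain CSV or YAML: acceleration traces (timestamp plus
three axes in g), per-second label series, focal records (one row per scan
and one per grooming bout), feature tables, confusion matrices and rate
tables.  Timestamps are ISO-8601 local clock time -- budget windows are
clock-time based, so no time-zone arithmetic is done anywhere.

Readers never silently drop data: every discarded or remapped row is counted
and logged, sensor gaps become in-place NaN spans (the origin of downstream
unclassified epochs), and format violations (non-monotone timestamps,
duplicate seconds, rate mismatches beyond 1%) raise errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import BehaviourConfig, Oscillation
from .types import BEHAVIOURS, TRANSITION, UNLABELLED, AccelTrace, FocalRecord, LabelSeries

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.9f"  # numeric round-trip precision for all writers
_KNOWN_LABELS = set(BEHAVIOURS) | {UNLABELLED, TRANSITION}


@dataclass
class PipelineConfig:
    """Tunable parameters shared by all pipeline stages."""

    sampling_rate_hz: int = 40
    static_window_s: float = 2.0
    vedbas_window_s: float = 3.0
    epoch_s: int = 1
    n_trees: int = 500
    train_fraction: float = 0.7
    day_window: tuple[str, str] = ("07:00", "17:00")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.static_window_s < self.epoch_s or self.vedbas_window_s < self.epoch_s:
            raise ValueError("smoothing windows must be at least one epoch long")
        if (self.sampling_rate_hz * self.epoch_s) % 1 != 0 or self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz x epoch_s must be a positive sample count")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML pipeline configuration, applying defaults for absent keys.

    Unknown keys raise (typo protection); the fully resolved configuration is
    echoed to the log.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "day_window" in raw:
        raw["day_window"] = tuple(raw["day_window"])
    try:
        cfg = PipelineConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid pipeline config: {exc}") from exc
    logger.info("resolved pipeline config: %s", cfg)
    return cfg


# ---------------------------------------------------------------------------
# acceleration traces


def write_accel_csv(trace: AccelTrace, path: str | Path) -> None:
    df = pd.DataFrame(trace.samples, columns=["ax_g", "ay_g", "az_g"])
    df.insert(0, "timestamp_iso", trace.times().strftime("%Y-%m-%dT%H:%M:%S.%f"))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_accel_csv(
    path: str | Path,
    individual_id: str | None = None,
    expected_rate_hz: int | None = None,
) -> AccelTrace:
    """Read an acceleration CSV; gaps become NaN spans, rate is checked.

    Timestamps must be monotone increasing; the sampling rate is inferred
    from the median step and, when ``expected_rate_hz`` is given, must match
    it within 1%.
    """
    df = pd.read_csv(path)
    ind = individual_id or Path(path).stem
    if df.empty:
        logger.warning("%s: empty data section; returning an empty trace", path)
        return AccelTrace(ind, pd.Timestamp("1970-01-01"),
                          expected_rate_hz or 40, np.empty((0, 3)))
    times = pd.DatetimeIndex(pd.to_datetime(df["timestamp_iso"]))
    steps = (times[1:] - times[:-1]).total_seconds().to_numpy() if len(times) > 1 else np.array([])
    if (steps <= 0).any():
        raise ValueError(f"{path}: timestamps are not strictly increasing")
    if steps.size:
        rate = 1.0 / np.median(steps)
    else:
        rate = float(expected_rate_hz or 40)
    if expected_rate_hz is not None and abs(rate - expected_rate_hz) / expected_rate_hz > 0.01:
        raise ValueError(f"{path}: inferred rate {rate:.2f} Hz does not match "
                         f"expected {expected_rate_hz} Hz (>1% off)")
    rate_hz = int(round(rate))
    samples = df[["ax_g", "ay_g", "az_g"]].to_numpy(float)
    # re-grid onto the nominal clock, leaving NaN in gaps
    offsets = np.round((times - times[0]).total_seconds().to_numpy() * rate_hz).astype(int)
    n = offsets[-1] + 1
    full = np.full((n, 3), np.nan)
    full[offsets] = samples
    n_gaps = len([g for g in np.diff(offsets) if g > 1])
    if n_gaps:
        logger.warning("%s: %d gap(s) totalling %d missing samples",
                       path, n_gaps, n - len(offsets))
    return AccelTrace(ind, times[0], rate_hz, full)


# ---------------------------------------------------------------------------
# label series


def write_labels_csv(labels: LabelSeries, path: str | Path) -> None:
    df = pd.DataFrame({
        "timestamp_iso": labels.times().strftime("%Y-%m-%dT%H:%M:%S"),
        "behaviour": labels.labels,
    })
    df.to_csv(path, index=False)


def read_labels_csv(path: str | Path, individual_id: str | None = None) -> LabelSeries:
    """Read a per-second label CSV into a contiguous series.

    Unknown behaviour strings are remapped to "unlabelled" with a logged
    count; duplicate seconds raise; gaps are filled with "unlabelled".
    """
    df = pd.read_csv(path)
    ind = individual_id or Path(path).stem
    if df.empty:
        logger.warning("%s: empty label file", path)
        return LabelSeries(ind, pd.Timestamp("1970-01-01"), np.array([], dtype=object))
    times = pd.DatetimeIndex(pd.to_datetime(df["timestamp_iso"])).floor("s")
    if times.duplicated().any():
        raise ValueError(f"{path}: duplicate seconds in label file")
    if not times.is_monotonic_increasing:
        raise ValueError(f"{path}: timestamps are not increasing")
    raw = df["behaviour"].astype(str).to_numpy()
    unknown = ~np.isin(raw, list(_KNOWN_LABELS))
    if unknown.any():
        logger.warning("%s: %d rows with out-of-vocabulary behaviours mapped "
                       "to unlabelled", path, int(unknown.sum()))
        raw = np.where(unknown, UNLABELLED, raw)
    sec = ((times - times[0]).total_seconds()).astype(int)
    labels = np.full(int(sec[-1]) + 1, UNLABELLED, dtype=object)
    labels[sec] = raw
    return LabelSeries(ind, times[0], labels)


# ---------------------------------------------------------------------------
# focal records


def write_focals_csv(focals: list[FocalRecord], path: str | Path) -> None:
    rows = []
    for r in focals:
        base = {"individual_id": r.individual_id, "follow_id": r.follow_id,
                "follow_start_iso": r.start_time.strftime("%Y-%m-%dT%H:%M:%S"),
                "duration_s": r.duration_s}
        for minute, beh in r.scans:
            rows.append({**base, "record_type": "scan", "minute_index": minute,
                         "behaviour": beh, "role": "", "start_s": "", "end_s": ""})
        for role, s, e in r.grooming_bouts:
            rows.append({**base, "record_type": "bout", "minute_index": "",
                         "behaviour": "", "role": role, "start_s": s, "end_s": e})
    cols = ["record_type", "individual_id", "follow_id", "follow_start_iso",
            "duration_s", "minute_index", "behaviour", "role", "start_s", "end_s"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_focals_csv(path: str | Path) -> list[FocalRecord]:
    df = pd.read_csv(path)
    out = []
    for (ind, fid), grp in df.groupby(["individual_id", "follow_id"], sort=True):
        scans = [(int(r.minute_index), str(r.behaviour))
                 for r in grp.loc[grp.record_type == "scan"].itertuples()]
        bouts = [(str(r.role), float(r.start_s), float(r.end_s))
                 for r in grp.loc[grp.record_type == "bout"].itertuples()]
        out.append(FocalRecord(str(ind), pd.Timestamp(grp["follow_start_iso"].iloc[0]),
                               scans, bouts, float(grp["duration_s"].iloc[0]),
                               follow_id=int(fid)))
    return out


# ---------------------------------------------------------------------------
# feature tables, confusion matrices, rates


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    df = features.copy()
    df["epoch_time"] = pd.DatetimeIndex(df["epoch_time"]).strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["epoch_time"] = pd.to_datetime(df["epoch_time"])
    if "valid" in df.columns:
        df["valid"] = df["valid"].astype(bool)
    if "label" in df.columns:
        df["label"] = df["label"].fillna("")
    return df


def write_confusion_csv(cm: pd.DataFrame, path: str | Path) -> None:
    cm.rename_axis("predicted").to_csv(path)


def read_confusion_csv(path: str | Path) -> pd.DataFrame:
    cm = pd.read_csv(path, index_col=0)
    cm.index.name = "predicted"
    cm.columns.name = "observed"
    return cm.astype(int)


def reference_confusion_matrix() -> pd.DataFrame:
    """The bundled published 6x6 confusion matrix (collar validation study).

    Rows are predicted, columns observed behaviour, entries are seconds; used
    by the worked examples and precision/recall checks.
    """
    with resources.as_file(resources.files("groomacc")
                           / "data" / "reference_confusion_matrix.csv") as p:
        return read_confusion_csv(p)


# ---------------------------------------------------------------------------
# generative ethogram configuration


def save_ethogram(configs: dict[str, BehaviourConfig],
                  weights: dict[str, float], path: str | Path) -> None:
    doc: dict = {"behaviours": {}, "transition_weights": dict(weights)}
    for b, c in configs.items():
        entry: dict = {
            "mean_bout_s": float(c.mean_bout_s),
            "posture_mean": [float(v) for v in c.posture_mean],
            "posture_jitter_deg": float(c.posture_jitter_deg),
            "dynamic_sd_g": float(c.dynamic_sd_g),
        }
        if c.oscillation is not None:
            entry["oscillation"] = {"axis": c.oscillation.axis,
                                    "freq_hz": float(c.oscillation.freq_hz),
                                    "amplitude_g": float(c.oscillation.amplitude_g),
                                    "harmonic_ratio": float(c.oscillation.harmonic_ratio)}
        doc["behaviours"][b] = entry
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_ethogram(path: str | Path) -> tuple[dict[str, BehaviourConfig], dict[str, float]]:
    doc = yaml.safe_load(Path(path).read_text())
    configs = {}
    for b, entry in doc["behaviours"].items():
        osc = entry.get("oscillation")
        configs[b] = BehaviourConfig(
            b, float(entry["mean_bout_s"]), tuple(entry["posture_mean"]),
            float(entry["posture_jitter_deg"]), float(entry["dynamic_sd_g"]),
            Oscillation(osc["axis"], float(osc["freq_hz"]), float(osc["amplitude_g"]),
                        float(osc.get("harmonic_ratio", 0.0)))
            if osc else None)
    weights = {b: float(w) for b, w in doc["transition_weights"].items()}
    return configs, weights


def default_ethogram_path() -> Path:
    with resources.as_file(resources.files("groomacc")
                           / "data" / "ethogram_default.yaml") as p:
        return Path(p)
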