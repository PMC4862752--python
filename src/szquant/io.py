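"""Reading and writing the pipeline's file formats.

All formats are plain delimited text (tab-separated) or YAML:

* EEG trace: two columns ``time_s`` / ``value``, with event markers in a
  side-car YAML file (keys ``ka_injection_s``, ``iv_injection_s``,
  optionally ``fs``). EDF recordings can be *read* when the optional ``mne``
  dependency is installed; output is always delimited text.
* Behavior trace: ``second`` / ``code``, plus optional horizon keys in a
  side-car YAML.
* Events / SE episodes: BED-like intervals ``onset_s`` / ``offset_s`` plus
  an attributes column.
* Dialysis samples: ``t_start_min`` / ``t_end_min`` / ``pg_ml`` / ``phase``.
* Spectrograms: delimited matrix, rows = frequency bins, columns = time bins.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .behavior import BehaviorTrace
from .detect import SeizureEvent
from .dialysis import DialysisSample
from .preprocess import EEGRecording
from .se import SEEpisode
from .spectral import Spectrogram

__all__ = [
    "write_eeg_text",
    "read_eeg_text",
    "read_eeg_edf",
    "write_markers",
    "read_markers",
    "write_behavior",
    "read_behavior",
    "write_intervals",
    "read_intervals",
    "write_dialysis",
    "read_dialysis",
    "write_spectrogram",
]


def write_markers(markers: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in markers.items()}, fh)


def read_markers(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return {k: float(v) for k, v in data.items()}


def write_eeg_text(rec: EEGRecording, path: str | Path, markers_path: str | Path | None = None) -> None:
    t = np.arange(rec.samples.size) / rec.fs
    pd.DataFrame({"time_s": t, "value": rec.samples}).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
    if markers_path is not None:
        write_markers({**rec.markers, "fs": rec.fs}, markers_path)


def read_eeg_text(path: str | Path, markers_path: str | Path | None = None) -> EEGRecording:
    df = pd.read_csv(path, sep="\t")
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, value")
    markers = read_markers(markers_path) if markers_path else {}
    fs = markers.pop("fs", None)
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"{path}: cannot infer a constant sampling rate")
        fs = 1.0 / dt[0]
    return EEGRecording(samples=df["value"].to_numpy(), fs=float(fs), markers=markers)


def read_eeg_edf(path: str | Path, channel: int | str = 0, markers: dict | None = None) -> EEGRecording:
    """Read one channel from an EDF file (requires the optional ``mne``
    dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency (pip install szquant[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if isinstance(channel, int):
        channel = raw.ch_names[channel]
    data = raw.get_data(picks=[channel])[0]
    return EEGRecording(samples=data, fs=float(raw.info["sfreq"]), markers=markers or {})


def write_behavior(trace: BehaviorTrace, path: str | Path, horizons_path: str | Path | None = None) -> None:
    pd.DataFrame({"second": np.arange(trace.n_seconds), "code": trace.codes}).to_csv(
        path, sep="\t", index=False
    )
    if horizons_path is not None:
        write_markers(trace.horizons, horizons_path)


def read_behavior(path: str | Path, horizons_path: str | Path | None = None) -> BehaviorTrace:
    df = pd.read_csv(path, sep="\t", dtype={"code": str})
    if not {"second", "code"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns second, code")
    horizons = read_markers(horizons_path) if horizons_path else {}
    return BehaviorTrace(codes=df["code"].to_numpy(dtype="U4"), horizons=horizons)


def write_intervals(
    intervals: Sequence[SeizureEvent | SEEpisode | tuple], path: str | Path
) -> None:
    rows = []
    for iv in intervals:
        if isinstance(iv, SeizureEvent):
            attrs = f"mode={iv.mode};threshold_x={iv.threshold_x:g};peak={iv.peak_value:.6g}"
            rows.append((iv.onset_s, iv.offset_s, attrs))
        elif isinstance(iv, SEEpisode):
            rows.append((iv.onset_s, iv.offset_s, f"kind={iv.kind}"))
        else:
            on, off = iv
            rows.append((on, off, "."))
    pd.DataFrame(rows, columns=["onset_s", "offset_s", "attributes"]).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_intervals(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(float(r.onset_s), float(r.offset_s)) for r in df.itertuples()]


def write_dialysis(samples: Sequence[DialysisSample], path: str | Path) -> None:
    pd.DataFrame(
        [(s.t_start_min, s.t_end_min, s.conc_pg_ml, s.phase) for s in samples],
        columns=["t_start_min", "t_end_min", "pg_ml", "phase"],
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_dialysis(path: str | Path) -> list[DialysisSample]:
    df = pd.read_csv(path, sep="\t")
    return [
        DialysisSample(float(r.t_start_min), float(r.t_end_min), float(r.pg_ml), str(r.phase))
        for r in df.itertuples()
    ]


def write_spectrogram(spec: Spectrogram, path: str | Path) -> None:
    """Delimited matrix for heat-map plotting: rows = frequency bins,
    columns = time bins; first column holds the frequency."""
    df = pd.DataFrame(spec.power, index=spec.freqs)
    df.index.name = "freq_hz"
    df.to_csv(path, sep="\t", float_format="%.8g")
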