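"""Readers and writers for the interchange formats.

EEG recordings travel either as EDF (read via :mod:`mne`, when installed)
or as the package's plain-text fixture format: a TSV sample matrix (one
column per channel, microvolts) plus a JSON sidecar with the sampling rate,
channel names, pair-onset events and optional ground truth.  Cohorts travel
as CSV with a fixed column set; model coefficients and validation reports as
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .erp import ERPAverage, EpochSet, RawRecording
from .errors import FormatError
from .protocol import COHORT_COLUMNS

__all__ = [
    "read_recording",
    "write_recording",
    "write_erp",
    "read_erp",
    "write_rejection_log",
    "read_cohort",
    "write_cohort",
]


def _sidecar_path(tsv_path: Path) -> Path:
    return tsv_path.with_suffix(".json")


def write_recording(rec: RawRecording, path) -> tuple[Path, Path]:
    """Write a recording as TSV samples + JSON sidecar; returns both paths."""
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "channel_names": rec.channel_names,
        "events": [{"pair_onset_ms": float(e)} for e in rec.events],
        "truth": rec.meta.get("truth"),
        "meta": {k: v for k, v in rec.meta.items() if k != "truth"},
    }
    sc = _sidecar_path(path)
    with open(sc, "w") as fh:
        json.dump(sidecar, fh)
    return path, sc


def _read_fixture(path: Path) -> RawRecording:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FormatError(f"missing JSON sidecar {sc} for {path}")
    with open(sc) as fh:
        try:
            side = json.load(fh)
        except json.JSONDecodeError as e:
            raise FormatError(f"malformed sidecar {sc}: {e}") from None
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:
        raise FormatError(
            f"malformed TSV {path} (file size {path.stat().st_size} bytes): {e}"
        ) from None
    names = side.get("channel_names", list(df.columns))
    if "Cz" not in names:
        raise FormatError(f"{path}: no Cz channel among {names}")
    events = side.get("events")
    if not events:
        raise FormatError(f"{sc}: no pair-onset events")
    meta = dict(side.get("meta") or {})
    if side.get("truth") is not None:
        meta["truth"] = side["truth"]
    return RawRecording(
        samples=df[names].to_numpy().T,
        sampling_rate=float(side["sampling_rate"]),
        channel_names=list(names),
        events=np.array([e["pair_onset_ms"] for e in events], dtype=float),
        meta=meta,
    )


def _read_edf(path: Path) -> RawRecording:
    try:
        import mne
    except ImportError:
        raise FormatError(
            "reading EDF requires the optional 'mne' dependency"
        ) from None
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = list(raw.ch_names)
    if "Cz" not in names:
        raise FormatError(f"{path}: no Cz channel among {names}")
    samples = raw.get_data() * 1e6  # volts -> microvolts
    onsets = [a["onset"] * 1000.0 for a in raw.annotations]
    sidecar = _sidecar_path(path)
    if not onsets and sidecar.exists():
        with open(sidecar) as fh:
            side = json.load(fh)
        onsets = [e["pair_onset_ms"] for e in side.get("events", [])]
    if not onsets:
        raise FormatError(
            f"{path}: no event annotations and no JSON sidecar {sidecar}"
        )
    return RawRecording(
        samples=samples,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=names,
        events=np.asarray(sorted(onsets), dtype=float),
    )


def read_recording(path) -> RawRecording:
    """Read an EEG recording (``.edf``, or fixture ``.tsv`` + ``.json``)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    return _read_fixture(path)


def write_erp(erp: ERPAverage, path) -> tuple[Path, Path]:
    """Write an averaged ERP as TSV (time_ms, uv) + JSON metadata."""
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    pd.DataFrame({"time_ms": erp.times_ms(), "uv": erp.waveform}).to_csv(
        path, sep="\t", index=False
    )
    meta = {
        "window_ms": list(erp.window),
        "sampling_rate": erp.sampling_rate,
        "n_trials_used": erp.n_trials_used,
        "filter_band_hz": list(erp.filter_band),
    }
    sc = _sidecar_path(path)
    with open(sc, "w") as fh:
        json.dump(meta, fh)
    return path, sc


def read_erp(path) -> ERPAverage:
    path = Path(path)
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FormatError(f"missing JSON sidecar {sc} for {path}")
    with open(sc) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path, sep="\t")
    return ERPAverage(
        waveform=df["uv"].to_numpy(),
        window=tuple(meta["window_ms"]),
        sampling_rate=float(meta["sampling_rate"]),
        n_trials_used=int(meta["n_trials_used"]),
        filter_band=tuple(meta["filter_band_hz"]),
    )


def write_rejection_log(epochs: EpochSet, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "trial": np.arange(epochs.retained.size),
        "retained": epochs.retained.astype(int),
        "reason": ["" if r is None else r for r in epochs.reasons],
    }).to_csv(path, sep="\t", index=False)
    return path


def write_cohort(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ("group",) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df
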