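"""Reading, preprocessing and windowing of EHG records.

Two on-disk layouts are supported:

* a minimal WFDB-style pair (``<id>.hea`` text header + ``<id>.dat`` 16-bit
  little-endian signal file), matching the subset of the format used by the
  TPEHG database;
* a delimited-text file with one column per channel and a header row naming
  the channels.

Gestational metadata is taken from ``#`` comment lines in the header when
present, otherwise from a sidecar table (CSV with columns ``record_id``,
``gestation_week_recording``, ``gestation_week_delivery``). A record whose
delivery week cannot be found anywhere is an error — the class label is never
silently defaulted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import CHANNEL_NAMES, EHGRecord, MetadataError, SignalWindow

__all__ = [
    "ChannelMap",
    "FormatError",
    "read_record",
    "write_record",
    "read_metadata_table",
    "write_metadata_table",
    "bandpass_filter",
    "trim_transients",
    "segment_windows",
    "preprocess_channel",
]


class FormatError(ValueError):
    """File exists but does not match the expected layout."""


@dataclass(frozen=True)
class ChannelMap:
    """Selects stored signals for CH1..CH3 and declares their filter state.

    ``indices`` are 0-based positions into the stored signal list.
    ``prefiltered`` means the stored signals already passed the band-pass
    stage, so the pipeline must not filter them again.
    """

    indices: tuple[int, int, int] = (0, 1, 2)
    prefiltered: bool = False


DEFAULT_CHANNEL_MAP = ChannelMap()

# Header comment keys accepted for gestational metadata.  The first pair is
# native; "Gestation"/"Rectime" mirror the TPEHG header vocabulary.
_DELIVERY_KEYS = ("gestation_week_delivery", "gestation")
_RECORDING_KEYS = ("gestation_week_recording", "rectime")


# ---------------------------------------------------------------------------
# WFDB-style header + signal pair
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    lines = hea_path.read_text().splitlines()
    body = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    comments = [ln.lstrip()[1:].strip() for ln in lines if ln.lstrip().startswith("#")]
    if not body:
        raise FormatError(f"{hea_path}: empty header")
    head = body[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea_path}: malformed record line {body[0]!r}")
    record_id = head[0]
    n_sig = int(head[1])
    fs = float(head[2])
    n_samples = int(head[3])
    if len(body) - 1 < n_sig:
        raise FormatError(f"{hea_path}: header declares {n_sig} signals, "
                          f"found {len(body) - 1} signal lines")
    sig_specs = []
    for ln in body[1:1 + n_sig]:
        fields = ln.split()
        fname, fmt = fields[0], fields[1]
        if fmt != "16":
            raise FormatError(f"{hea_path}: unsupported signal format {fmt!r}")
        # gain field: e.g. "13107.2(0)/mV" — gain, optional baseline, units
        m = re.match(r"([0-9.eE+-]+)(?:\(([-0-9]+)\))?(?:/(\S+))?", fields[2])
        if not m:
            raise FormatError(f"{hea_path}: malformed gain field {fields[2]!r}")
        gain = float(m.group(1)) or 200.0
        baseline = int(m.group(2)) if m.group(2) else 0
        sig_specs.append((fname, gain, baseline))
    return record_id, fs, n_samples, sig_specs, comments


def _read_wfdb(hea_path: Path) -> tuple[str, float, np.ndarray, dict[str, float]]:
    record_id, fs, n_samples, sig_specs, comments = _parse_header(hea_path)
    dat_path = hea_path.with_name(sig_specs[0][0])
    try:
        raw = np.fromfile(dat_path, dtype="<i2")
    except OSError as exc:
        raise IOError(f"cannot read signal file {dat_path}: {exc}") from exc
    n_sig = len(sig_specs)
    if raw.size < n_sig * n_samples:
        raise FormatError(f"{dat_path}: expected {n_sig * n_samples} samples, "
                          f"found {raw.size}")
    frames = raw[: n_sig * n_samples].reshape(n_samples, n_sig).T.astype(float)
    signals = np.empty_like(frames)
    for i, (_, gain, baseline) in enumerate(sig_specs):
        signals[i] = (frames[i] - baseline) / gain
    meta = _metadata_from_comments(comments)
    return record_id, fs, signals, meta


def _metadata_from_comments(comments: list[str]) -> dict[str, float]:
    meta: dict[str, float] = {}
    for line in comments:
        parts = line.split()
        if len(parts) < 2:
            continue
        key = parts[0].lower()
        try:
            value = float(parts[1])
        except ValueError:
            continue
        if key in _DELIVERY_KEYS:
            meta["gestation_week_delivery"] = value
        elif key in _RECORDING_KEYS:
            meta["gestation_week_recording"] = value
    return meta


def write_record(
    record: EHGRecord,
    directory: str | Path,
    fmt: str = "wfdb",
    adc_range_mv: float = 2.5,
) -> Path:
    """Write a record as a WFDB header/signal pair or a delimited-text file.

    WFDB output uses 16-bit samples scaled to ``±adc_range_mv`` millivolts,
    mirroring the acquisition resolution of the source database. Returns the
    path of the header (WFDB) or CSV file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        path = directory / f"{record.record_id}.csv"
        pd.DataFrame(record.channels.T, columns=list(CHANNEL_NAMES)).to_csv(
            path, index=False, float_format="%.9g"
        )
        return path
    if fmt != "wfdb":
        raise ValueError(f"unknown record format {fmt!r}")
    gain = 32768.0 / adc_range_mv
    adc = np.clip(np.round(record.channels * gain), -32768, 32767).astype("<i2")
    dat_name = f"{record.record_id}.dat"
    adc.T.reshape(-1).tofile(directory / dat_name)
    hea_path = directory / f"{record.record_id}.hea"
    lines = [f"{record.record_id} 3 {record.fs:g} {record.n_samples}"]
    for name in CHANNEL_NAMES:
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {name}")
    if record.gestation_week_recording is not None:
        lines.append(f"# gestation_week_recording {record.gestation_week_recording:g}")
    lines.append(f"# gestation_week_delivery {record.gestation_week_delivery:g}")
    hea_path.write_text("\n".join(lines) + "\n")
    return hea_path


def _read_csv_record(path: Path) -> tuple[str, np.ndarray]:
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    return path.stem, frame.to_numpy(dtype=float).T


# ---------------------------------------------------------------------------
# Metadata sidecar
# ---------------------------------------------------------------------------

def read_metadata_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"record_id": str})
    if "record_id" not in table.columns or "gestation_week_delivery" not in table.columns:
        raise FormatError(
            f"{path}: metadata table needs record_id and gestation_week_delivery columns"
        )
    return table.set_index("record_id")


def write_metadata_table(records: list[EHGRecord], path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "gestation_week_recording": r.gestation_week_recording,
            "gestation_week_delivery": r.gestation_week_delivery,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_record(
    path: str | Path,
    channel_map: ChannelMap = DEFAULT_CHANNEL_MAP,
    metadata: str | Path | pd.DataFrame | None = None,
) -> EHGRecord:
    """Read one EHG record from a WFDB header or a delimited-text file.

    ``metadata`` supplies gestation weeks for records whose header lacks
    them: either a path to the sidecar CSV or an already-loaded table
    indexed by record_id.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such record file: {path}")
    if path.suffix == ".hea":
        record_id, fs, signals, meta = _read_wfdb(path)
    else:
        record_id, signals = _read_csv_record(path)
        fs, meta = 20.0, {}
    if signals.shape[0] <= max(channel_map.indices):
        raise FormatError(
            f"{path}: channel map needs signal index {max(channel_map.indices)} "
            f"but file stores only {signals.shape[0]} signals"
        )
    channels = signals[list(channel_map.indices)]

    if "gestation_week_delivery" not in meta and metadata is not None:
        table = metadata if isinstance(metadata, pd.DataFrame) else read_metadata_table(metadata)
        if record_id in table.index:
            row = table.loc[record_id]
            meta["gestation_week_delivery"] = float(row["gestation_week_delivery"])
            if "gestation_week_recording" in row and pd.notna(row["gestation_week_recording"]):
                meta["gestation_week_recording"] = float(row["gestation_week_recording"])
    if "gestation_week_delivery" not in meta:
        raise MetadataError(
            f"record {record_id}: gestation week at delivery not found in header "
            f"comments or sidecar metadata; cannot derive class label"
        )
    return EHGRecord(
        record_id=record_id,
        channels=channels,
        fs=fs,
        gestation_week_recording=meta.get("gestation_week_recording"),
        gestation_week_delivery=meta["gestation_week_delivery"],
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = 0.08,
    high: float = 4.0,
    order: int = 4,
    zero_phase: bool = False,
) -> np.ndarray:
    """Butterworth band-pass.

    Default is a single causal pass: the filter transient is dealt with
    downstream by trimming, not by forward-backward filtering. ``zero_phase``
    switches to ``filtfilt`` (which squares the magnitude response and doubles
    the effective order).
    """
    nyquist = fs / 2.0
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"cut-offs must satisfy 0 < low < high < fs/2; got low={low}, "
            f"high={high}, fs={fs}"
        )
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * order:
        raise ValueError(f"signal too short to filter: {x.size} samples")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def trim_transients(x: np.ndarray, fs: float, trim_seconds: float = 180.0) -> np.ndarray:
    """Drop ``trim_seconds`` from each end of the signal."""
    x = np.asarray(x)
    n_trim = int(round(trim_seconds * fs))
    if n_trim == 0:
        return x
    minimum = 2 * n_trim + 1
    if x.size < minimum:
        raise ValueError(
            f"signal of {x.size} samples too short to trim {trim_seconds} s from "
            f"each end at fs={fs}; need at least {minimum} samples"
        )
    return x[n_trim:-n_trim]


def segment_windows(
    x: np.ndarray, fs: float, window_seconds: float = 60.0
) -> list[SignalWindow]:
    """Cut a signal into consecutive non-overlapping windows.

    A trailing partial window is discarded.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(window_seconds * fs))
    if x.size < win:
        raise ValueError(
            f"signal of {x.size} samples shorter than one {window_seconds} s "
            f"window ({win} samples)"
        )
    n_windows = x.size // win
    return [
        SignalWindow(samples=x[i * win:(i + 1) * win], fs=fs, start_index=i * win)
        for i in range(n_windows)
    ]


def preprocess_channel(
    record: EHGRecord,
    channel: str,
    channel_map: ChannelMap = DEFAULT_CHANNEL_MAP,
    low: float = 0.08,
    high: float = 4.0,
    order: int = 4,
    trim_seconds: float = 180.0,
    window_seconds: float = 60.0,
    zero_phase: bool = False,
) -> list[SignalWindow]:
    """Full per-channel preprocessing: band-pass (unless the stored signals
    are already filtered), trim the filter transients, window."""
    x = record.channel(channel)
    if not channel_map.prefiltered:
        x = bandpass_filter(x, record.fs, low=low, high=high, order=order,
                            zero_phase=zero_phase)
    x = trim_transients(x, record.fs, trim_seconds=trim_seconds)
    return segment_windows(x, record.fs, window_seconds=window_seconds)
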