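"""Reading and writing ECG records and beat-matrix datasets.

Two record formats are supported: a minimal subset of the PhysioNet WFDB
format (format-16 single-segment ``.hea``/``.dat`` pairs, gain/baseline
conversion to mV) and a plain two-column CSV ``time,mV`` dialect.  Beat
datasets travel as one CSV per cohort with the fixed header
``subject_id,record_id,s0..s149``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .records import BEAT_LENGTH, BeatDataset, EcgRecord


class ChannelNotFoundError(KeyError):
    """Requested channel absent from a record."""


class FormatError(ValueError):
    """File content violates the expected dialect."""


# ---------------------------------------------------------------------------
# WFDB subset (format 16, single segment)
# ---------------------------------------------------------------------------

_WFDB_GAIN = 200.0  # adu per mV written by default
_WFDB_FMT = 16


def write_record_wfdb(
    channels: list[EcgRecord] | EcgRecord, directory: str | Path, record_name: str
) -> Path:
    """Write one or more same-length channels as a format-16 WFDB record.

    Samples are quantized with a gain of 200 adu/mV into 16-bit integers.
    Returns the path of the header file.
    """
    if isinstance(channels, EcgRecord):
        channels = [channels]
    if not channels:
        raise ValueError("need at least one channel")
    n = channels[0].n_samples
    fs = channels[0].fs
    for ch in channels:
        if ch.n_samples != n or ch.fs != fs:
            raise ValueError("all channels must share length and sampling rate")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dat_name = f"{record_name}.dat"
    adc = np.empty((n, len(channels)), dtype="<i2")
    for j, ch in enumerate(channels):
        q = np.round(ch.samples * _WFDB_GAIN)
        adc[:, j] = np.clip(q, -32768, 32767).astype("<i2")
    (directory / dat_name).write_bytes(adc.tobytes())
    lines = [f"{record_name} {len(channels)} {fs:g} {n}"]
    for j, ch in enumerate(channels):
        first = int(adc[0, j])
        checksum = int(np.sum(adc[:, j], dtype=np.int64) % 65536)
        lines.append(
            f"{dat_name} {_WFDB_FMT} {_WFDB_GAIN:g}(0)/mV 16 0 {first} {checksum} 0 {ch.lead}"
        )
    hea = directory / f"{record_name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


def _parse_gain(token: str) -> tuple[float, float]:
    """Parse a WFDB gain token ``gain(baseline)/units`` -> (gain, baseline)."""
    if "/" in token:
        token = token.split("/", 1)[0]
    baseline = 0.0
    if "(" in token:
        token, rest = token.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(token) if token else 200.0
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means unspecified, default 200
    return gain, baseline


def _read_wfdb(path: Path, channel: str) -> EcgRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    sig_lines = lines[1 : 1 + n_sig]
    names, gains, baselines, fmts, files = [], [], [], [], []
    for j, ln in enumerate(sig_lines):
        parts = ln.split()
        files.append(parts[0])
        fmts.append(int(parts[1].split("x")[0].split(":")[0].split("+")[0]))
        gains.append(_parse_gain(parts[2]) if len(parts) > 2 else (200.0, 0.0))
        baselines.append(gains[-1][1])
        names.append(parts[8] if len(parts) > 8 else f"ch{j}")
    if any(f != _WFDB_FMT for f in fmts):
        raise FormatError(f"{hea.name}: only WFDB format 16 is supported")
    if len(set(files)) != 1:
        raise FormatError(f"{hea.name}: multi-file records are not supported")
    if channel not in names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in record {record_name}; available: {names}"
        )
    j = names.index(channel)
    raw = np.frombuffer((hea.parent / files[0]).read_bytes(), dtype="<i2")
    raw = raw.reshape(-1, n_sig)
    if n_samples and raw.shape[0] < n_samples:
        raise FormatError(f"{files[0]}: fewer samples than the header declares")
    gain, baseline = gains[j]
    samples = (raw[:, j].astype(float) - baseline) / gain
    return EcgRecord(
        samples=samples, fs=fs, record_id=record_name, lead=channel
    )


# ---------------------------------------------------------------------------
# CSV record dialect: two columns (time, mV) or one column (mV)
# ---------------------------------------------------------------------------

def write_record_csv(rec: EcgRecord, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    pd.DataFrame({"time": t, "mV": rec.samples}).to_csv(
        path, index=False, float_format="%.8g"
    )
    return path


def _read_csv_record(path: Path, fs: float | None) -> EcgRecord:
    df = pd.read_csv(path)
    if "mV" not in df.columns:
        raise FormatError(f"{path.name}: expected a 'mV' column")
    if fs is None:
        if "time" in df.columns and len(df) > 1:
            dt = float(np.median(np.diff(df["time"].to_numpy())))
            if dt <= 0:
                raise FormatError(f"{path.name}: non-increasing time column")
            fs = 1.0 / dt
        else:
            raise ValueError(
                "sampling rate required: CSV has no usable 'time' column and no fs given"
            )
    return EcgRecord(samples=df["mV"].to_numpy(float), fs=fs, record_id=path.stem)


def read_record(
    path: str | Path,
    format: str = "wfdb",
    channel: str = "ECG1",
    fs: float | None = None,
    subject_id: str = "",
) -> EcgRecord:
    """Read a single channel of an ECG record.

    Parameters
    ----------
    format : {"wfdb", "csv"}
        ``wfdb`` expects a ``.hea``/``.dat`` pair (format 16); ``csv`` a
        ``time,mV`` table, in which case ``fs`` must be supplied unless a
        time column is present.
    channel : str
        Channel name to select (WFDB only); an explicit choice is required
        because multi-lead records are common.
    """
    path = Path(path)
    if format == "wfdb":
        rec = _read_wfdb(path, channel)
    elif format == "csv":
        rec = _read_csv_record(path, fs)
    else:
        raise ValueError(f"unknown format {format!r}; choose 'wfdb' or 'csv'")
    if subject_id:
        rec.subject_id = subject_id
    return rec


def write_r_indices_csv(
    entries: list[tuple[str, np.ndarray]], path: str | Path
) -> Path:
    """Ground-truth sidecar: one (record_id, sample_index) row per R peak."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "sample_index"])
        for record_id, indices in entries:
            for i in np.asarray(indices).ravel():
                w.writerow([record_id, int(i)])
    return path


# ---------------------------------------------------------------------------
# Beat-matrix CSV dialect
# ---------------------------------------------------------------------------

_BEAT_HEADER = ["subject_id", "record_id"] + [f"s{i}" for i in range(BEAT_LENGTH)]


def write_beats_csv(ds: BeatDataset, path: str | Path) -> Path:
    """Write a beat dataset as CSV: header ``subject_id,record_id,s0..s149``."""
    path = Path(path)
    df = pd.DataFrame(ds.beats, columns=_BEAT_HEADER[2:])
    df.insert(0, "record_id", ds.provenance)
    df.insert(0, "subject_id", ds.labels)
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def read_beats_csv(path: str | Path) -> BeatDataset:
    """Read a beat dataset, validating the dialect row by row."""
    path = Path(path)
    labels: list[str] = []
    prov: list[str] = []
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path.name}: empty file") from None
        if header[:2] != ["subject_id", "record_id"] or len(header) != BEAT_LENGTH + 2:
            raise FormatError(
                f"{path.name}: bad header; expected subject_id,record_id,s0..s{BEAT_LENGTH - 1}"
            )
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != BEAT_LENGTH + 2:
                raise FormatError(
                    f"{path.name}: row {rownum} has {len(row) - 2} sample columns, "
                    f"expected {BEAT_LENGTH}"
                )
            labels.append(row[0])
            prov.append(row[1])
            try:
                rows.append([float(v) for v in row[2:]])
            except ValueError as e:
                raise FormatError(f"{path.name}: row {rownum}: {e}") from None
    beats = np.asarray(rows, dtype=float).reshape(len(rows), BEAT_LENGTH)
    return BeatDataset(
        beats,
        np.array(labels, dtype=object),
        np.array(prov, dtype=object),
    )


def merge_datasets(
    parts: list[BeatDataset], namespace: list[str] | None = None
) -> BeatDataset:
    """Concatenate beat datasets from different sources.

    With ``namespace`` (one prefix per part), labels become
    ``prefix:subject_id`` so subjects from different databases can never be
    silently merged into one identity.  Without namespaces, any label that
    appears in more than one part raises.
    """
    if not parts:
        raise ValueError("no datasets to merge")
    if namespace is not None:
        if len(namespace) != len(parts):
            raise ValueError("one namespace prefix per part required")
        renamed = []
        for prefix, p in zip(namespace, parts):
            labels = np.array([f"{prefix}:{lab}" for lab in p.labels], dtype=object)
            renamed.append(BeatDataset(p.beats, labels, p.provenance))
        parts = renamed
    elif len(parts) > 1:
        seen: dict[str, int] = {}
        for i, p in enumerate(parts):
            for lab in set(map(str, p.labels)):
                if lab in seen:
                    raise ValueError(
                        f"label {lab!r} appears in parts {seen[lab]} and {i}; "
                        "pass namespace prefixes to keep sources distinct"
                    )
                seen[lab] = i
    return BeatDataset.concat(parts)
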