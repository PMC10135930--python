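"""Record and annotation readers/writers.

Two on-disk representations are supported, sharing one in-memory type
(:class:`~ecgmpa.synthetic.AnnotatedRecord`):

* a plain CSV dialect — ``<prefix>.csv`` with ``sample_index,amplitude``
  rows (amplitude in mV) plus ``<prefix>.ann.csv`` with
  ``sample_index,label`` rows, and a small ``<prefix>.meta.json`` sidecar
  recording the sampling rate and generator seed;
* a WFDB-compatible pair — a text ``.hea`` header and a 16-bit
  little-endian ``.dat`` signal file (WFDB format 16, ADC gain in
  adu/mV), with annotations in the same ``.ann.csv`` text format.

The WFDB codec here is deliberately minimal: it reads single- or
multi-channel format-16 records with a per-signal gain and selects one
lead (default channel 0, the MLII position in MIT-BIH-style records).
Binary ``.atr`` annotation files are not parsed; annotations travel as
text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import AnnotatedRecord

DEFAULT_GAIN = 200.0  # adu per mV, the MIT-BIH convention
_FMT = 16


def write_csv_record(record: AnnotatedRecord, prefix: str | Path) -> Path:
    """Write ``<prefix>.csv``, ``<prefix>.ann.csv`` and ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sig = pd.DataFrame(
        {"sample_index": np.arange(len(record.signal)), "amplitude": record.signal}
    )
    sig.to_csv(prefix.with_suffix(".csv"), index=False, float_format="%.17g")
    ann = pd.DataFrame({"sample_index": record.r_peaks, "label": record.labels})
    ann.to_csv(_ann_path(prefix), index=False)
    meta = {
        "record_id": record.record_id,
        "fs": record.fs,
        "n_samples": int(len(record.signal)),
        "seed": record.seed,
    }
    prefix.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
    return prefix.with_suffix(".csv")


def read_csv_record(prefix: str | Path, fs: float | None = None) -> AnnotatedRecord:
    """Read a record written by :func:`write_csv_record`.

    ``fs`` overrides the sidecar value; one of the two must be available.
    """
    prefix = Path(prefix)
    meta_path = prefix.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise ValueError(f"no sampling rate: pass fs= or provide {meta_path}")
    sig = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    ann = _read_annotations(_ann_path(prefix))
    return AnnotatedRecord(
        signal=sig["amplitude"].to_numpy(),
        fs=float(fs),
        r_peaks=ann["sample_index"].to_numpy(),
        labels=list(ann["label"]),
        record_id=meta.get("record_id", prefix.name),
        seed=meta.get("seed"),
    )


def write_wfdb_record(
    record: AnnotatedRecord, prefix: str | Path, gain: float = DEFAULT_GAIN
) -> Path:
    """Write ``<prefix>.hea`` + ``<prefix>.dat`` (format 16) + ``<prefix>.ann.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    adu = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    prefix.with_suffix(".dat").write_bytes(adu.tobytes())
    header = (
        f"{prefix.name} 1 {record.fs:g} {len(adu)}\n"
        f"{prefix.name}.dat {_FMT} {gain:g} 16 0 {int(adu[0]) if len(adu) else 0} 0 0 MLII\n"
    )
    prefix.with_suffix(".hea").write_text(header)
    ann = pd.DataFrame({"sample_index": record.r_peaks, "label": record.labels})
    ann.to_csv(_ann_path(prefix), index=False)
    return prefix.with_suffix(".hea")


def read_wfdb_record(prefix: str | Path, channel: int = 0) -> AnnotatedRecord:
    """Read a format-16 WFDB record plus its text annotation file.

    ``channel`` selects the lead of a multi-channel record (default 0,
    the MLII slot in MIT-BIH-style layouts).
    """
    prefix = Path(prefix)
    lines = prefix.with_suffix(".hea").read_text().strip().splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    if not 0 <= channel < n_sig:
        raise ValueError(f"channel {channel} out of range for {n_sig} signal(s)")
    sig_lines = lines[1 : 1 + n_sig]
    fmts, gains = [], []
    for ln in sig_lines:
        f = ln.split()
        fmts.append(int(f[1].split("x")[0]))
        gains.append(float(f[2].split("(")[0].split("/")[0]) if len(f) > 2 else DEFAULT_GAIN)
    if any(f != _FMT for f in fmts):
        raise ValueError(f"only WFDB format {_FMT} is supported, got {fmts}")
    raw = np.frombuffer(prefix.with_suffix(".dat").read_bytes(), dtype="<i2")
    # format-16 multi-channel data is sample-interleaved
    raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig)
    gain = gains[channel] or DEFAULT_GAIN
    signal = raw[:, channel].astype(float) / gain
    ann = _read_annotations(_ann_path(prefix))
    keep = ann["sample_index"] < len(signal)
    ann = ann[keep]
    return AnnotatedRecord(
        signal=signal,
        fs=fs,
        r_peaks=ann["sample_index"].to_numpy(),
        labels=list(ann["label"]),
        record_id=prefix.name,
    )


def _ann_path(prefix: Path) -> Path:
    return prefix.parent / (prefix.name + ".ann.csv")


def _read_annotations(path: Path) -> pd.DataFrame:
    ann = pd.read_csv(path)
    if not {"sample_index", "label"} <= set(ann.columns):
        raise ValueError(f"{path} must have sample_index,label columns")
    return ann.sort_values("sample_index", kind="stable").reset_index(drop=True)
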