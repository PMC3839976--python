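"""Recording and results I/O.

Two interchange formats for recordings: 16-bit EDF (written by a compact
built-in writer, read back through MNE's EDF reader) and a lossless
``.npy`` + JSON-header dialect.  Event markers and the exact sample count
accompany EDF files in a JSON sidecar (``<file>.events.json``) — the
package's documented dialect — and are restored on read; annotations in
third-party EDF+ files whose descriptions match the two condition names
are used when no sidecar exists.  Result tables are TSV with JSON
sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features.registry import FeatureMatrix
from .synth import Recording


class FormatError(ValueError):
    """Unreadable or malformed recording file."""


# ---------------------------------------------------------------------------
# npy + JSON dialect

def write_recording_npy(rec: Recording, basepath: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.npy`` (channels x time float64, uV) + ``<base>.json``."""
    base = Path(basepath)
    npy = base.with_suffix(".npy")
    meta = base.with_suffix(".json")
    np.save(npy, rec.samples)
    header = {
        "rate": rec.rate,
        "channel_labels": list(rec.channel_labels),
        "events": [[int(i), c] for i, c in rec.events],
        "subject_id": rec.subject_id,
        "group_tag": rec.group_tag,
        "units": "uV",
    }
    meta.write_text(json.dumps(header, indent=1))
    return npy, meta


def read_recording_npy(basepath: str | Path) -> Recording:
    base = Path(basepath)
    npy = base.with_suffix(".npy")
    meta = base.with_suffix(".json")
    if not npy.exists() or not meta.exists():
        raise FormatError(f"missing {npy} or {meta}")
    try:
        header = json.loads(meta.read_text())
        samples = np.load(npy)
        return Recording(
            samples=samples, rate=float(header["rate"]),
            channel_labels=list(header["channel_labels"]),
            events=[(int(i), str(c)) for i, c in header["events"]],
            subject_id=header.get("subject_id", "S00"),
            group_tag=header.get("group_tag", "responsive"),
        )
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed header {meta}: {exc}") from exc


# ---------------------------------------------------------------------------
# EDF

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field too long: {s!r} > {width}")
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Write a plain 16-bit EDF file plus a JSON event sidecar.

    Physical units are microvolts; per-channel physical ranges are rounded
    outward to integers so header fields stay short.  The signal is padded
    with zeros to a whole number of 1 s records; the sidecar stores the
    true sample count, events, subject id and group tag.
    """
    path = Path(path)
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))
    n_ch = rec.samples.shape[0]
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, : rec.n_samples] = rec.samples

    pmin = np.floor(padded.min(axis=1)).astype(int)
    pmax = np.ceil(padded.max(axis=1)).astype(int)
    same = pmax <= pmin
    pmax[same] = pmin[same] + 1
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin[:, None]) / gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join([
        _edf_field(0, 8),
        _edf_field(rec.subject_id, 80),
        _edf_field(f"group {rec.group_tag}", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (n_ch + 1), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    per_signal = b"".join([
        b"".join(_edf_field(lab, 16) for lab in rec.channel_labels),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(int(v), 8) for v in pmin),
        b"".join(_edf_field(int(v), 8) for v in pmax),
        b"".join(_edf_field(dmin, 8) for _ in range(n_ch)),
        b"".join(_edf_field(dmax, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(spr, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for rec_i in range(n_records):
            chunk = digital[:, rec_i * spr:(rec_i + 1) * spr]
            fh.write(chunk.tobytes())

    sidecar = {
        "n_samples": int(rec.n_samples),
        "events": [[int(i), c] for i, c in rec.events],
        "subject_id": rec.subject_id,
        "group_tag": rec.group_tag,
    }
    Path(str(path) + ".events.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_edf(path: str | Path) -> Recording:
    """Read an EDF file via MNE; restore events from the sidecar if present."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"unreadable EDF {path}: {exc}") from exc
    samples = raw.get_data() * 1e6  # MNE returns volts for uV channels
    labels = list(raw.ch_names)
    rate = float(raw.info["sfreq"])
    events: list[tuple[int, str]] = []
    subject_id, group_tag = path.stem, "responsive"
    n_samples = samples.shape[1]
    sidecar = Path(str(path) + ".events.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        events = [(int(i), str(c)) for i, c in meta.get("events", [])]
        subject_id = meta.get("subject_id", subject_id)
        group_tag = meta.get("group_tag", group_tag)
        n_samples = int(meta.get("n_samples", n_samples))
    else:
        for onset, desc in zip(raw.annotations.onset,
                               raw.annotations.description):
            if desc in ("imagery", "rest"):
                events.append((int(round(onset * rate)), desc))
    return Recording(
        samples=samples[:, :n_samples], rate=rate, channel_labels=labels,
        events=events, subject_id=subject_id, group_tag=group_tag,
    )


def read_recording(path: str | Path) -> Recording:
    """Dispatch on extension: ``.edf`` or the ``.npy``+JSON dialect."""
    p = Path(path)
    if p.suffix.lower() == ".edf":
        return read_recording_edf(p)
    if p.suffix.lower() in (".npy", ".json", ""):
        return read_recording_npy(p)
    raise FormatError(f"unknown recording format: {p.suffix!r}")


# ---------------------------------------------------------------------------
# result tables

def write_rejection_log(log: list[dict], path: str | Path) -> Path:
    """Rejection log as TSV: event index, condition, rule, channel."""
    path = Path(path)
    df = pd.DataFrame(log) if log else pd.DataFrame(
        columns=["event", "condition", "reason", "channel"]
    )
    df = df.fillna({"reason": "", "channel": ""})
    df.to_csv(path, sep="\t", index=False)
    return path


def write_results_table(results, path: str | Path) -> Path:
    """Classification results as TSV (one row per subject/feature/classifier)."""
    rows = [{
        "subject": r.subject_id, "group": r.group_tag,
        "feature": r.feature_name, "classifier": r.classifier,
        "N": r.n_total, "n1": r.n1, "n2": r.n2, "n_correct": r.n_correct,
        "accuracy": r.accuracy, "cpro": r.cpro, "z": r.z, "p": r.p,
        "iocc": r.iocc, "failed": r.failed, "reason": r.reason,
    } for r in results]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_feature_matrix(fm: FeatureMatrix, basepath: str | Path) -> tuple[Path, Path]:
    """Feature matrix as TSV plus a JSON sidecar with labels and flags."""
    base = Path(basepath)
    tsv = base.with_suffix(".tsv")
    meta = base.with_suffix(".meta.json")
    df = pd.DataFrame(fm.values, columns=fm.dim_labels)
    df.insert(0, "condition", fm.conditions)
    df.to_csv(tsv, sep="\t", index=False)
    meta.write_text(json.dumps({
        "feature_name": fm.feature_name,
        "subject_id": fm.subject_id,
        "group_tag": fm.group_tag,
        "degenerate_flag": fm.degenerate_flag,
        "degenerate_reason": fm.degenerate_reason,
        "n_trials": fm.n_trials,
        "n_dims": len(fm.dim_labels),
    }, indent=1))
    return tsv, meta
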