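"""Session persistence: HDF5 and plain delimited-text formats.

An HDF5 session file holds groups ``/ref`` and ``/exp`` (dataset
``samples``) and ``/meta`` attributes (``fs``, ``subject_id``,
ground-truth R peaks when the session is synthetic).  The text format is
a two-column tab-separated table (REF, EXP) with a ``# fs=... subject=...``
header line, for quick inspection and interoperability.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from seatecg.signals import SignalRecord

__all__ = ["write_session_h5", "read_session_h5", "write_session_txt",
           "read_session_txt"]


def write_session_h5(path: str | Path, ref: SignalRecord, exp: SignalRecord) -> None:
    with h5py.File(path, "w") as f:
        f.create_group("ref").create_dataset("samples", data=ref.samples)
        f.create_group("exp").create_dataset("samples", data=exp.samples)
        meta = f.create_group("meta")
        meta.attrs["fs"] = ref.fs
        meta.attrs["subject_id"] = ref.subject_id
        if "r_peaks_true" in ref.meta:
            meta.create_dataset("r_peaks_true", data=ref.meta["r_peaks_true"])
        if "clip_level" in ref.meta:
            meta.attrs["clip_level"] = ref.meta["clip_level"]


def read_session_h5(path: str | Path) -> tuple[SignalRecord, SignalRecord]:
    with h5py.File(path, "r") as f:
        fs = float(f["meta"].attrs["fs"])
        sid = str(f["meta"].attrs["subject_id"])
        meta: dict = {}
        if "r_peaks_true" in f["meta"]:
            meta["r_peaks_true"] = f["meta/r_peaks_true"][()]
        if "clip_level" in f["meta"].attrs:
            meta["clip_level"] = float(f["meta"].attrs["clip_level"])
        ref = SignalRecord(f["ref/samples"][()], fs, "REF", sid, meta=dict(meta))
        exp = SignalRecord(f["exp/samples"][()], fs, "EXP", sid, meta=dict(meta))
    return ref, exp


def write_session_txt(path: str | Path, ref: SignalRecord, exp: SignalRecord) -> None:
    header = f"fs={ref.fs} subject={ref.subject_id} columns=REF,EXP"
    np.savetxt(
        path,
        np.column_stack([ref.samples, exp.samples]),
        delimiter="\t",
        header=header,
        fmt="%.6g",
    )


def read_session_txt(path: str | Path) -> tuple[SignalRecord, SignalRecord]:
    with open(path) as f:
        first = f.readline().lstrip("#").split()
    kv = dict(tok.split("=", 1) for tok in first if "=" in tok)
    fs = float(kv.get("fs", 1000.0))
    sid = kv.get("subject", "")
    data = np.loadtxt(path, delimiter="\t")
    ref = SignalRecord(data[:, 0], fs, "REF", sid)
    exp = SignalRecord(data[:, 1], fs, "EXP", sid)
    return ref, exp
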