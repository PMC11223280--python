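"""Readers and writers.

Three recording dialects are supported:

- ``tsv_manifest`` — the package's own plain-text format: a channels x
  samples TSV of amplitudes plus a JSON sidecar with labels, sampling
  rate, subject id and group.
- ``eeglab_set`` — EEGLAB ``.set`` files (MATLAB v5 container, read via
  scipy.io), with the sample matrix either embedded or in a raw float32
  ``.fdt`` sidecar, as in BIDS-EEG derivatives.
- ``edf`` — European Data Format; a minimal reader/writer for
  continuous unannotated EDF is included here because no EDF library is
  assumed installed.

Connectivity matrices and networks are exported as labeled TSV with a
JSON sidecar carrying provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from eegfc.connectivity import ConnectivityMatrix
from eegfc.errors import ConfigurationError, DataError
from eegfc.graphnet import BinaryNetwork
from eegfc.signal_prep import BANDS, Recording
from eegfc.synth import SyntheticStudy

DIALECTS = ("eeglab_set", "edf", "tsv_manifest")


# ---------------------------------------------------------------- tsv_manifest

def write_recording_tsv(rec: Recording, directory: str | Path) -> Path:
    """Write one subject as <id>.tsv (channels x samples) + <id>.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = rec.subject_id or "recording"
    tsv = directory / f"{stem}.tsv"
    np.savetxt(tsv, rec.data, delimiter="\t", fmt="%.10g")
    manifest = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "n_samples": rec.n_samples,
    }
    (directory / f"{stem}.json").write_text(json.dumps(manifest, indent=1))
    return tsv


def _read_tsv_manifest(path: Path) -> Recording:
    tsv = path.with_suffix(".tsv")
    sidecar = path.with_suffix(".json")
    if not tsv.exists():
        raise DataError(f"missing data file {tsv}")
    if not sidecar.exists():
        raise DataError(f"missing manifest sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "channel_labels"):
        if key not in meta:
            raise DataError(f"{sidecar}: manifest missing {key!r}")
    data = np.loadtxt(tsv, delimiter="\t", ndmin=2)
    if data.shape[0] != len(meta["channel_labels"]):
        raise DataError(
            f"{tsv}: {data.shape[0]} rows but {len(meta['channel_labels'])} labels in manifest"
        )
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channel_labels=tuple(meta["channel_labels"]),
        subject_id=str(meta.get("subject_id", path.stem)),
        group=str(meta.get("group", "")),
    )


def write_study(study: SyntheticStudy, directory: str | Path) -> Path:
    """Write a synthetic study: per-subject TSV+JSON plus a study manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in study.recordings:
        write_recording_tsv(rec, directory)
    spec = study.spec
    manifest = {
        "group_labels": list(spec.group_labels),
        "n_subjects_per_group": list(spec.n_subjects_per_group),
        "fs": spec.fs,
        "duration_s": spec.duration_s,
        "seed": spec.seed,
        "bands": list(spec.bands),
        "base_pairs": spec.base_pairs,
        "band_effects": [
            {"group": g, "band": b, "effect": e} for (g, b), e in spec.band_effects.items()
        ],
        "subjects": [rec.subject_id for rec in study.recordings],
        "ground_truth": {
            subj: {
                band: [asdict(cs) for cs in couplings]
                for band, couplings in bands.items()
            }
            for subj, bands in study.ground_truth.items()
        },
    }
    out = directory / "study_manifest.json"
    out.write_text(json.dumps(manifest, indent=1))
    return out


def read_study(directory: str | Path) -> list[Recording]:
    """Load every subject of a written study (ground truth stays in the manifest)."""
    directory = Path(directory)
    manifest_path = directory / "study_manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no study_manifest.json under {directory}")
    manifest = json.loads(manifest_path.read_text())
    return [_read_tsv_manifest(directory / subj) for subj in manifest["subjects"]]


# ---------------------------------------------------------------------- EDF

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def write_edf(rec: Recording, path: str | Path, record_duration_s: float = 1.0) -> Path:
    """Write a continuous, annotation-free EDF file (16-bit samples)."""
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs * record_duration_s))
    if abs(spr - fs * record_duration_s) > 1e-9:
        raise ConfigurationError("record duration must hold an integer number of samples")
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise DataError(f"recording shorter than one {record_duration_s} s data record")
    data = rec.data[:, : n_rec * spr]
    ns = rec.n_channels

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    header = b"".join([
        pad("0", 8),
        pad(rec.subject_id or "X", 80),
        pad("eegfc export", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad(f"{record_duration_s:g}", 8),
        pad(str(ns), 4),
    ])
    sig = b"".join([
        b"".join(pad(lbl, 16) for lbl in rec.channel_labels),
        b"".join(pad("EEG", 80) for _ in range(ns)),
        b"".join(pad("uV", 8) for _ in range(ns)),
        b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_min),
        b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_max),
        b"".join(pad(str(_EDF_DIG_MIN), 8) for _ in range(ns)),
        b"".join(pad(str(_EDF_DIG_MAX), 8) for _ in range(ns)),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad(str(spr), 8) for _ in range(ns)),
        b"".join(pad("", 32) for _ in range(ns)),
    ])
    gain = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    dig = np.round((data - phys_min[:, None]) / gain[:, None] + _EDF_DIG_MIN)
    dig = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            fh.write(dig[:, r * spr : (r + 1) * spr].tobytes())
    return path


def _read_edf(path: Path) -> Recording:
    raw = path.read_bytes()
    if len(raw) < 256:
        raise DataError(f"{path}: truncated EDF header")
    try:
        n_rec = int(raw[236:244].decode("ascii").strip())
        rec_dur = float(raw[244:252].decode("ascii").strip())
        ns = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise DataError(f"{path}: malformed EDF header: {exc}") from None
    hdr_len = 256 * (1 + ns)
    if len(raw) < hdr_len:
        raise DataError(f"{path}: truncated EDF signal headers")
    sig = raw[256:hdr_len]

    def fields(offset: int, width: int) -> list[str]:
        base = offset * ns
        return [
            sig[base + k * width : base + (k + 1) * width].decode("ascii").strip()
            for k in range(ns)
        ]

    labels = fields(0, 16)
    if any(not l for l in labels):
        raise DataError(f"{path}: EDF signal labels missing")
    # fixed EDF layout: labels 16, transducer 80, unit 8, then 8-byte numeric fields
    off = 16 + 80 + 8
    phys_min = np.array([float(v) for v in _slice_fields(sig, ns, off, 8)])
    phys_max = np.array([float(v) for v in _slice_fields(sig, ns, off + 8, 8)])
    dig_min = np.array([float(v) for v in _slice_fields(sig, ns, off + 16, 8)])
    dig_max = np.array([float(v) for v in _slice_fields(sig, ns, off + 24, 8)])
    spr = [int(v) for v in _slice_fields(sig, ns, off + 32 + 80, 8)]
    if len(set(spr)) != 1:
        raise DataError(f"{path}: mixed per-signal sampling rates are not supported")
    spr0 = spr[0]
    fs = spr0 / rec_dur
    expect = hdr_len + n_rec * ns * spr0 * 2
    if len(raw) < expect:
        raise DataError(f"{path}: truncated EDF data ({len(raw)} < {expect} bytes)")
    dig = np.frombuffer(raw[hdr_len:expect], dtype="<i2").reshape(n_rec, ns, spr0)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (dig.transpose(1, 0, 2).reshape(ns, -1) - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    return Recording(
        data=data, fs=fs, channel_labels=tuple(labels), subject_id=path.stem
    )


def _slice_fields(sig: bytes, ns: int, offset: int, width: int) -> list[str]:
    base = offset * ns
    return [
        sig[base + k * width : base + (k + 1) * width].decode("ascii").strip()
        for k in range(ns)
    ]


# ------------------------------------------------------------------ EEGLAB

def _read_eeglab_set(path: Path) -> Recording:
    try:
        mat = scipy.io.loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except NotImplementedError:
        raise DataError(f"{path}: MATLAB v7.3 (HDF5) .set files are not supported") from None
    except Exception as exc:  # scipy raises plain errors on truncation
        raise DataError(f"{path}: cannot parse as EEGLAB .set: {exc}") from None
    eeg = mat.get("EEG", None)
    if eeg is None:
        # some exports store the struct fields at top level
        class _Top:  # noqa: D401 - tiny adapter
            pass

        eeg = _Top()
        for key in ("data", "srate", "nbchan", "pnts", "chanlocs"):
            if key in mat:
                setattr(eeg, key, mat[key])
    for attr in ("data", "srate", "nbchan"):
        if not hasattr(eeg, attr):
            raise DataError(f"{path}: EEGLAB structure missing field {attr!r}")
    nbchan = int(eeg.nbchan)
    data = eeg.data
    if isinstance(data, str):
        fdt = path.parent / data
        if not fdt.exists():
            fdt = path.with_suffix(".fdt")
        if not fdt.exists():
            raise DataError(f"{path}: sample file {data!r} not found")
        flat = np.fromfile(fdt, dtype="<f4")
        if flat.size % nbchan:
            raise DataError(f"{fdt}: sample count not divisible by {nbchan} channels")
        data = flat.reshape(-1, nbchan).T  # .fdt multiplexes by sample
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:  # epoched .set: concatenate trials
        data = data.reshape(data.shape[0], -1)
    try:
        chanlocs = eeg.chanlocs
        labels = tuple(str(c.labels) for c in np.atleast_1d(chanlocs))
    except AttributeError:
        raise DataError(f"{path}: channel labels missing from chanlocs") from None
    return Recording(
        data=data,
        fs=float(eeg.srate),
        channel_labels=labels,
        subject_id=path.stem,
    )


# --------------------------------------------------------------- dispatch

def load_recording(path: str | Path, dialect: str) -> Recording:
    """Load one subject's recording under the named dialect."""
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if dialect == "tsv_manifest":
        return _read_tsv_manifest(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if dialect == "edf":
        return _read_edf(path)
    return _read_eeglab_set(path)


# ------------------------------------------------------------- matrices etc.

def write_connectivity(m: ConnectivityMatrix, directory: str | Path) -> Path:
    """Labeled TSV + JSON sidecar for one connectivity matrix."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{m.subject_id}_{m.band.name}_{m.metric}"
    df = pd.DataFrame(m.values, index=m.channel_labels, columns=m.channel_labels)
    out = directory / f"{stem}.tsv"
    df.to_csv(out, sep="\t", float_format="%.8g")
    meta = {
        "metric": m.metric,
        "band": m.band.name,
        "subject_id": m.subject_id,
        "group": m.group,
        "n_epochs_averaged": m.n_epochs_averaged,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    return out


def read_connectivity(tsv_path: str | Path) -> ConnectivityMatrix:
    tsv_path = Path(tsv_path)
    sidecar = tsv_path.with_suffix(".json")
    if not sidecar.exists():
        raise DataError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(),
        metric=meta["metric"],
        band=BANDS[meta["band"]],
        channel_labels=tuple(df.index),
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group", ""),
        n_epochs_averaged=int(meta.get("n_epochs_averaged", 1)),
    )


def write_network(net: BinaryNetwork, directory: str | Path) -> Path:
    """Adjacency TSV + edge-list TSV for one binary network."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{net.subject_id}_{net.band.name}_net"
    adj = pd.DataFrame(net.adjacency, index=net.channel_labels, columns=net.channel_labels)
    out = directory / f"{stem}_adjacency.tsv"
    adj.to_csv(out, sep="\t")
    edges = [
        {"source": net.channel_labels[i], "target": net.channel_labels[j]}
        for i in range(net.n_nodes)
        for j in range(i + 1, net.n_nodes)
        if net.adjacency[i, j]
    ]
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(
        directory / f"{stem}_edges.tsv", sep="\t", index=False
    )
    (directory / f"{stem}.json").write_text(
        json.dumps({"threshold": net.threshold, "band": net.band.name,
                    "subject_id": net.subject_id, "group": net.group}, indent=1)
    )
    return out
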