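"""Readers and writers for recordings and result tables.

The native on-disk dialect is a long-format CSV with columns
``subject, channel, wavelength_nm, sample_index, value`` plus a JSON
sidecar (same stem, ``.json``) carrying the sampling rate, per-channel
gain/CV metadata, the video-onset markers, the RAS item responses and,
for simulated data, the generator's ground truth.  SNIRF (HDF5) files with
one ``/nirs{i}`` group per subject are accepted as an alternative input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DyadCompletenessError,
    FormatError,
    MarkerMissingError,
)
from .ras import RASResponse
from .recording import RawDyadRecording, SubjectRecording, WAVELENGTHS_NM

_CSV_COLUMNS = ["subject", "channel", "wavelength_nm", "sample_index", "value"]


def write_dyad_recording(recording: RawDyadRecording, stem: Path | str) -> tuple[Path, Path]:
    """Write one recording as ``<stem>.csv`` + ``<stem>.json``; returns the paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for subj in recording.subjects:
        for ch in subj.channels:
            for wl in WAVELENGTHS_NM:
                series = subj.od[ch][wl]
                frames.append(
                    pd.DataFrame(
                        {
                            "subject": subj.label,
                            "channel": ch,
                            "wavelength_nm": wl,
                            "sample_index": np.arange(series.size),
                            "value": series,
                        }
                    )
                )
    csv_path = stem.with_suffix(".csv")
    # %.17g round-trips float64 exactly
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False, float_format="%.17g")

    meta = {
        "dyad_id": recording.dyad_id,
        "sequence_label": recording.sequence_label,
        "sampling_rate": recording.sampling_rate,
        "video_onsets_s": list(recording.video_onsets_s),
        "subjects": {
            subj.label: {
                "gain": {str(ch): g for ch, g in subj.gain.items()},
                "cv": {
                    str(ch): {str(wl): v for wl, v in by_wl.items()}
                    for ch, by_wl in subj.cv.items()
                },
                "ras_items": list(subj.ras.items) if subj.ras is not None else None,
            }
            for subj in recording.subjects
        },
        "sim_truth": recording.sim_truth,
    }
    json_path = stem.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path, json_path


def _read_csv_dialect(path: Path) -> RawDyadRecording:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surfaced as a format error
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df[~np.isfinite(df["value"])]
    if len(bad):
        first = bad.index[0]
        raise FormatError(f"{path}: non-finite value at row {first + 2} (1-based incl. header)")

    json_path = path.with_suffix(".json")
    if not json_path.exists():
        raise FormatError(f"{path}: JSON sidecar {json_path.name} not found")
    meta = json.loads(json_path.read_text())
    if "video_onsets_s" not in meta or not meta["video_onsets_s"]:
        raise MarkerMissingError(f"{json_path}: video-onset markers missing")

    subject_labels = sorted(df["subject"].astype(str).unique())
    if len(subject_labels) != 2:
        raise DyadCompletenessError(
            f"{path}: expected 2 subjects, found {len(subject_labels)} "
            f"({subject_labels})"
        )
    subjects = []
    for label in subject_labels:
        sub = df[df["subject"].astype(str) == label]
        smeta = meta["subjects"][label]
        od: dict[int, dict[int, np.ndarray]] = {}
        for (ch, wl), grp in sub.groupby(["channel", "wavelength_nm"], sort=True):
            series = (
                grp.sort_values("sample_index")["value"].to_numpy(dtype=float)
            )
            od.setdefault(int(ch), {})[int(wl)] = series
        gain = {int(ch): float(g) for ch, g in smeta["gain"].items()}
        cv = {
            int(ch): {int(wl): float(v) for wl, v in by_wl.items()}
            for ch, by_wl in smeta["cv"].items()
        }
        ras = (
            RASResponse(tuple(int(x) for x in smeta["ras_items"]))
            if smeta.get("ras_items")
            else None
        )
        subjects.append(SubjectRecording(label=label, od=od, gain=gain, cv=cv, ras=ras))

    return RawDyadRecording(
        dyad_id=str(meta["dyad_id"]),
        sequence_label=str(meta["sequence_label"]),
        sampling_rate=float(meta["sampling_rate"]),
        subjects=(subjects[0], subjects[1]),
        video_onsets_s=tuple(float(t) for t in meta["video_onsets_s"]),
        sim_truth=meta.get("sim_truth"),
    )


# ---------------------------------------------------------------------------
# SNIRF (HDF5) alternative reader/writer: one /nirs{i} group per subject.
# ---------------------------------------------------------------------------

def write_snirf(recording: RawDyadRecording, path: Path | str) -> Path:
    """Write a two-subject SNIRF file (groups ``/nirs1`` and ``/nirs2``)."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = recording.n_samples
    time = np.arange(n) / recording.sampling_rate
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        for si, subj in enumerate(recording.subjects, start=1):
            g = f.create_group(f"nirs{si}")
            channels = subj.channels
            cols = []
            ml_index = 0
            data = g.create_group("data1")
            for ch in channels:
                for wi, wl in enumerate(WAVELENGTHS_NM, start=1):
                    ml_index += 1
                    ml = data.create_group(f"measurementList{ml_index}")
                    ml.create_dataset("sourceIndex", data=int(ch))
                    ml.create_dataset("detectorIndex", data=int(ch))
                    ml.create_dataset("wavelengthIndex", data=wi)
                    ml.create_dataset("dataType", data=99999)  # processed dOD
                    ml.create_dataset("dataTypeLabel", data=np.bytes_("dOD"))
                    cols.append(subj.od[ch][wl])
            data.create_dataset("dataTimeSeries", data=np.column_stack(cols))
            data.create_dataset("time", data=time)
            probe = g.create_group("probe")
            probe.create_dataset("wavelengths", data=np.asarray(WAVELENGTHS_NM, float))
            stim = g.create_group("stim1")
            stim.create_dataset("name", data=np.bytes_("video"))
            stim.create_dataset(
                "data",
                data=np.column_stack(
                    [
                        np.asarray(recording.video_onsets_s, float),
                        np.full(len(recording.video_onsets_s), 114.0),
                        np.ones(len(recording.video_onsets_s)),
                    ]
                ),
            )
            tags = g.create_group("metaDataTags")
            side = {
                "label": subj.label,
                "gain": {str(c): v for c, v in subj.gain.items()},
                "cv": {
                    str(c): {str(wl): v for wl, v in by_wl.items()}
                    for c, by_wl in subj.cv.items()
                },
                "ras_items": list(subj.ras.items) if subj.ras else None,
            }
            tags.create_dataset("dyadsyncSubject", data=np.bytes_(json.dumps(side)))
        f.create_dataset(
            "dyadsyncMeta",
            data=np.bytes_(
                json.dumps(
                    {
                        "dyad_id": recording.dyad_id,
                        "sequence_label": recording.sequence_label,
                        "sampling_rate": recording.sampling_rate,
                        "sim_truth": recording.sim_truth,
                    }
                )
            ),
        )
    return path


def read_snirf(path: Path | str) -> RawDyadRecording:
    """Read a two-subject SNIRF file written by :func:`write_snirf`."""
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        groups = sorted(k for k in f.keys() if k.startswith("nirs"))
        if len(groups) != 2:
            raise DyadCompletenessError(
                f"{path}: expected 2 /nirs groups, found {len(groups)}"
            )
        meta = (
            json.loads(bytes(f["dyadsyncMeta"][()]).decode())
            if "dyadsyncMeta" in f
            else {}
        )
        subjects = []
        sampling_rate = meta.get("sampling_rate")
        onsets: tuple[float, ...] = tuple(meta.get("video_onsets_s", ()))
        for gname in groups:
            g = f[gname]
            data = g["data1"]
            ts = np.asarray(data["dataTimeSeries"])
            time = np.asarray(data["time"])
            if sampling_rate is None:
                sampling_rate = float(1.0 / np.median(np.diff(time)))
            wavelengths = [int(w) for w in np.asarray(g["probe/wavelengths"])]
            side = json.loads(bytes(g["metaDataTags/dyadsyncSubject"][()]).decode())
            od: dict[int, dict[int, np.ndarray]] = {}
            mls = sorted(
                (k for k in data.keys() if k.startswith("measurementList")),
                key=lambda s: int(s[len("measurementList") :]),
            )
            for col, ml_name in enumerate(mls):
                ml = data[ml_name]
                ch = int(ml["sourceIndex"][()])
                wl = wavelengths[int(ml["wavelengthIndex"][()]) - 1]
                od.setdefault(ch, {})[wl] = ts[:, col].astype(float)
            if "stim1" in g:
                onsets = tuple(float(t) for t in np.asarray(g["stim1/data"])[:, 0])
            subjects.append(
                SubjectRecording(
                    label=str(side["label"]),
                    od=od,
                    gain={int(c): float(v) for c, v in side["gain"].items()},
                    cv={
                        int(c): {int(w): float(v) for w, v in by_wl.items()}
                        for c, by_wl in side["cv"].items()
                    },
                    ras=RASResponse(tuple(int(x) for x in side["ras_items"]))
                    if side.get("ras_items")
                    else None,
                )
            )
    if not onsets:
        raise MarkerMissingError(f"{path}: video-onset markers missing")
    return RawDyadRecording(
        dyad_id=str(meta.get("dyad_id", path.stem)),
        sequence_label=str(meta.get("sequence_label", "A")),
        sampling_rate=float(sampling_rate),
        subjects=(subjects[0], subjects[1]),
        video_onsets_s=onsets,
        sim_truth=meta.get("sim_truth"),
    )


def read_dyad_recording(path: Path | str, format: str | None = None) -> RawDyadRecording:
    """Read one dyad recording (CSV dialect or SNIRF, inferred from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    if format is None:
        format = "snirf" if path.suffix.lower() in (".snirf", ".h5", ".hdf5") else "csv"
    if format == "csv":
        return _read_csv_dialect(path)
    if format == "snirf":
        return read_snirf(path)
    raise FormatError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def write_cohort(recordings: Sequence[RawDyadRecording], directory: Path | str) -> Path:
    """Write every recording plus a ``cohort_manifest.tsv`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        write_dyad_recording(rec, directory / rec.dyad_id)
        truth = rec.sim_truth or {}
        rows.append(
            {
                "dyad_id": rec.dyad_id,
                "sequence": rec.sequence_label,
                "delta_sat": truth.get("delta_sat", np.nan),
                "kappa_true": truth.get("kappa", np.nan),
            }
        )
    manifest = directory / "cohort_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(directory: Path | str) -> list[RawDyadRecording]:
    """Read every ``*.csv`` dyad recording in ``directory`` (sorted by name)."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"))
    paths = [p for p in paths if p.name != "cohort_manifest.tsv"]
    if not paths:
        raise FormatError(f"{directory}: no dyad recordings found")
    return [read_dyad_recording(p) for p in paths]


def write_table(df: pd.DataFrame, path: Path | str) -> Path:
    """Write a result table as TSV (deterministic formatting)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
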