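"""On-disk formats: HDF5 stream archives, BED-like interval TSVs, JSON reports.

* Channel streams are HDF5: complex datasets ``channels`` (n_frames x
  n_pairs) and ``baseline`` (n_pairs), integer ``schedule`` (n_pairs x 2),
  with geometry/seed/noise attributes; a JSON sidecar duplicates the
  attributes for tool-free inspection.
* Interval tracks (annotations, validity masks, alert events) are BED-like
  TSVs with 0-based, half-open frame intervals, stated in the header.
* Reports are plain JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py

import pandas as pd

from .array_forward import ArrayGeometry, ChannelFrame, ChannelStream, SwitchingSchedule
from .detection import AlertEvent
from .quality import ValidityMask
from .scene import AnnotationTrack

STREAM_SCHEMA_VERSION = 1

_INTERVAL_HEADER = "# mwcolon intervals: 0-based, half-open [frame_start, frame_end)\n"


class FormatError(ValueError):
    """Archive is missing required structure or is unreadable."""


def write_stream(stream: ChannelStream, path: str | Path) -> None:
    """Persist a channel stream archive plus its JSON attribute sidecar."""
    path = Path(path)
    attrs = {
        "schema_version": STREAM_SCHEMA_VERSION,
        "n_tx": stream.geometry.n_tx,
        "n_rx": stream.geometry.n_rx,
        "ring_radius": stream.geometry.ring_radius,
        "frequency": stream.geometry.frequency,
        "noise_sigma": stream.noise_sigma,
        "seed": stream.seed,
        "background_tissue": stream.background_tissue,
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("channels", data=stream.data_matrix(), track_times=False)
        f.create_dataset("baseline", data=stream.baseline.data, track_times=False)
        f.create_dataset("schedule", data=stream.schedule.as_array(), track_times=False)
        for key, val in attrs.items():
            f.attrs[key] = val
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(attrs, indent=2, sort_keys=True) + "\n"
    )


def read_stream(path: str | Path) -> ChannelStream:
    """Load a channel stream archive; lossless complex round-trip."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open stream archive {path}: {exc}") from exc
    with f:
        version = int(f.attrs.get("schema_version", -1))
        if version != STREAM_SCHEMA_VERSION:
            raise FormatError(
                f"stream schema version {version} != supported {STREAM_SCHEMA_VERSION}"
            )
        for name in ("channels", "baseline", "schedule"):
            if name not in f:
                raise FormatError(f"stream archive missing dataset {name!r}")
        channels = f["channels"][...]
        baseline = f["baseline"][...]
        schedule = f["schedule"][...]
        geometry = ArrayGeometry(
            n_tx=int(f.attrs["n_tx"]),
            n_rx=int(f.attrs["n_rx"]),
            ring_radius=float(f.attrs["ring_radius"]),
            frequency=float(f.attrs["frequency"]),
        )
        noise_sigma = float(f.attrs["noise_sigma"])
        seed = int(f.attrs["seed"])
        background = str(f.attrs["background_tissue"])
    frames = [
        ChannelFrame(frame_idx=i, data=row) for i, row in enumerate(channels)
    ]
    return ChannelStream(
        geometry=geometry,
        schedule=SwitchingSchedule(
            pairs=tuple((int(a), int(b)) for a, b in schedule)
        ),
        frames=frames,
        baseline=ChannelFrame(frame_idx=-1, data=baseline, is_baseline=True),
        noise_sigma=noise_sigma,
        seed=seed,
        background_tissue=background,
    )


def write_intervals(intervals: list[tuple[int, int, str]], path: str | Path) -> None:
    """Write (frame_start, frame_end, label) rows as a BED-like TSV."""
    _validate_intervals(intervals)
    df = pd.DataFrame(intervals, columns=["frame_start", "frame_end", "label"])
    with open(path, "w") as fh:
        fh.write(_INTERVAL_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def read_intervals(path: str | Path) -> list[tuple[int, int, str]]:
    """Read a BED-like interval TSV; empty files yield an empty list."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    out = [
        (int(r.frame_start), int(r.frame_end), str(r.label))
        for r in df.itertuples()
    ]
    _validate_intervals(out)
    return out


def _validate_intervals(intervals: list[tuple[int, int, str]]) -> None:
    by_label: dict[str, list[tuple[int, int]]] = {}
    for start, end, label in intervals:
        if end <= start:
            raise ValueError(f"interval end {end} <= start {start}")
        by_label.setdefault(label, []).append((start, end))
    for label, ivs in by_label.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping {label!r} intervals [{s1},{e1}) and [{s2},{e2})"
                )


def annotation_to_intervals(track: AnnotationTrack) -> list[tuple[int, int, str]]:
    return [(s, e, lab) for s, e, lab in track.intervals]


def intervals_to_annotation(intervals: list[tuple[int, int, str]], n_frames: int) -> AnnotationTrack:
    return AnnotationTrack(n_frames=n_frames, intervals=tuple(sorted(intervals)))


def mask_to_intervals(mask: ValidityMask) -> list[tuple[int, int, str]]:
    """Compress a per-frame validity mask to maximal labelled intervals."""
    out: list[tuple[int, int, str]] = []
    start = 0
    flags = mask.flags
    for i in range(1, mask.n_frames + 1):
        if i == mask.n_frames or flags[i] != flags[start]:
            out.append((start, i, str(flags[start])))
            start = i
    return out


def write_events(events: list[AlertEvent], path: str | Path) -> None:
    """Write alert events as TSV plus a JSON-lines twin alongside."""
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "frame_start": ev.frame_start,
                "frame_end": ev.frame_end,
                "label": ev.label,
                "theta_peak": ev.theta_peak,
                "peak_contrast": ev.peak_contrast,
            }
            for ev in events
        ],
        columns=["frame_start", "frame_end", "label", "theta_peak", "peak_contrast"],
    )
    with open(path, "w") as fh:
        fh.write(_INTERVAL_HEADER)
        df.to_csv(fh, sep="\t", index=False)
    with open(path.with_suffix(".jsonl"), "w") as fh:
        for rec in df.to_dict(orient="records"):
            fh.write(json.dumps(rec) + "\n")


def read_events(path: str | Path) -> list[AlertEvent]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return []
    return [
        AlertEvent(
            frame_start=int(r.frame_start),
            frame_end=int(r.frame_end),
            theta_peak=float(r.theta_peak),
            peak_contrast=float(r.peak_contrast),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]


def write_map(map_, path: str | Path) -> None:
    """Persist a contrast map: datasets ``profiles`` and ``aggregate``."""
    with h5py.File(path, "w") as f:
        f.create_dataset("profiles", data=map_.profiles, track_times=False)
        f.create_dataset("aggregate", data=map_.aggregate, track_times=False)
        f.attrs["schema_version"] = STREAM_SCHEMA_VERSION


def read_map(path: str | Path):
    from .imaging import ContrastMap

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open map archive {path}: {exc}") from exc
    with f:
        for name in ("profiles", "aggregate"):
            if name not in f:
                raise FormatError(f"map archive missing dataset {name!r}")
        return ContrastMap(profiles=f["profiles"][...], aggregate=f["aggregate"][...])


def write_report(report: dict, path: str | Path) -> None:
    """Write a JSON report, dropping non-scalar entries (arrays, objects)."""
    clean = {
        k: v
        for k, v in report.items()
        if isinstance(v, (int, float, str, bool, type(None)))
    }
    Path(path).write_text(json.dumps(clean, indent=2, sort_keys=True) + "\n")
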