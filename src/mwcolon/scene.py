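"""Synthetic colon pull-back scenes: inclusions, contact events, annotations.

The longitudinal coordinate is the frame index (0-based); a frame is one
cross-sectional slice of the colon at one pull-back position.  A
:class:`SceneTimeline` describes what the antenna ring would see along a
pull-back: point-like inclusions (polyps, stool remnants) active over frame
intervals, and wall-contact events that corrupt specific channels.

Inclusions are modelled as point scatterers — extended lesions are absorbed
into the scattering ``amplitude`` — which keeps the forward model analytic.
The only structural difference between polyps and stool remnants is their
longitudinal extent: polyps persist over many consecutive frames ("wider
bright areas"), stool over few ("shorter bright areas").

All intervals are half-open ``[start, end)`` in frame units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Default longitudinal extents in frames.  Polyps are deliberately wider
#: than stool remnants with a clear margin: that width difference is the
#: detector's discriminant.
POLYP_EXTENT_RANGE = (15, 40)
STOOL_EXTENT_RANGE = (2, 6)

#: Annotation lane priority, highest first.  Contact-corrupted frames are
#: unusable regardless of content; clustered-polyp regions are excluded from
#: scoring by annotation.
LABEL_PRIORITY = ("contact", "cluster", "polyp", "stool", "healthy")


@dataclass(frozen=True)
class Inclusion:
    """A point-scatterer inclusion active over a frame interval.

    ``theta_center``/``radial_offset`` place it in the cross-section:
    the scatterer sits at radius ``lumen_radius - radial_offset`` (mm) and
    angle ``theta_center`` (radians).  ``tissue_class`` names an entry of the
    tissue table; ``amplitude`` scales its scattering strength.
    """

    kind: str  # "polyp" | "stool"
    theta_center: float
    theta_width: float
    frame_start: int
    frame_extent: int
    radial_offset: float = 2.0
    tissue_class: str = ""
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("polyp", "stool"):
            raise ValueError(f"unknown inclusion kind {self.kind!r}")
        if self.frame_extent < 1:
            raise ValueError("frame_extent must be >= 1")
        if self.theta_width <= 0:
            raise ValueError("theta_width must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if not self.tissue_class:
            object.__setattr__(self, "tissue_class", self.kind)

    @property
    def frame_end(self) -> int:
        return self.frame_start + self.frame_extent


@dataclass(frozen=True)
class ContactEvent:
    """Wall/stool contact mismatching a subset of channels over an interval.

    ``severity`` is the multiplicative magnitude distortion (> 1) applied to
    the affected channels; a random phase is added at simulation time.
    """

    frame_start: int
    frame_extent: int
    affected_channels: tuple[int, ...]
    severity: float = 10.0

    def __post_init__(self) -> None:
        if self.frame_extent < 1:
            raise ValueError("frame_extent must be >= 1")
        if len(self.affected_channels) == 0:
            raise ValueError("affected_channels must be non-empty")
        if self.severity <= 1:
            raise ValueError("severity must be > 1")

    @property
    def frame_end(self) -> int:
        return self.frame_start + self.frame_extent


@dataclass(frozen=True)
class SceneTimeline:
    """Longitudinal description of one simulated pull-back."""

    n_frames: int
    lumen_radius: float = 15.0  # mm
    background_tissue: str = "mucosa"
    inclusions: tuple[Inclusion, ...] = ()
    contacts: tuple[ContactEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        object.__setattr__(self, "inclusions", tuple(self.inclusions))
        object.__setattr__(self, "contacts", tuple(self.contacts))
        for inc in self.inclusions:
            if inc.frame_start < 0 or inc.frame_end > self.n_frames:
                raise ValueError(
                    f"inclusion interval [{inc.frame_start},{inc.frame_end}) "
                    f"outside [0,{self.n_frames})"
                )
        for ev in self.contacts:
            if ev.frame_start < 0 or ev.frame_end > self.n_frames:
                raise ValueError(
                    f"contact interval [{ev.frame_start},{ev.frame_end}) "
                    f"outside [0,{self.n_frames})"
                )


@dataclass(frozen=True)
class Scatterer:
    """One point scatterer in a cross-section: polar position, contrast, amplitude."""

    r: float  # mm from lumen axis
    theta: float  # radians
    chi: complex
    amplitude: float
    kind: str


@dataclass(frozen=True)
class AnnotationTrack:
    """Per-frame ground-truth labels stored as half-open labelled intervals.

    Intervals tile ``[0, n_frames)`` exactly; each frame carries the single
    highest-priority label that applies (contact > cluster > polyp > stool >
    healthy).
    """

    n_frames: int
    intervals: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        pos = 0
        for start, end, label in self.intervals:
            if start != pos or end <= start:
                raise ValueError(
                    f"intervals must tile [0,{self.n_frames}) contiguously; "
                    f"got [{start},{end}) at position {pos}"
                )
            if label not in LABEL_PRIORITY:
                raise ValueError(f"unknown label {label!r}")
            pos = end
        if pos != self.n_frames:
            raise ValueError(f"intervals cover [0,{pos}), expected [0,{self.n_frames})")

    def labels(self) -> np.ndarray:
        """Expand to a per-frame label array (dtype object of str)."""
        out = np.empty(self.n_frames, dtype=object)
        for start, end, label in self.intervals:
            out[start:end] = label
        return out

    def segments(self, label: str) -> list[tuple[int, int]]:
        """All maximal intervals carrying ``label``, in order."""
        return [(s, e) for s, e, lab in self.intervals if lab == label]


def _labels_to_track(labels: np.ndarray) -> AnnotationTrack:
    """Compress a per-frame label array into maximal labelled intervals."""
    n = len(labels)
    intervals: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            intervals.append((start, i, str(labels[start])))
            start = i
    return AnnotationTrack(n_frames=n, intervals=tuple(intervals))


def cross_section(
    timeline: SceneTimeline,
    frame_idx: int,
    tissues: dict[str, tuple[float, float]] | None = None,
    frequency: float | None = None,
) -> list[Scatterer]:
    """Point scatterers active in the cross-section at ``frame_idx``.

    Each inclusion whose frame interval contains ``frame_idx`` contributes one
    scatterer at radius ``lumen_radius - radial_offset`` and angle
    ``theta_center``, carrying the dielectric contrast of its tissue class
    against the background tissue.  Order follows the timeline's inclusion
    list, so output is deterministic.
    """
    from . import dielectrics as dx

    if not 0 <= frame_idx < timeline.n_frames:
        raise ValueError(
            f"frame_idx {frame_idx} outside [0,{timeline.n_frames})"
        )
    if tissues is None:
        tissues = dx.DEFAULT_TISSUES
    if frequency is None:
        frequency = dx.DEFAULT_FREQUENCY
    bg = dx.complex_permittivity(
        dx.DielectricProps(*tissues[timeline.background_tissue]), frequency
    )
    out: list[Scatterer] = []
    for inc in timeline.inclusions:
        if inc.frame_start <= frame_idx < inc.frame_end:
            eps_inc = dx.complex_permittivity(
                dx.DielectricProps(*tissues[inc.tissue_class]), frequency
            )
            out.append(
                Scatterer(
                    r=timeline.lumen_radius - inc.radial_offset,
                    theta=inc.theta_center % (2.0 * math.pi),
                    chi=dx.contrast(eps_inc, bg),
                    amplitude=inc.amplitude,
                    kind=inc.kind,
                )
            )
    return out


def ground_truth(timeline: SceneTimeline) -> AnnotationTrack:
    """Derive the per-frame annotation track from a timeline.

    Labels are assigned per frame with priority contact > cluster > polyp >
    stool > healthy.  Frames where two or more polyps overlap are labelled
    ``cluster`` (the study excluded clustered-polyp regions from scoring).
    """
    labels = np.full(timeline.n_frames, "healthy", dtype=object)
    # lowest priority first, later writes win
    for inc in timeline.inclusions:
        if inc.kind == "stool":
            labels[inc.frame_start:inc.frame_end] = "stool"
    polyp_depth = np.zeros(timeline.n_frames, dtype=int)
    for inc in timeline.inclusions:
        if inc.kind == "polyp":
            polyp_depth[inc.frame_start:inc.frame_end] += 1
    labels[polyp_depth >= 1] = "polyp"
    labels[polyp_depth >= 2] = "cluster"
    for ev in timeline.contacts:
        labels[ev.frame_start:ev.frame_end] = "contact"
    return _labels_to_track(labels)


def _random_inclusion(
    rng: np.random.Generator,
    kind: str,
    frame_start: int,
    frame_extent: int,
) -> Inclusion:
    return Inclusion(
        kind=kind,
        theta_center=float(rng.uniform(0.0, 2.0 * math.pi)),
        theta_width=float(rng.uniform(0.2, 0.6)),
        frame_start=int(frame_start),
        frame_extent=int(frame_extent),
    )


def _place_disjoint(
    rng: np.random.Generator,
    n_frames: int,
    extents: list[int],
    occupied: np.ndarray,
    max_tries: int = 10_000,
) -> list[tuple[int, int]]:
    """Place intervals of the given extents without overlapping ``occupied``.

    Mutates ``occupied`` in place.  Raises if packing fails.
    """
    placed: list[tuple[int, int]] = []
    for extent in extents:
        for _ in range(max_tries):
            start = int(rng.integers(0, n_frames - extent + 1))
            if not occupied[start:start + extent].any():
                occupied[start:start + extent] = True
                placed.append((start, extent))
                break
        else:
            raise RuntimeError(
                f"could not place an interval of extent {extent}: "
                "rates too high for n_frames"
            )
    return placed


def random_timeline(
    n_frames: int,
    polyp_rate: float = 0.0,
    stool_rate: float = 0.0,
    contact_fraction: float = 0.0,
    cluster: bool = False,
    seed: int = 0,
    contact_severity: float = 10.0,
    n_channels: int = 24,
) -> SceneTimeline:
    """Generate a random pull-back timeline with the requested event rates.

    ``polyp_rate``/``stool_rate`` are expected inclusions per frame (events
    per frame, not frame coverage).  ``contact_fraction`` is the target
    fraction of contact-corrupted *frames*; contact events are placed
    disjointly and the final event is trimmed so the realized coverage equals
    ``round(contact_fraction * n_frames)`` frames exactly.  With
    ``cluster=True`` each polyp is drawn as an overlapping pair so the
    ``cluster`` annotation path is exercised.

    Fully reproducible from ``seed``.
    """
    if polyp_rate < 0 or stool_rate < 0:
        raise ValueError("rates must be >= 0")
    if not 0.0 <= contact_fraction < 1.0:
        raise ValueError("contact_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    occupied = np.zeros(n_frames, dtype=bool)

    inclusions: list[Inclusion] = []
    n_polyps = rng.poisson(polyp_rate * n_frames)
    polyp_extents = [int(rng.integers(*POLYP_EXTENT_RANGE)) for _ in range(n_polyps)]
    for start, extent in _place_disjoint(rng, n_frames, polyp_extents, occupied):
        inclusions.append(_random_inclusion(rng, "polyp", start, extent))
        if cluster:
            # overlapping partner polyp offset by roughly half an extent
            shift = int(rng.integers(1, max(2, extent // 2)))
            p_start = min(max(0, start + shift), n_frames - extent)
            inclusions.append(_random_inclusion(rng, "polyp", p_start, extent))
            occupied[p_start:p_start + extent] = True

    n_stool = rng.poisson(stool_rate * n_frames)
    stool_extents = [int(rng.integers(*STOOL_EXTENT_RANGE)) for _ in range(n_stool)]
    for start, extent in _place_disjoint(rng, n_frames, stool_extents, occupied):
        inclusions.append(_random_inclusion(rng, "stool", start, extent))

    contacts: list[ContactEvent] = []
    target = int(round(contact_fraction * n_frames))
    if target > 0:
        contact_occupied = np.zeros(n_frames, dtype=bool)
        covered = 0
        tries = 0
        while covered < target:
            tries += 1
            if tries > 100_000:
                raise RuntimeError("could not reach requested contact_fraction")
            extent = min(int(rng.integers(2, 11)), target - covered)
            start = int(rng.integers(0, n_frames - extent + 1))
            if contact_occupied[start:start + extent].any():
                continue
            contact_occupied[start:start + extent] = True
            n_aff = int(rng.integers(2, 9))
            channels = tuple(
                int(c) for c in rng.choice(n_channels, size=n_aff, replace=False)
            )
            contacts.append(
                ContactEvent(
                    frame_start=start,
                    frame_extent=extent,
                    affected_channels=channels,
                    severity=contact_severity,
                )
            )
            covered += extent

    return SceneTimeline(
        n_frames=n_frames,
        inclusions=tuple(inclusions),
        contacts=tuple(contacts),
        seed=seed,
    )


def replica_fig3_timeline(seed: int = 0, include_stool: bool = False) -> SceneTimeline:
    """A 600-frame valid pull-back: 3 isolated polyps, 4 healthy stretches.

    Mirrors the study's valid sequence: exactly 600 frames with three isolated
    polyp segments separated (and flanked) by four healthy-mucosa segments,
    and no contact-corrupted frames.  The leading healthy stretch is at least
    60 frames so baseline estimation and threshold calibration always see a
    clean start.  Polyp positions and extents are randomized per ``seed`` but
    the segment composition is invariant.

    With ``include_stool=True`` one short stool remnant is added inside a
    healthy stretch; note that its frames are then labelled ``stool``, which
    splits that healthy segment, so the default keeps stool out.
    """
    n_frames = 600
    rng = np.random.default_rng(seed)
    extents = [int(rng.integers(*POLYP_EXTENT_RANGE)) for _ in range(3)]
    # Partition the free frames into 4 healthy gaps, each at least min_gap,
    # the first at least 60 (calibration window + margin).
    free = n_frames - sum(extents)
    min_gap = 20
    first_gap_min = 60
    slack = free - (first_gap_min + 3 * min_gap)
    cuts = np.sort(rng.integers(0, slack + 1, size=3))
    extra = [int(cuts[0]), int(cuts[1] - cuts[0]), int(cuts[2] - cuts[1]), int(slack - cuts[2])]
    gaps = [first_gap_min + extra[0]] + [min_gap + e for e in extra[1:]]

    inclusions: list[Inclusion] = []
    pos = 0
    for gap, extent in zip(gaps[:3], extents):
        pos += gap
        inclusions.append(_random_inclusion(rng, "polyp", pos, extent))
        pos += extent
    assert pos + gaps[3] == n_frames

    if include_stool:
        # drop a short remnant into the middle of the final healthy stretch
        extent = int(rng.integers(*STOOL_EXTENT_RANGE))
        start = pos + (gaps[3] - extent) // 2
        inclusions.append(_random_inclusion(rng, "stool", start, extent))

    return SceneTimeline(n_frames=n_frames, inclusions=tuple(inclusions), seed=seed)
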