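"""Antenna ring geometry, switching schedule, and Born forward model.

The acquisition device is a ring worn on the colonoscope tip carrying eight
transmitting and eight receiving antennas at uniform 45-degree spacing,
operating at 7.5 GHz.  For each transmitter the total field is measured at
the adjacent receiver and the two closest diagonal receivers, giving
8 x 3 = 24 complex channels per frame.

Each frame is treated as an independent 2-D cross-section.  Propagation in
the homogeneous mucosa background uses the 2-D scalar outgoing-wave Green's
function

    G(r) = (-j / 4) H0^(2)(k r)

(e^{+j omega t} convention, Im(k) <= 0 so |G| decays).  Scattering is
computed in the Born approximation: the received field is the deterministic
direct tx->rx coupling (the baseline) plus, for each point scatterer s,

    amplitude_s * chi_s * G(tx, s) * G(s, rx)

plus circular complex Gaussian noise.  Wall-contact events multiply the
affected channels by a severity factor with a random phase, emulating
antenna mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import hankel2

from . import dielectrics as dx
from .scene import ContactEvent, Scatterer, SceneTimeline, cross_section, ground_truth

#: Half the element spacing; the rx ring is rotated by this so no tx/rx pair
#: is co-located (a co-located pair would make the direct coupling singular).
RX_ANGLE_OFFSET = math.pi / 8.0


@dataclass(frozen=True)
class ArrayGeometry:
    """The 8+8 antenna ring.

    ``ring_radius`` defaults to 10 mm (20 mm device diameter).  Transmit
    elements sit at uniform 45-degree spacing; receive elements are
    co-indexed with the transmit elements but rotated by half the spacing,
    so rx_i lies between tx_i and tx_{i+1}.
    """

    n_tx: int = 8
    n_rx: int = 8
    ring_radius: float = 10.0  # mm
    frequency: float = dx.DEFAULT_FREQUENCY

    def __post_init__(self) -> None:
        if self.n_tx != self.n_rx:
            raise ValueError("tx and rx rings must have equal element counts")
        if self.n_tx < 3:
            raise ValueError("need at least 3 elements per ring")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def tx_angles(self) -> np.ndarray:
        return 2.0 * math.pi * np.arange(self.n_tx) / self.n_tx

    @property
    def rx_angles(self) -> np.ndarray:
        return self.tx_angles + RX_ANGLE_OFFSET * 8 / self.n_rx

    def tx_positions(self) -> np.ndarray:
        """(n_tx, 2) cartesian positions in mm."""
        a = self.tx_angles
        return self.ring_radius * np.stack([np.cos(a), np.sin(a)], axis=1)

    def rx_positions(self) -> np.ndarray:
        a = self.rx_angles
        return self.ring_radius * np.stack([np.cos(a), np.sin(a)], axis=1)


@dataclass(frozen=True)
class SwitchingSchedule:
    """Ordered (tx_index, rx_index) acquisition pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def as_array(self) -> np.ndarray:
        return np.array(self.pairs, dtype=int)


def build_schedule(geometry: ArrayGeometry) -> SwitchingSchedule:
    """The multistatic switching schedule: 3 receivers per transmitter.

    For each transmitter i in acquisition order the adjacent receiver (same
    index) is read first, then the two diagonals (i-1 and i+1, modulo the
    ring).  The default 8+8 ring yields exactly 24 pairs.
    """
    n = geometry.n_tx
    pairs = []
    for i in range(n):
        pairs.append((i, i))
        pairs.append((i, (i - 1) % n))
        pairs.append((i, (i + 1) % n))
    return SwitchingSchedule(pairs=tuple(pairs))


def greens(geometry: ArrayGeometry, k: complex, point_a: np.ndarray, point_b: np.ndarray) -> complex:
    """2-D outgoing-wave Green's function between two points (positions in mm).

    G = (-j/4) H0^(2)(k r) with r = |a - b| in metres; depends only on the
    separation, and |G| decays with r for lossy backgrounds.
    """
    r_m = float(np.linalg.norm(np.asarray(point_a) - np.asarray(point_b))) * 1e-3
    if r_m == 0.0:
        raise ValueError("Green's function singular at zero separation")
    return complex(-0.25j * hankel2(0, k * r_m))


def _greens_vec(k: complex, points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Vectorized G between row sets of mm positions: (len(a), len(b))."""
    d = np.linalg.norm(points_a[:, None, :] - points_b[None, :, :], axis=-1) * 1e-3
    if np.any(d == 0.0):
        raise ValueError("Green's function singular at zero separation")
    return -0.25j * hankel2(0, k * d)


def background_wavenumber(
    geometry: ArrayGeometry,
    background_tissue: str = "mucosa",
    tissues: dict[str, tuple[float, float]] | None = None,
) -> complex:
    """Wavenumber of the homogeneous propagation background (rad/m)."""
    if tissues is None:
        tissues = dx.DEFAULT_TISSUES
    eps = dx.complex_permittivity(
        dx.DielectricProps(*tissues[background_tissue]), geometry.frequency
    )
    return dx.wavenumber(eps)


@dataclass(frozen=True)
class ChannelFrame:
    """The 24 complex channel measurements of one frame."""

    frame_idx: int
    data: np.ndarray  # complex, length == len(schedule)
    is_baseline: bool = False

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=complex)
        if not np.all(np.isfinite(data)):
            raise ValueError("channel data must be finite")
        object.__setattr__(self, "data", data)


@dataclass
class ChannelStream:
    """An ordered sequence of channel frames plus the true baseline."""

    geometry: ArrayGeometry
    schedule: SwitchingSchedule
    frames: list[ChannelFrame]
    baseline: ChannelFrame
    noise_sigma: float
    seed: int
    background_tissue: str = "mucosa"

    def __post_init__(self) -> None:
        for i, f in enumerate(self.frames):
            if f.frame_idx != i:
                raise ValueError("frame indices must be contiguous from 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def data_matrix(self) -> np.ndarray:
        """(n_frames, n_pairs) complex channel matrix."""
        return np.stack([f.data for f in self.frames])


def compute_baseline(geometry: ArrayGeometry, schedule: SwitchingSchedule, k: complex) -> np.ndarray:
    """Deterministic direct tx->rx coupling for every schedule pair."""
    txp = geometry.tx_positions()
    rxp = geometry.rx_positions()
    g = _greens_vec(k, txp, rxp)  # (n_tx, n_rx)
    pairs = schedule.as_array()
    return g[pairs[:, 0], pairs[:, 1]]


def simulate_frame(
    geometry: ArrayGeometry,
    schedule: SwitchingSchedule,
    scatterers: list[Scatterer],
    k: complex,
    baseline: np.ndarray,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    frame_idx: int = 0,
) -> ChannelFrame:
    """Born-approximation channel data for one cross-section.

    ``noise_sigma`` is the absolute std of the circular complex Gaussian
    noise added per channel (see :func:`noise_std` for the relative default).
    Scatterers must not coincide with antenna positions.
    """
    data = baseline.astype(complex).copy()
    if scatterers:
        txp = geometry.tx_positions()
        rxp = geometry.rx_positions()
        pos = np.array(
            [[s.r * math.cos(s.theta), s.r * math.sin(s.theta)] for s in scatterers]
        )
        g_tx = _greens_vec(k, txp, pos)  # (n_tx, n_s)
        g_rx = _greens_vec(k, pos, rxp)  # (n_s, n_rx)
        w = np.array([s.amplitude * s.chi for s in scatterers])
        pairs = schedule.as_array()
        # scattered[pair] = sum_s w_s G(tx,s) G(s,rx)
        data += np.einsum(
            "ps,s,sp->p",
            g_tx[pairs[:, 0], :],
            w,
            g_rx[:, pairs[:, 1]],
        )
    if noise_sigma > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        n = len(schedule)
        data += noise_sigma * (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / math.sqrt(2)
    return ChannelFrame(frame_idx=frame_idx, data=data)


def apply_contact(frame: ChannelFrame, event: ContactEvent, rng: np.random.Generator) -> ChannelFrame:
    """Mismatch the affected channels: multiply by severity with random phase.

    Unaffected channels are returned bit-identical.
    """
    data = frame.data.copy()
    for c in event.affected_channels:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        data[c] = data[c] * event.severity * np.exp(1j * phase)
    return ChannelFrame(frame_idx=frame.frame_idx, data=data, is_baseline=frame.is_baseline)


def noise_std(baseline: np.ndarray, relative_sigma: float) -> float:
    """Absolute noise std: ``relative_sigma`` times the median |baseline|."""
    return float(relative_sigma * np.median(np.abs(baseline)))


def simulate_stream(
    timeline: SceneTimeline,
    geometry: ArrayGeometry | None = None,
    noise_sigma: float = 1e-3,
    seed: int = 0,
    tissues: dict[str, tuple[float, float]] | None = None,
):
    """Simulate the full pull-back: one channel frame per timeline frame.

    ``noise_sigma`` is relative to the median baseline magnitude (default
    1e-3).  Contact events are applied after scattering and noise.  Returns
    ``(ChannelStream, AnnotationTrack)``; fully reproducible from ``seed``.
    """
    if geometry is None:
        geometry = ArrayGeometry()
    schedule = build_schedule(geometry)
    k = background_wavenumber(geometry, timeline.background_tissue, tissues)
    baseline = compute_baseline(geometry, schedule, k)
    sigma_abs = noise_std(baseline, noise_sigma) if noise_sigma > 0 else 0.0
    rng = np.random.default_rng(seed)

    contact_by_frame: dict[int, list[ContactEvent]] = {}
    for ev in timeline.contacts:
        for f in range(ev.frame_start, ev.frame_end):
            contact_by_frame.setdefault(f, []).append(ev)

    frames: list[ChannelFrame] = []
    for f in range(timeline.n_frames):
        scat = cross_section(timeline, f, tissues=tissues, frequency=geometry.frequency)
        frame = simulate_frame(
            geometry, schedule, scat, k, baseline,
            noise_sigma=sigma_abs, rng=rng, frame_idx=f,
        )
        for ev in contact_by_frame.get(f, ()):
            frame = apply_contact(frame, ev, rng)
        frames.append(frame)

    stream = ChannelStream(
        geometry=geometry,
        schedule=schedule,
        frames=frames,
        baseline=ChannelFrame(frame_idx=-1, data=baseline, is_baseline=True),
        noise_sigma=noise_sigma,
        seed=seed,
        background_tissue=timeline.background_tissue,
    )
    return stream, ground_truth(timeline)
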