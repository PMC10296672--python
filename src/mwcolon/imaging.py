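"""Per-frame dielectric-contrast imaging and the longitudinal contrast map.

Reconstruction is matched-filter backprojection of the Born forward
operator: after subtracting an estimated per-channel baseline, the residual
d is correlated with the unit-norm steering vector of every pixel p of a
polar grid,

    I(p) = | a_p^H d | / ||a_p||,   a_p[pair] = G(tx, p) G(p, rx).

The norm matters: without it the image is weighted by ||a_p||, which decays
steeply with distance from the antenna ring in a lossy background, so the
argmax is dragged radially toward the ring regardless of where the
scatterer sits.  The unit-norm matched filter peaks at the true position.

Healthy, inclusion-free frames reconstruct to (numerically) zero
images, while a polyp produces a bright blob near its true position.  No
regularized inversion is attempted: the output is a qualitative contrast
magnitude, which is all the downstream detector needs.

A pull-back's frames are summarized into a :class:`ContrastMap`: for each
frame, the radial maximum in each angular bin (an angular profile), plus the
overall per-frame peak ("aggregated dielectric contrast").  Stacking profiles
over frames gives the longitudinal B-scan on which bright runs indicate
lesions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .array_forward import (
    ArrayGeometry,
    ChannelFrame,
    ChannelStream,
    SwitchingSchedule,
    _greens_vec,
    background_wavenumber,
)


@dataclass(frozen=True)
class PolarGrid:
    """Polar pixel grid for a cross-sectional frame.

    Radial bin centers at (i + 1/2) r_max / n_r over (0, r_max]; angular bin
    centers at (j + 1/2) 2 pi / n_theta.  ``r_max`` may exceed the ring
    radius: the wall lies outside the antenna ring.
    """

    n_r: int = 20
    n_theta: int = 64
    r_max: float = 25.0  # mm

    def __post_init__(self) -> None:
        if self.n_r < 1 or self.n_theta < 1:
            raise ValueError("n_r and n_theta must be >= 1")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.n_r) + 0.5) * self.r_max / self.n_r

    @property
    def theta_centers(self) -> np.ndarray:
        return (np.arange(self.n_theta) + 0.5) * 2.0 * math.pi / self.n_theta

    def pixel_positions(self) -> np.ndarray:
        """(n_r * n_theta, 2) cartesian mm positions, row-major (r, theta)."""
        r = self.r_centers[:, None]
        t = self.theta_centers[None, :]
        x = (r * np.cos(t)).ravel()
        y = (r * np.sin(t)).ravel()
        return np.stack([x, y], axis=1)

    def theta_bin(self, theta: float) -> int:
        return int(theta % (2.0 * math.pi) / (2.0 * math.pi) * self.n_theta) % self.n_theta


@dataclass(frozen=True)
class FrameImage:
    """Non-negative contrast-magnitude image of one frame (a.u.)."""

    frame_idx: int
    grid: PolarGrid
    pixels: np.ndarray  # (n_r, n_theta), >= 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.shape != (self.grid.n_r, self.grid.n_theta):
            raise ValueError("pixel shape does not match grid")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("pixels must be finite and non-negative")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ContrastMap:
    """Stacked angular profiles and per-frame aggregate over a pull-back."""

    profiles: np.ndarray  # (n_frames, n_theta)
    aggregate: np.ndarray  # (n_frames,), == profiles.max(axis=1)

    def __post_init__(self) -> None:
        p = np.asarray(self.profiles, dtype=float)
        a = np.asarray(self.aggregate, dtype=float)
        if p.ndim != 2 or a.shape != (p.shape[0],):
            raise ValueError("inconsistent profile/aggregate shapes")
        if p.shape[0] and not np.allclose(a, p.max(axis=1)):
            raise ValueError("aggregate must equal the per-frame profile maximum")
        object.__setattr__(self, "profiles", p)
        object.__setattr__(self, "aggregate", a)

    @property
    def n_frames(self) -> int:
        return self.profiles.shape[0]


def estimate_baseline(stream: ChannelStream, window: int = 50) -> np.ndarray:
    """Robust per-channel baseline: component-wise median over early frames.

    The first ``window`` frames are assumed to cover healthy, contact-free
    colon (an operator responsibility in practice).  Real and imaginary parts
    are medianed separately, so a minority of corrupted frames inside the
    window cannot drag the estimate.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > stream.n_frames:
        raise ValueError(
            f"window {window} exceeds stream length {stream.n_frames}"
        )
    d = stream.data_matrix()[:window]
    return np.median(d.real, axis=0) + 1j * np.median(d.imag, axis=0)


#: Pixels closer than this (mm) to any antenna are excluded from images:
#: the point-source Green's model is meaningless in the element's reactive
#: near field, and such pixels otherwise host matched-filter sidelobes.
ANTENNA_GUARD_MM = 2.0


def _adjoint_matrix(
    geometry: ArrayGeometry,
    schedule: SwitchingSchedule,
    grid: PolarGrid,
    k: complex,
    guard: float = ANTENNA_GUARD_MM,
) -> np.ndarray:
    """(n_pairs, n_pixels) two-way propagation factors G(tx,p) G(p,rx).

    Pixels within ``guard`` mm of an antenna get a zero column (excluded
    from the image rather than raising).
    """
    px = grid.pixel_positions()
    txp = geometry.tx_positions()
    rxp = geometry.rx_positions()
    d_tx = np.linalg.norm(txp[:, None, :] - px[None, :, :], axis=-1)
    d_rx = np.linalg.norm(rxp[:, None, :] - px[None, :, :], axis=-1)
    bad = (d_tx < guard).any(axis=0) | (d_rx < guard).any(axis=0)
    if ((d_tx == 0) | (d_rx == 0)).any():
        # displace coincident pixels before evaluating G, zeroed below anyway
        px = px.copy()
        px[bad] += 1e-6
    g_tx = _greens_vec(k, txp, px)  # (n_tx, n_px)
    g_rx = _greens_vec(k, rxp, px)  # (n_rx, n_px)
    pairs = schedule.as_array()
    a = g_tx[pairs[:, 0], :] * g_rx[pairs[:, 1], :]
    a[:, bad] = 0.0
    return a


class Reconstructor:
    """Caches the adjoint operator for one (geometry, schedule, grid) triple."""

    def __init__(
        self,
        geometry: ArrayGeometry,
        schedule: SwitchingSchedule,
        grid: PolarGrid,
        background_tissue: str = "mucosa",
        tissues: dict[str, tuple[float, float]] | None = None,
    ) -> None:
        self.geometry = geometry
        self.schedule = schedule
        self.grid = grid
        self.k = background_wavenumber(geometry, background_tissue, tissues)
        adj = _adjoint_matrix(geometry, schedule, grid, self.k)
        norms = np.linalg.norm(adj, axis=0)
        norms[norms == 0.0] = 1.0  # excluded (antenna-coincident) pixels
        self._adj = adj.conj()
        self._inv_norms = 1.0 / norms

    def reconstruct(self, frame: ChannelFrame, baseline: np.ndarray) -> FrameImage:
        if len(baseline) != len(self.schedule):
            raise ValueError("baseline length does not match schedule")
        residual = frame.data - baseline
        img = np.abs(residual @ self._adj) * self._inv_norms
        return FrameImage(
            frame_idx=frame.frame_idx,
            grid=self.grid,
            pixels=img.reshape(self.grid.n_r, self.grid.n_theta),
        )


def reconstruct_frame(
    frame: ChannelFrame,
    baseline: np.ndarray,
    geometry: ArrayGeometry,
    schedule: SwitchingSchedule,
    grid: PolarGrid,
    background_tissue: str = "mucosa",
    tissues: dict[str, tuple[float, float]] | None = None,
) -> FrameImage:
    """Adjoint backprojection of one frame's baseline-subtracted residual."""
    rec = Reconstructor(geometry, schedule, grid, background_tissue, tissues)
    return rec.reconstruct(frame, baseline)


def aggregate_frame(image: FrameImage) -> tuple[np.ndarray, float]:
    """Angular profile (radial max per angular bin) and its overall peak."""
    profile = image.pixels.max(axis=0)
    return profile, float(profile.max())


def build_contrast_map(
    stream: ChannelStream,
    baseline: np.ndarray,
    grid: PolarGrid,
    tissues: dict[str, tuple[float, float]] | None = None,
) -> ContrastMap:
    """Reconstruct and aggregate every frame of a stream, order-preserving."""
    rec = Reconstructor(
        stream.geometry, stream.schedule, grid, stream.background_tissue, tissues
    )
    profiles = np.empty((stream.n_frames, grid.n_theta))
    for i, frame in enumerate(stream.frames):
        profile, _ = aggregate_frame(rec.reconstruct(frame, baseline))
        profiles[i] = profile
    return ContrastMap(profiles=profiles, aggregate=profiles.max(axis=1) if stream.n_frames else np.empty(0))


def render_map_png(map_: ContrastMap, path: str) -> None:
    """Render the B-scan heatmap (frames on x, angle on y) to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    im = ax.imshow(
        map_.profiles.T,
        aspect="auto",
        origin="lower",
        cmap="viridis",
        interpolation="nearest",
    )
    ax.set_xlabel("frame")
    ax.set_ylabel("angular bin")
    fig.colorbar(im, ax=ax, label="contrast (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
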