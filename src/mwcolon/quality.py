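"""Frame-validity classification: detecting contact-mismatched frames.

When the antenna ring touches the colon wall or stool, the affected antennas
are mismatched and their channels no longer resemble the calibration
baseline.  Such frames are not usable for imaging and must be discarded.

The classifier is a per-channel relative-deviation count: channel c of a
frame is "deviant" when

    |data_c - baseline_c| / |baseline_c| > tau_chan

and the frame's mismatch score is the number of deviant channels.  A frame
is invalid when the score reaches ``m_min``.  A count (rather than a norm)
is used because contact corrupts *specific* antennas; a single large polyp
echo on one channel must not invalidate a frame, and the defaults
(tau_chan = 0.5, m_min = 2) leave simulated polyp echoes far below the
deviation threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .array_forward import ChannelStream

logger = logging.getLogger(__name__)

VALID = "valid"
INVALID_CONTACT = "invalid_contact"


@dataclass(frozen=True)
class ValidityMask:
    """Per-frame validity flags and mismatch scores."""

    flags: np.ndarray  # object array of {"valid", "invalid_contact"}
    scores: np.ndarray  # int >= 0

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=object)
        scores = np.asarray(self.scores, dtype=int)
        if flags.shape != scores.shape:
            raise ValueError("flags and scores must have equal length")
        if np.any(scores < 0):
            raise ValueError("scores must be >= 0")
        object.__setattr__(self, "flags", flags)
        object.__setattr__(self, "scores", scores)

    @property
    def n_frames(self) -> int:
        return len(self.flags)

    @property
    def valid(self) -> np.ndarray:
        return self.flags == VALID


def mismatch_score(
    frame_data: np.ndarray, baseline: np.ndarray, tau_chan: float = 0.5
) -> int:
    """Count channels whose relative deviation from baseline exceeds tau_chan.

    Channels with a zero baseline cannot be normalized and are excluded from
    the count (with a warning).
    """
    data = np.asarray(frame_data)
    base = np.asarray(baseline)
    if data.shape != base.shape:
        raise ValueError("frame and baseline lengths differ")
    mag = np.abs(base)
    ok = mag > 0
    if not ok.all():
        logger.warning(
            "excluding %d zero-baseline channel(s) from mismatch score",
            int((~ok).sum()),
        )
    e = np.abs(data[ok] - base[ok]) / mag[ok]
    return int(np.count_nonzero(e > tau_chan))


def classify_validity(
    stream: ChannelStream,
    baseline: np.ndarray,
    tau_chan: float = 0.5,
    m_min: int = 2,
) -> ValidityMask:
    """Flag each frame valid/invalid by thresholding its mismatch score."""
    if m_min < 1:
        raise ValueError("m_min must be >= 1")
    scores = np.array(
        [mismatch_score(f.data, baseline, tau_chan) for f in stream.frames], dtype=int
    )
    flags = np.where(scores >= m_min, INVALID_CONTACT, VALID).astype(object)
    return ValidityMask(flags=flags, scores=scores)


def validity_summary(mask: ValidityMask) -> dict:
    """Counts and invalid fraction for a validity mask."""
    if mask.n_frames == 0:
        raise ValueError("empty validity mask")
    n_invalid = int(np.count_nonzero(~mask.valid))
    return {
        "n_frames": int(mask.n_frames),
        "n_invalid": n_invalid,
        "invalid_fraction": n_invalid / mask.n_frames,
    }
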