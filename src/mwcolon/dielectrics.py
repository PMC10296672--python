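"""Complex permittivity, dielectric contrast, and background wavenumber.

Microwave polyp detection rests on one physical premise: neoplastic tissue
differs from healthy mucosa in its dielectric properties (relative
permittivity ``eps_r`` and conductivity ``sigma``).  At a single operating
frequency these combine into a complex relative permittivity

    eps*(f) = eps_r - j * sigma / (2 pi f eps0)

using the e^{+j omega t} time convention, so losses carry a *negative*
imaginary part.  The imaged quantity is the relative contrast between an
inclusion (polyp, stool) and the mucosa background,

    chi = (eps*_inc - eps*_bg) / eps*_bg

and wave propagation through the background is governed by the complex
wavenumber k = (2 pi f / c) sqrt(eps*_bg), taken on the branch with
Im(k) <= 0 (outgoing, decaying waves).

All modules in this package share the e^{+j omega t} convention.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
C0 = 299792458.0  # speed of light, m/s

#: Default tissue table.  These are plausible high-water-content soft-tissue
#: values at 7.5 GHz chosen to give a clear polyp/mucosa contrast; they are
#: configurable and not measured values.
DEFAULT_TISSUES = {
    "mucosa": (50.0, 6.0),
    "polyp": (60.0, 8.0),
    "stool": (40.0, 4.0),
}

DEFAULT_FREQUENCY = 7.5e9  # Hz, single-frequency device


@dataclass(frozen=True)
class DielectricProps:
    """Real dielectric properties of a tissue class.

    Parameters
    ----------
    eps_r : float
        Relative permittivity (dimensionless, >= 1).
    sigma : float
        Conductivity in S/m (>= 0).
    """

    eps_r: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.eps_r >= 1.0:
            raise ValueError(f"eps_r must be >= 1, got {self.eps_r}")
        if not self.sigma >= 0.0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class ComplexPermittivity:
    """Complex relative permittivity at a fixed frequency.

    Invariants: real part >= 1, imaginary part <= 0 (lossy, e^{+j omega t}).
    """

    value: complex
    frequency: float

    def __post_init__(self) -> None:
        if self.value.real < 1.0:
            raise ValueError(f"Re(eps*) must be >= 1, got {self.value.real}")
        if self.value.imag > 0.0:
            raise ValueError(
                f"Im(eps*) must be <= 0 under e^{{+j omega t}}, got {self.value.imag}"
            )
        if not self.frequency > 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")


def complex_permittivity(props: DielectricProps, frequency: float) -> ComplexPermittivity:
    """Evaluate eps* = eps_r - j sigma / (2 pi f eps0) at ``frequency`` Hz."""
    if not frequency > 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    loss = props.sigma / (2.0 * math.pi * frequency * EPS0)
    return ComplexPermittivity(complex(props.eps_r, -loss), frequency)


def contrast(inclusion: ComplexPermittivity, background: ComplexPermittivity) -> complex:
    """Relative dielectric contrast chi = (eps*_inc - eps*_bg) / eps*_bg.

    Both permittivities must be evaluated at the same frequency.  chi == 0
    exactly when the inclusion matches the background.
    """
    if inclusion.frequency != background.frequency:
        raise ValueError(
            "frequency mismatch: "
            f"{inclusion.frequency} Hz vs {background.frequency} Hz"
        )
    return (inclusion.value - background.value) / background.value


def wavenumber(background: ComplexPermittivity) -> complex:
    """Complex background wavenumber k = (2 pi f / c) sqrt(eps*), rad/m.

    The square-root branch is chosen so Im(k) <= 0, i.e. outgoing waves decay
    with distance.
    """
    k = (2.0 * math.pi * background.frequency / C0) * cmath.sqrt(background.value)
    if k.imag > 0:
        k = -k
    return k
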