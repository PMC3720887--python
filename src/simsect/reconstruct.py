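"""Square-law demodulation of three phase-shifted frames.

With frames I_i = A + B cos(theta + phi_i), phi = (0, 2pi/3, 4pi/3),
the sum of squared pairwise differences is (9/2) B^2 independently of
theta, so

    I_sectioned = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I1-I3)^2 + (I2-I3)^2)

recovers exactly the modulated (in-focus) amplitude B = m_eff f / 2,
while the phase average

    I_widefield = (I1 + I2 + I3) / 3

cancels the modulation and returns the conventional uniform image
A = d/2 + f/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import PhaseTriplet

__all__ = ["SectionedImage", "WidefieldImage", "sectioned_image", "widefield_image"]


@dataclass(frozen=True)
class SectionedImage:
    pixels: np.ndarray
    source: dict = field(default_factory=dict)


@dataclass(frozen=True)
class WidefieldImage:
    pixels: np.ndarray
    source: dict = field(default_factory=dict)


def _frames(triplet: PhaseTriplet):
    i1, i2, i3 = (np.asarray(f, dtype=float) for f in triplet.frames)
    return i1, i2, i3


def sectioned_image(triplet: PhaseTriplet) -> SectionedImage:
    """Optically sectioned image by square-law detection.

    Non-negative, invariant under cyclic frame relabeling and under
    adding any common image to all three frames; computed in floating
    point regardless of the input bit depth.
    """
    i1, i2, i3 = _frames(triplet)
    pixels = (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i1 - i3) ** 2 + (i2 - i3) ** 2
    )
    return SectionedImage(pixels=pixels, source=dict(triplet.provenance))


def widefield_image(triplet: PhaseTriplet) -> WidefieldImage:
    """Conventional (uniform-illumination) image: the phase average."""
    i1, i2, i3 = _frames(triplet)
    return WidefieldImage(pixels=(i1 + i2 + i3) / 3.0,
                          source=dict(triplet.provenance))
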