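"""Orientation arithmetic and the cosine-power channel basis.

Orientations live on a 180°-periodic space: a bar tilted 135° clockwise is
indistinguishable from one tilted -45°.  All public functions take and
return degrees; the canonical interval is ``(-90, 90]`` with 0° vertical
and positive angles clockwise.

The channel basis models the population response of orientation-selective
neurons as a half-wave-rectified cosine raised to a power (default 7),
evaluated on the wrapped orientation difference so responses are always
non-negative.  Six channels centered on ±15°, ±45° and ±75° span the
space used throughout the decoding pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_CHANNEL_CENTERS",
    "ChannelBasis",
    "wrap_orientation",
    "orientation_difference",
    "channel_response",
    "channel_response_matrix",
]

#: Preferred orientations of the six default channels, matching the six
#: uniform stimulus orientations (degrees).
DEFAULT_CHANNEL_CENTERS: tuple[float, ...] = (75.0, 45.0, 15.0, -15.0, -45.0, -75.0)


def wrap_orientation(angle):
    """Wrap an angle (degrees) into the canonical interval ``(-90, 90]``.

    Accepts scalars or arrays; returns the same shape.  The map is the
    quotient onto the 180°-periodic orientation space: ``wrap(a + 180) ==
    wrap(a)`` for every finite ``a``.

    Raises
    ------
    ValueError
        If any input value is NaN or infinite.
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("orientation angles must be finite")
    wrapped = 90.0 - np.mod(90.0 - a, 180.0)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def orientation_difference(a, b):
    """Signed wrapped difference ``a - b`` in degrees, in ``(-90, 90]``."""
    return wrap_orientation(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def channel_response(theta, theta_max, exponent: int = 7):
    """Response of an orientation channel tuned to ``theta_max``.

    The tuning function is ``cos(theta - theta_max) ** exponent`` with the
    difference wrapped into ``(-90, 90]``, so the response lies in
    ``[0, 1]``: 1 at the preferred orientation, 0 at ±90° away.

    Parameters
    ----------
    theta : scalar or array of degrees
        Stimulus orientation(s) presented to the channel.
    theta_max : scalar or array of degrees
        Preferred orientation(s) of the channel.
    exponent : int
        Power applied to the cosine; larger values narrow the tuning.
    """
    if not (isinstance(exponent, (int, np.integer)) and exponent >= 1):
        raise ValueError(f"exponent must be a positive integer, got {exponent!r}")
    d = orientation_difference(theta, theta_max)
    return np.cos(np.deg2rad(d)) ** exponent


@dataclass(frozen=True)
class ChannelBasis:
    """A bank of ``k`` orientation channels with a shared tuning exponent.

    Attributes
    ----------
    centers : tuple of float
        Preferred orientations in degrees, pairwise distinct after
        wrapping into ``(-90, 90]``.
    exponent : int
        Tuning-curve exponent shared by all channels.
    """

    centers: tuple[float, ...] = DEFAULT_CHANNEL_CENTERS
    exponent: int = 7

    def __post_init__(self):
        wrapped = tuple(wrap_orientation(c) for c in self.centers)
        if len(set(wrapped)) != len(wrapped):
            raise ValueError("channel centers must be pairwise distinct after wrapping")
        if not (isinstance(self.exponent, (int, np.integer)) and self.exponent >= 1):
            raise ValueError("exponent must be a positive integer")
        object.__setattr__(self, "centers", tuple(float(c) for c in self.centers))

    @property
    def k(self) -> int:
        """Number of channels."""
        return len(self.centers)

    def response(self, theta) -> np.ndarray:
        """Channel response vector(s) to orientation(s) ``theta``.

        For scalar ``theta`` returns shape ``(k,)``; for an array of n
        orientations returns shape ``(k, n)``.
        """
        theta = np.asarray(theta, dtype=float)
        centers = np.asarray(self.centers)
        if theta.ndim == 0:
            return channel_response(theta, centers, self.exponent)
        return channel_response(theta[None, :], centers[:, None], self.exponent)


def channel_response_matrix(orientations_per_condition: Sequence, basis: ChannelBasis) -> np.ndarray:
    """Build the ``k x n`` channel-response matrix ``C`` for n conditions.

    Each condition is either a single orientation (a scalar) or a sequence
    of element orientations; for multi-element conditions the column is
    the mean channel response over the elements.  The mean convention is
    used only by the synthetic generator's forward drive -- the encoding
    model itself is always fit with single-orientation columns.
    """
    conditions = list(orientations_per_condition)
    if len(conditions) == 0:
        raise ValueError("at least one condition is required")
    cols = []
    for cond in conditions:
        elems = np.atleast_1d(np.asarray(cond, dtype=float))
        if elems.size == 0:
            raise ValueError("conditions must contain at least one orientation")
        cols.append(basis.response(elems).mean(axis=1))
    return np.column_stack(cols)
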