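"""Angle conventions and wrapping helpers.

All angles are in degrees.  Yaw (and azimuths generally) are measured from
the +x axis, positive **clockwise** when viewed from above (z up), so that a
positive relative azimuth lies to the listener's right.  Wrapped angles live
in the half-open interval (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "heading_vector", "absolute_azimuth", "mirror_front_back"]


def wrap_deg(angle):
    """Wrap an angle (or array of angles) into (-180, 180] degrees."""
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


def heading_vector(yaw_deg: float) -> np.ndarray:
    """Unit horizontal heading (x, y) for a yaw angle."""
    r = np.deg2rad(yaw_deg)
    return np.array([np.cos(r), -np.sin(r)])


def absolute_azimuth(dx: float, dy: float) -> float:
    """World-frame azimuth of the horizontal offset (dx, dy).

    0 points along +x; positive azimuths rotate toward -y (clockwise from
    above, i.e. to the right of a listener facing +x).
    """
    return float(wrap_deg(-np.degrees(np.arctan2(dy, dx))))


def mirror_front_back(az_deg: float) -> float:
    """Reflect an azimuth about the interaural (left-right) axis.

    Sources ahead map behind and vice versa while left/right is preserved:
    +30 -> +150, -10 -> -170, 0 -> 180.
    """
    az = float(wrap_deg(az_deg))
    if az >= 0.0:
        return float(wrap_deg(180.0 - az))
    return float(wrap_deg(-180.0 - az))
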