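"""Euler-angle conventions shared by the forward model and the refinement.

Orientations use ZYZ Euler angles ``(rot, tilt, psi)`` in degrees:
``R = Rz(psi) @ Ry(tilt) @ Rz(rot)`` maps body (lattice) coordinates to
image coordinates.  The projection integrates along image z, and image
components (x, y) map to array axes (0, 1).  A filament built along the
body z axis therefore appears edge-on along image axis 0 at
``tilt = 90°, psi = 0``; ``psi`` is the in-plane angle (from axis 0
toward axis 1) and ``rot`` the azimuthal view around the filament axis.
"""

from __future__ import annotations

import numpy as np


def rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ rotation, body -> image frame (degrees)."""
    return rot_z(psi) @ rot_y(tilt) @ rot_z(rot)
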