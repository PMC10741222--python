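"""Approximate spherical 10-20/10-10 electrode positions.

Angles follow the BESA spherical convention: ``theta`` is the inclination
from the vertex (negative = left hemisphere), ``phi`` the azimuth in the
horizontal plane. Positions are unit vectors on a sphere — adequate for
spherical-spline interpolation and for generating spatially smooth
synthetic topographies, not for source analysis.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["SPHERICAL_ANGLES", "channel_positions", "DEFAULT_MONTAGE_32"]

# label -> (theta, phi) in degrees
SPHERICAL_ANGLES: dict[str, tuple[float, float]] = {
    "Fp1": (-92, -72), "Fp2": (92, 72), "Fpz": (92, 90),
    "F7": (-92, -36), "F3": (-60, -51), "Fz": (46, 90), "F4": (60, 51), "F8": (92, 36),
    "FC5": (-69, -21), "FC1": (-31, -46), "FC2": (31, 46), "FC6": (69, 21),
    "FT9": (-113, -18), "FT10": (113, 18),
    "T7": (-92, 0), "C3": (-45, 0), "Cz": (0, 0), "C4": (45, 0), "T8": (92, 0),
    "TP9": (-113, 18), "TP10": (113, -18),
    "CP5": (-69, 21), "CP1": (-31, 46), "CP2": (31, -46), "CP6": (69, -21),
    "P7": (-92, 36), "P3": (-60, 51), "Pz": (46, -90), "P4": (60, -51), "P8": (92, -36),
    "POz": (69, -90),
    "O1": (-92, 72), "Oz": (92, -90), "O2": (92, -72),
}

#: 31 scalp labels + ECG, BrainAmp-style cap layout.
DEFAULT_MONTAGE_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "FT9", "FT10",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "TP10",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2", "ECG",
]


def channel_positions(ch_names) -> np.ndarray:
    """Unit-sphere 3-D positions for the given scalp labels."""
    pos = np.empty((len(ch_names), 3))
    for i, name in enumerate(ch_names):
        key = next((k for k in SPHERICAL_ANGLES if k.lower() == name.lower()), None)
        if key is None:
            raise KeyError(f"no montage position for channel {name!r}")
        theta, phi = SPHERICAL_ANGLES[key]
        th, ph = math.radians(theta), math.radians(phi)
        pos[i] = (math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th))
    return pos
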