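"""Approximate cEEGrid electrode geometry on the unit sphere.

The cEEGrid is a C-shaped flex-printed array of ten Ag/AgCl electrodes
placed around each ear, opening towards the face.  One right-grid electrode
pair serves as reference/ground, leaving 18 recorded channels.  Exact
per-subject electrode coordinates are never published for this montage, so
the positions here are idealized: each grid's electrodes lie on a small
circle (about 15 degrees angular radius) around the ear direction, spanning
a 240-degree arc with electrodes 1-3 above the ear and 6-8 below.  Only the
relative geometry matters: spherical-spline interpolation and the
simulated vertical amplitude gradient both depend on positions only through
smooth functions of inter-electrode angles.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CEEGRID_CHANNELS", "ceegrid_positions", "vertical_loadings"]

#: Recorded channels: full left grid, right grid minus the reference/ground
#: pair at position 4.
CEEGRID_CHANNELS: tuple[str, ...] = (
    "L1", "L2", "L3", "L4a", "L4b", "L5", "L6", "L7", "L8", "L9", "L10",
    "R1", "R2", "R3", "R5", "R6", "R7", "R8", "R9",
)

# within-grid slot order along the C, top-front to bottom-front
_SLOTS = ["1", "2", "3", "4a", "4b", "5", "6", "7", "8", "9", "10"]


def _grid(side: str) -> dict[str, np.ndarray]:
    az = np.deg2rad(-100.0 if side == "L" else 100.0)
    center = np.array([np.cos(az), np.sin(az), 0.0])
    up = np.array([0.0, 0.0, 1.0])
    u = np.cross(up, center)
    u /= np.linalg.norm(u)
    v = np.cross(center, u)
    r = np.deg2rad(15.0)
    # arc from +120 deg (top) sweeping behind the ear down to -120 deg
    angles = np.deg2rad(np.linspace(120.0, -120.0, len(_SLOTS)))
    out = {}
    for slot, phi in zip(_SLOTS, angles):
        p = np.cos(r) * center + np.sin(r) * (np.cos(phi) * u + np.sin(phi) * v)
        out[f"{side}{slot}"] = p / np.linalg.norm(p)
    return out


def ceegrid_positions(labels: tuple[str, ...] | list[str] = CEEGRID_CHANNELS):
    """Unit-sphere coordinates (label -> xyz) for the requested channels."""
    table = {**_grid("L"), **_grid("R")}
    missing = [lab for lab in labels if lab not in table]
    if missing:
        raise KeyError(f"unknown cEEGrid labels: {missing}")
    return {lab: table[lab] for lab in labels}


def vertical_loadings(labels: tuple[str, ...] | list[str] = CEEGRID_CHANNELS):
    """Per-channel spatial loadings of the simulated ERP source.

    A linear gradient in each electrode's vertical (z) coordinate,
    normalized so that mean(R2, R3) - mean(R6, R7) = 1.  Upper channels
    therefore load positively and lower channels negatively, and the
    vertical bipolar cEEGrid derivation recovers the source waveform at
    unit gain.
    """
    table = {**_grid("L"), **_grid("R")}
    top = 0.5 * (table["R2"][2] + table["R3"][2])
    bottom = 0.5 * (table["R6"][2] + table["R7"][2])
    mid, span = 0.5 * (top + bottom), top - bottom
    pos = ceegrid_positions(labels)
    return {lab: (p[2] - mid) / span for lab, p in pos.items()}
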