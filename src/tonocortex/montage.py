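"""Idealized 10/10 electrode montage on the unit sphere.

Positions are generated from the standard extended 10/20 naming grid: each
label maps to a front-back angle (row) and a lateral angle (column), both in
multiples of 18 degrees (10% of the nasion-inion arc), which are combined
into a direction on the unit sphere with Cz at the vertex.  This is a
synthetic, idealized geometry — adequate for simulation, scalp-spline
interpolation and topography construction, not a digitized head shape.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

# row -> front(+)/back(-) angle in units of 18 deg
_ROW_STEP = {
    "Fp": +4, "AF": +3, "F": +2, "FC": +1, "FT": +1, "C": 0, "T": 0,
    "CP": -1, "TP": -1, "P": -2, "PO": -3, "O": -4, "I": -5,
}

# 64-channel cap layout (Easycap-style): 61 grid positions + Iz + TP9/TP10
MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "Iz",
)

# channel excluded from analysis (64 recorded -> 63 analyzed)
EXCLUDED_CHANNEL = "Iz"

# compact 16-channel subset for fast test profiles (keeps the fronto-central
# and temporal sites the auditory response lives on)
MONTAGE_16: tuple[str, ...] = (
    "Fz", "FCz", "Cz", "CPz", "Pz", "F3", "F4", "FC3", "FC4",
    "C3", "C4", "CP3", "CP4", "T7", "T8", "Oz",
)


def _parse_label(label: str) -> tuple[int, int]:
    """Split an electrode label into (row_step, signed_lateral_step).

    Lateral steps are in units of 18 deg, negative = left.  Odd numbers are
    left hemisphere, even right; 'z' is midline.  9/10 suffixes (e.g. TP9)
    sit one step below the 10/20 circumference ring.
    """
    i = 0
    while i < len(label) and not (label[i].isdigit() or label[i] == "z"):
        i += 1
    row, col = label[:i], label[i:]
    if row not in _ROW_STEP:
        raise ValueError(f"unrecognized electrode label {label!r}")
    if col == "z":
        lat = 0
    else:
        num = int(col)
        side = -1 if num % 2 == 1 else 1
        # 1/2 -> 1 step, 3/4 -> 2, 5/6 -> 3, 7/8 -> 4, 9/10 -> 5
        lat = side * ((num + 1) // 2)
    # T7/T8 are the C-row 7/8 positions under 10/10 naming
    if row == "T":
        lat = -4 if col in ("7", "9") else 4
        if col in ("9", "10"):
            lat = int(np.sign(lat)) * 5
    if row in ("FT", "TP") and col in ("7", "8", "9", "10"):
        lat = (-1 if col in ("7", "9") else 1) * (4 if col in ("7", "8") else 5)
    return _ROW_STEP[row], lat


def electrode_position(label: str) -> np.ndarray:
    """Unit-sphere (x, y, z) for a 10/10 label; +x right, +y nasion, +z vertex."""
    row_step, lat_step = _parse_label(label)
    ang_y = np.deg2rad(18.0 * row_step)   # toward nasion
    ang_x = np.deg2rad(18.0 * lat_step)   # toward right ear
    v = np.array([ang_x, ang_y])
    rho = np.linalg.norm(v)
    if rho == 0:
        return np.array([0.0, 0.0, 1.0])
    direction = v / rho
    return np.array([np.sin(rho) * direction[0],
                     np.sin(rho) * direction[1],
                     np.cos(rho)])


def montage_positions(labels: tuple[str, ...] | list[str] = MONTAGE_64) -> pd.DataFrame:
    """DataFrame indexed by label with unit-sphere x, y, z columns."""
    pos = np.array([electrode_position(l) for l in labels])
    return pd.DataFrame(pos, index=list(labels), columns=["x", "y", "z"])


def analysis_channels(labels: tuple[str, ...] = MONTAGE_64,
                      excluded: str = EXCLUDED_CHANNEL) -> list[str]:
    """The recorded montage minus the designated excluded channel."""
    return [l for l in labels if l != excluded]


def default_channels(n_channels: int = 63) -> list[str]:
    """Canonical channel list for a requested montage size.

    63 = full analysis montage; 16 = fast test subset; other sizes take the
    first n analysis channels but always retain Cz, FCz, T7 and T8 so the
    auditory topography stays representable.
    """
    full = analysis_channels()
    if n_channels >= len(full):
        return full
    if n_channels == len(MONTAGE_16):
        return list(MONTAGE_16)
    keep = [l for l in ("Cz", "FCz", "T7", "T8") if l in full]
    rest = [l for l in full if l not in keep]
    if n_channels < len(keep):
        raise ValueError("montage too small to represent the auditory topography")
    return sorted(keep + rest[: n_channels - len(keep)], key=full.index)


def montage_to_csv(path: str | Path,
                   labels: tuple[str, ...] | list[str] = MONTAGE_64) -> None:
    """Write ``label,x,y,z`` unit-sphere coordinates."""
    df = montage_positions(labels).rename_axis("label").reset_index()
    df.to_csv(path, index=False)


def montage_from_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"label", "x", "y", "z"}.issubset(df.columns):
        raise ValueError("montage CSV must have columns label,x,y,z")
    return df.set_index("label")[["x", "y", "z"]]
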