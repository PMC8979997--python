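"""RELION-style STAR export/import of per-image Euler angles.

Column mapping (documented, not asserted to match RELION's internal sign
conventions): our ZYZ (alpha, beta, gamma) in degrees are written as
``rlnAngleRot``, ``rlnAngleTilt``, ``rlnAnglePsi`` in that order, one row per
image, in a ``data_particles`` loop block.  Only this block and these columns
are parsed back.
"""

from __future__ import annotations

import numpy as np

from .geometry import OrientationSet

__all__ = ["write_star", "read_star"]

_COLUMNS = ("rlnImageName", "rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")


def write_star(path, orientations: OrientationSet, stack_name: str = "stack.mrcs") -> None:
    deg = np.degrees(orientations.angles)
    lines = ["", "data_particles", "", "loop_"]
    lines += [f"_{c} #{i + 1}" for i, c in enumerate(_COLUMNS)]
    for i, (a, b, g) in enumerate(deg):
        lines.append(f"{i + 1:06d}@{stack_name} {a:12.6f} {b:12.6f} {g:12.6f}")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_star(path) -> OrientationSet:
    labels: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                in_loop = False
                labels, rows = [], rows
                continue
            if line == "loop_":
                in_loop = True
                labels = []
                continue
            if in_loop and line.startswith("_"):
                labels.append(line.split()[0].lstrip("_"))
                continue
            if in_loop and labels:
                rows.append(line.split())
    needed = ("rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")
    try:
        idx = [labels.index(c) for c in needed]
    except ValueError as err:
        raise ValueError(f"STAR file {path} lacks Euler angle columns") from err
    ang = np.array([[float(r[j]) for j in idx] for r in rows])
    return OrientationSet(np.radians(ang))
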