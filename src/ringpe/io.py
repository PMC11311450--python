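"""Trajectory text formats: extended XYZ and a LAMMPS-dump-style dialect.

Both dialects carry, per particle, a species label (or numeric type),
coordinates and the charge, and round-trip through
:func:`write_trajectory` / :func:`read_trajectory` exactly on species
and charges and to float precision on coordinates.  Dump frames with
shuffled atom ids are re-sorted by id on read.
"""

from __future__ import annotations

import shlex
from pathlib import Path

import numpy as np

from .dynamics import Trajectory

SPECIES_TO_TYPE = {"M": 1, "CI": 2, "SC": 3, "SA": 4}
TYPE_TO_SPECIES = {v: k for k, v in SPECIES_TO_TYPE.items()}


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; message carries the line number."""


def _fmt_meta(meta: dict) -> str:
    parts = []
    for k, v in meta.items():
        s = str(v)
        parts.append(f'{k}="{s}"' if " " in s else f"{k}={s}")
    return " ".join(parts)


def _parse_meta(comment: str) -> dict:
    meta = {}
    for tok in shlex.split(comment):
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def write_xyz(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write(f"{len(frame)}\n")
            meta = {"step": t, "box": traj.box_length,
                    "n_monomer": traj.n_monomer, **traj.meta}
            fh.write(_fmt_meta(meta) + "\n")
            for s, p, q in zip(traj.species, frame, traj.charges):
                fh.write(f"{s} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f} {int(q)}\n")
    return path


def read_xyz(path: str | Path) -> Trajectory:
    path = Path(path)
    frames, times = [], []
    species = charges = None
    meta: dict = {}
    box = 0.0
    n_monomer = 0
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"line {ln + 1}: expected particle count, got {lines[ln]!r}") from exc
        if ln + 1 + n >= len(lines) + 1:
            raise TrajectoryParseError(f"line {ln + 1}: truncated frame of {n} atoms")
        frame_meta = _parse_meta(lines[ln + 1])
        box = float(frame_meta.pop("box", box))
        n_monomer = int(frame_meta.pop("n_monomer", n_monomer))
        step = int(float(frame_meta.pop("step", len(frames))))
        meta.update(frame_meta)
        sp, pos, q = [], [], []
        for m in range(n):
            toks = lines[ln + 2 + m].split()
            if len(toks) < 4:
                raise TrajectoryParseError(
                    f"line {ln + 3 + m}: expected 'species x y z [charge]'")
            sp.append(toks[0])
            pos.append([float(toks[1]), float(toks[2]), float(toks[3])])
            q.append(float(toks[4]) if len(toks) > 4 else 0.0)
        frames.append(np.array(pos))
        times.append(step)
        species = np.array(sp)
        charges = np.array(q)
        ln += 2 + n
    if not frames:
        raise TrajectoryParseError("line 1: file contains no frames")
    return Trajectory(frames, times, charges, species, n_monomer, box, meta=meta)


def write_dump(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    L = traj.box_length
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{t}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{len(frame)}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0.0 {L:.8f}\n")
            fh.write("ITEM: ATOMS id type q x y z\n")
            for idx, (s, p, q) in enumerate(zip(traj.species, frame, traj.charges)):
                typ = SPECIES_TO_TYPE.get(str(s), 0)
                fh.write(f"{idx + 1} {typ} {int(q)} "
                         f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")
    return path


def read_dump(path: str | Path) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    frames, times = [], []
    species = charges = None
    box = 0.0
    ln = 0

    def expect(tag: str) -> None:
        nonlocal ln
        if ln >= len(lines) or not lines[ln].startswith(tag):
            raise TrajectoryParseError(f"line {ln + 1}: expected '{tag}'")
        ln += 1

    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        expect("ITEM: TIMESTEP")
        times.append(int(lines[ln].strip()))
        ln += 1
        expect("ITEM: NUMBER OF ATOMS")
        n = int(lines[ln].strip())
        ln += 1
        expect("ITEM: BOX BOUNDS")
        bounds = []
        for _ in range(3):
            toks = lines[ln].split()
            bounds.append(float(toks[1]) - float(toks[0]))
            ln += 1
        box = bounds[0]
        if not lines[ln].startswith("ITEM: ATOMS"):
            raise TrajectoryParseError(f"line {ln + 1}: expected 'ITEM: ATOMS'")
        cols = lines[ln].split()[2:]
        try:
            c_id, c_type, c_q = cols.index("id"), cols.index("type"), cols.index("q")
            c_x, c_y, c_z = cols.index("x"), cols.index("y"), cols.index("z")
        except ValueError as exc:
            raise TrajectoryParseError(
                f"line {ln + 1}: dump needs columns id type q x y z") from exc
        ln += 1
        rows = []
        for m in range(n):
            toks = lines[ln + m].split()
            if len(toks) < len(cols):
                raise TrajectoryParseError(f"line {ln + m + 1}: short atom row")
            rows.append((int(toks[c_id]), int(toks[c_type]), float(toks[c_q]),
                         float(toks[c_x]), float(toks[c_y]), float(toks[c_z])))
        ln += n
        rows.sort(key=lambda r: r[0])
        frames.append(np.array([[r[3], r[4], r[5]] for r in rows]))
        species = np.array([TYPE_TO_SPECIES.get(r[1], "X") for r in rows])
        charges = np.array([r[2] for r in rows])
    if not frames:
        raise TrajectoryParseError("line 1: file contains no frames")
    n_monomer = int(np.sum(species == "M"))
    return Trajectory(frames, times, charges, species, n_monomer, box)


def write_trajectory(traj: Trajectory, path: str | Path,
                     dialect: str = "xyz") -> Path:
    if dialect == "xyz":
        return write_xyz(traj, path)
    if dialect == "dump":
        return write_dump(traj, path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'xyz' or 'dump'")


def read_trajectory(path: str | Path, dialect: str | None = None) -> Trajectory:
    path = Path(path)
    if dialect is None:
        with open(path) as fh:
            first = fh.readline()
        dialect = "dump" if first.startswith("ITEM:") else "xyz"
    if dialect == "xyz":
        return read_xyz(path)
    if dialect == "dump":
        return read_dump(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'xyz' or 'dump'")
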