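"""Trajectory containers and I/O for coarse-grained (C-alpha) ensembles.

Coordinates are in Angstrom everywhere.  Two on-disk formats are supported:

* multi-model PDB (``MODEL``/``ATOM ... CA``/``ENDMDL``), read via Bio.PDB —
  lossy only to the format's fixed 0.001 A precision;
* a lossless tab-separated table with columns ``frame, residue_index, x, y, z``
  and a leading ``# snapshot_interval_steps=N`` metadata comment.

Trajectory boundaries matter: contact events must never span two independent
trajectories, so :func:`pool_frames` tags every frame with its source label
instead of silently merging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio.PDB import PDBParser

from .errors import TrajectoryFormatError
from .topology import Topology, THREE_TO_ONE

logger = logging.getLogger(__name__)

#: Snapshot spacing assumed when a file carries no metadata (simulation steps).
DEFAULT_SNAPSHOT_INTERVAL = 10_000


@dataclass
class Frame:
    """One snapshot: an (N, 3) float array of C-alpha positions in Angstrom."""

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TrajectoryFormatError(
                f"frame coordinates must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryFormatError("frame contains non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered frames plus the simulation-step spacing between snapshots."""

    frames: list[Frame]
    snapshot_interval_steps: int = DEFAULT_SNAPSHOT_INTERVAL
    label: str = ""

    def __post_init__(self):
        if self.snapshot_interval_steps <= 0:
            raise TrajectoryFormatError("snapshot_interval_steps must be > 0")
        if not self.frames:
            raise TrajectoryFormatError("trajectory must have at least one frame")
        n = self.frames[0].n_residues
        if any(f.n_residues != n for f in self.frames):
            raise TrajectoryFormatError("frames have unequal residue counts")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        return self.frames[0].n_residues

    def as_array(self) -> np.ndarray:
        """Stack into an (n_frames, N, 3) array."""
        return np.stack([f.coords for f in self.frames])


@dataclass
class TrajectoryEnsemble:
    """Independent trajectories of one system sharing a topology."""

    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self):
        if self.trajectories:
            n = self.trajectories[0].n_residues
            if any(t.n_residues != n for t in self.trajectories):
                raise TrajectoryFormatError(
                    "ensemble members have unequal residue counts")

    @property
    def n_frames_total(self) -> int:
        return sum(t.n_frames for t in self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)


def as_ensemble(data: Trajectory | TrajectoryEnsemble) -> TrajectoryEnsemble:
    if isinstance(data, Trajectory):
        return TrajectoryEnsemble([data])
    return data


def pool_frames(ensemble: Trajectory | TrajectoryEnsemble
                ) -> list[tuple[str, int, Frame]]:
    """Flatten an ensemble to ``(trajectory_label, frame_index, frame)`` tuples.

    Frame order within each trajectory is preserved; labels let downstream
    event detection respect trajectory boundaries.
    """
    ensemble = as_ensemble(ensemble)
    if not ensemble.trajectories:
        raise TrajectoryFormatError("empty ensemble")
    out = []
    for traj in ensemble:
        for i, fr in enumerate(traj.frames):
            out.append((traj.label, i, fr))
    return out


# ---------------------------------------------------------------------------
# multi-model PDB

def read_multimodel_pdb(path: str | Path, topology: Topology,
                        snapshot_interval_steps: int = DEFAULT_SNAPSHOT_INTERVAL,
                        label: str | None = None) -> Trajectory:
    """Read a multi-model C-alpha PDB into a :class:`Trajectory`.

    Frames are ordered by MODEL number.  Chains are matched to the topology by
    order of appearance (CG PDB chain IDs are unreliable); each model must
    provide exactly one CA per topology residue.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = sorted(structure.get_models(), key=lambda m: m.serial_num)
    if not models:
        raise TrajectoryFormatError(f"{path}: no MODEL records found")

    frames = []
    for model in models:
        coords = []
        for chain in model:
            for residue in chain:
                if "CA" in residue:
                    coords.append(residue["CA"].coord)
        if len(coords) != topology.n_residues:
            raise TrajectoryFormatError(
                f"{path}: model {model.serial_num} has {len(coords)} CA atoms, "
                f"topology expects {topology.n_residues}")
        frames.append(Frame(np.asarray(coords, dtype=float)))
    return Trajectory(frames, snapshot_interval_steps,
                      label=label if label is not None else path.stem)


_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


def write_multimodel_pdb(trajectory: Trajectory, topology: Topology,
                         path: str | Path) -> None:
    """Write a trajectory as a CA-only multi-model PDB."""
    if trajectory.n_residues != topology.n_residues:
        raise TrajectoryFormatError(
            f"trajectory has {trajectory.n_residues} residues, topology "
            f"{topology.n_residues}")
    chain_char = {cid: _CHAIN_ALPHABET[i % len(_CHAIN_ALPHABET)]
                  for i, cid in enumerate(topology.chain_ids)}
    lines = []
    for m, frame in enumerate(trajectory.frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 0
        for rec, xyz in zip(topology.residues, frame.coords):
            serial += 1
            name = rec.name if rec.name in THREE_TO_ONE else "UNK"
            lines.append(
                f"ATOM  {serial:5d}  CA  {name:>3s} {chain_char[rec.chain_id]}"
                f"{rec.local_index:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tabular format (lossless)

def write_coordinate_table(trajectory: Trajectory, path: str | Path) -> None:
    """Write the lossless TSV format (full floating precision)."""
    with open(path, "w") as fh:
        fh.write(f"# snapshot_interval_steps={trajectory.snapshot_interval_steps}\n")
        if trajectory.label:
            fh.write(f"# label={trajectory.label}\n")
        fh.write("frame\tresidue_index\tx\ty\tz\n")
        for fi, frame in enumerate(trajectory.frames):
            for ri, (x, y, z) in enumerate(frame.coords, start=1):
                fh.write(f"{fi}\t{ri}\t{float(x)!r}\t{float(y)!r}"
                         f"\t{float(z)!r}\n")


def read_coordinate_table(path: str | Path) -> Trajectory:
    """Read the TSV trajectory format written by :func:`write_coordinate_table`."""
    path = Path(path)
    interval = None
    label = ""
    rows: list[tuple[int, int, float, float, float]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("snapshot_interval_steps="):
                    interval = int(body.split("=", 1)[1])
                elif body.startswith("label="):
                    label = body.split("=", 1)[1]
                continue
            if not header_seen:
                cols = line.split("\t")
                if cols[:5] != ["frame", "residue_index", "x", "y", "z"]:
                    raise TrajectoryFormatError(
                        f"{path}:{lineno}: unexpected header {cols}")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise TrajectoryFormatError(
                    f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            rows.append((int(parts[0]), int(parts[1]),
                         float(parts[2]), float(parts[3]), float(parts[4])))
    if interval is None:
        interval = DEFAULT_SNAPSHOT_INTERVAL
        msg = (f"{path}: no snapshot_interval_steps metadata; "
               f"defaulting to {interval}")
        logger.warning(msg)
        warnings.warn(msg)
    if not rows:
        raise TrajectoryFormatError(f"{path}: no coordinate rows")

    frames: list[Frame] = []
    n_res = None
    current: list[list[float]] = []
    current_frame = rows[0][0]
    expected_ri = 1
    for fi, ri, x, y, z in rows:
        if fi != current_frame:
            if n_res is None:
                n_res = len(current)
            elif len(current) != n_res:
                raise TrajectoryFormatError(
                    f"{path}: ragged frames ({len(current)} vs {n_res} residues)")
            frames.append(Frame(np.asarray(current)))
            current, expected_ri, current_frame = [], 1, fi
        if ri != expected_ri:
            raise TrajectoryFormatError(
                f"{path}: frame {fi} residue indices not contiguous "
                f"(got {ri}, expected {expected_ri})")
        current.append([x, y, z])
        expected_ri += 1
    if n_res is not None and len(current) != n_res:
        raise TrajectoryFormatError(
            f"{path}: ragged frames ({len(current)} vs {n_res} residues)")
    frames.append(Frame(np.asarray(current)))
    return Trajectory(frames, interval, label=label)
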