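"""Superposition-based RMSD, radius of gyration, anchor distances, histograms.

The superposition is the classical least-squares (Kabsch) fit via SVD, with
the reflection branch excluded so the returned rotation is always proper.
RMSD series fit each frame on a rigid-core selection (by default the
topology's restrained regions) and report the deviation over a separate
calculation selection, so flexible-part motion is measured rather than
absorbed into the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConditioningError, InputError
from .topology import Topology
from .trajectory import Frame, Trajectory


@dataclass
class SuperpositionResult:
    """Proper rotation + translation mapping mobile onto reference, and RMSD."""

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,), Angstrom
    rmsd: float               # Angstrom, over the calc selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DistributionSeries:
    """Histogram of a per-frame scalar series, frequencies summing to 1."""

    values: np.ndarray
    bin_edges: np.ndarray
    frequency: np.ndarray
    median: float
    vmin: float
    vmax: float


def _as_index_array(selection: Sequence[int], n: int) -> np.ndarray:
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise InputError("empty selection")
    if idx.min() < 1 or idx.max() > n:
        raise InputError(f"selection indices outside 1..{n}")
    return idx - 1


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     fit_selection: Sequence[int] | None = None,
                     calc_selection: Sequence[int] | None = None
                     ) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    ``fit_selection``/``calc_selection`` are 1-based indices into the point
    lists (default: all points).  The fit minimises RMSD over the fit
    selection; the reported RMSD is over the calc selection after applying
    the fitted transform.  Collinear (rank < 2) fit selections raise
    :class:`ConditioningError` because the in-plane rotation is undetermined.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise InputError("mobile and reference must be matching (N, 3) arrays")
    n = mob.shape[0]
    fit = (_as_index_array(fit_selection, n) if fit_selection is not None
           else np.arange(n))
    calc = (_as_index_array(calc_selection, n) if calc_selection is not None
            else np.arange(n))
    if fit.size < 3:
        raise InputError("fit selection needs at least 3 points")

    mf, rf = mob[fit], ref[fit]
    mc, rc = mf.mean(axis=0), rf.mean(axis=0)
    h = (mf - mc).T @ (rf - rc)
    u, s, vt = np.linalg.svd(h)
    # collinear point sets leave a rotational degree of freedom
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ConditioningError("fit selection is (near-)collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc

    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved[calc] - ref[calc]) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(trajectory: Trajectory, reference: Frame | np.ndarray,
                fit_selection: Sequence[int] | None = None,
                calc_selection: Sequence[int] | None = None,
                topology: Topology | None = None) -> np.ndarray:
    """Per-frame RMSD (A) after superposing each frame onto ``reference``.

    Defaults when a topology is given: fit on its restrained (rigid-core)
    regions, calculate over all residues.  Fitting on the rigid cores keeps
    flexible-domain motion in the signal instead of the fit.
    """
    ref = reference.coords if isinstance(reference, Frame) else np.asarray(reference)
    if fit_selection is None and topology is not None and topology.restrained_regions:
        fit_selection = topology.indices_in_regions(topology.restrained_regions)
    out = np.empty(trajectory.n_frames)
    for k, frame in enumerate(trajectory.frames):
        out[k] = kabsch_superpose(frame.coords, ref, fit_selection,
                                  calc_selection).rmsd
    return out


def radius_of_gyration(frame: Frame | np.ndarray,
                       selection: Sequence[int] | None = None) -> float:
    """Rg (A): RMS distance of selected sites from their centroid.

    Uniform bead masses (one site per residue on the C-alpha trace).
    """
    x = frame.coords if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    if selection is not None:
        x = x[_as_index_array(selection, x.shape[0])]
    if x.shape[0] == 0:
        raise InputError("empty selection")
    centered = x - x.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered ** 2, axis=1))))


def rg_series(trajectory: Trajectory,
              selection: Sequence[int] | None = None) -> np.ndarray:
    return np.array([radius_of_gyration(f, selection) for f in trajectory.frames])


def anchor_distance_series(trajectory: Trajectory, topology: Topology,
                           anchors: str | tuple[int, int]) -> np.ndarray:
    """Per-frame C-alpha distance between two anchor residues.

    ``anchors`` is either a named pair declared in the topology config
    (e.g. a PDZ-to-BAR-tip pair) or an explicit (i, j) of concatenated
    indices.
    """
    if isinstance(anchors, str):
        i, j = topology.anchor_pair(anchors)
    else:
        i, j = anchors
        topology.residue(i), topology.residue(j)  # raise on bad index
    xyz = trajectory.as_array()
    return np.linalg.norm(xyz[:, i - 1, :] - xyz[:, j - 1, :], axis=-1)


def make_distribution(values: Sequence[float],
                      bins: int | Sequence[float] = 50) -> DistributionSeries:
    """Frequency histogram: proportions of frames per bin (sums to 1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("need at least one value")
    if np.isscalar(bins) or isinstance(bins, int):
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:  # degenerate range: one occupied bin
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise InputError("bin edges must be strictly increasing")
    counts, edges = np.histogram(v, bins=edges)
    return DistributionSeries(
        values=v, bin_edges=edges, frequency=counts / v.size,
        median=float(np.median(v)), vmin=float(v.min()), vmax=float(v.max()))
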