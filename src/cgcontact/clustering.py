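"""Most-probable positions of mobile units relative to a rigid reference body.

Every frame is superposed onto a reference structure using the rigid
reference region's C-alpha sites; the centroid of each copy of the mobile
region (one copy per chain that carries the region) is then a single 3-D
observation in the common reference frame.  Seeded k-means partitions these
observations; per-cluster occupancy fractions are percentages of all
observations, so they always sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConditioningError, InputError
from .geometry import kabsch_superpose
from .topology import Topology
from .trajectory import Frame, Trajectory, TrajectoryEnsemble, as_ensemble


@dataclass
class MobilePositionSet:
    """Mobile-unit positions in the reference-body frame.

    ``observations`` has one row per (trajectory, frame, copy); columns of
    ``positions`` are x, y, z in Angstrom.
    """

    labels: list[str]            # trajectory label per observation
    frame_indices: np.ndarray    # frame index per observation
    copy_ids: np.ndarray         # 0-based symmetric-copy id per observation
    positions: np.ndarray        # (n_obs, 3)
    reference_coords: np.ndarray  # the structure everything was fitted to

    @property
    def n_observations(self) -> int:
        return self.positions.shape[0]


@dataclass
class ClusterResult:
    """Cluster centroids, assignments and occupancy fractions (descending)."""

    centroids: np.ndarray        # (k, 3)
    assignments: np.ndarray      # cluster id per observation
    fractions_pct: np.ndarray    # (k,), sums to 100
    algorithm: str = "kmeans"
    params: dict = field(default_factory=dict)
    seed: int = 0


def mobile_positions(data: Trajectory | TrajectoryEnsemble, topology: Topology,
                     mobile_region: str, ref_region: str,
                     reference: Frame | np.ndarray | None = None,
                     anchor_residue_offset: int | None = None
                     ) -> MobilePositionSet:
    """Mobile-region positions expressed in the reference-body frame.

    ``mobile_region``/``ref_region`` are region labels.  By default the
    position of a copy is the centroid of its C-alpha sites; pass
    ``anchor_residue_offset`` (0-based within the copy) to track a single
    residue instead.  ``reference`` defaults to the first frame of the first
    trajectory.
    """
    ensemble = as_ensemble(data)
    if not ensemble.trajectories:
        raise InputError("empty ensemble")

    ref_idx = topology.indices_in_regions(ref_region)
    if len(ref_idx) < 3:
        raise ConditioningError(
            f"reference region {ref_region!r} has {len(ref_idx)} residues; "
            f"need >= 3 for superposition")
    mob_all = topology.indices_in_regions(mobile_region)
    if not mob_all:
        raise InputError(f"no residues in mobile region {mobile_region!r}")
    # one copy per chain carrying the region
    copies: list[list[int]] = []
    for cid in topology.chain_ids:
        c = [i for i in mob_all if topology.residue(i).chain_id == cid]
        if c:
            copies.append(c)

    if reference is None:
        ref_coords = ensemble.trajectories[0].frames[0].coords
    else:
        ref_coords = reference.coords if isinstance(reference, Frame) \
            else np.asarray(reference, dtype=float)

    labels: list[str] = []
    frame_indices: list[int] = []
    copy_ids: list[int] = []
    positions: list[np.ndarray] = []
    for traj in ensemble:
        for fi, frame in enumerate(traj.frames):
            sup = kabsch_superpose(frame.coords, ref_coords,
                                   fit_selection=ref_idx)
            moved = sup.apply(frame.coords)
            for ci, copy in enumerate(copies):
                sel = np.asarray(copy) - 1
                if anchor_residue_offset is not None:
                    pos = moved[sel[anchor_residue_offset]]
                else:
                    pos = moved[sel].mean(axis=0)
                labels.append(traj.label)
                frame_indices.append(fi)
                copy_ids.append(ci)
                positions.append(pos)
    return MobilePositionSet(
        labels=labels, frame_indices=np.asarray(frame_indices),
        copy_ids=np.asarray(copy_ids), positions=np.asarray(positions),
        reference_coords=ref_coords)


def cluster_positions(positions: MobilePositionSet | np.ndarray, k: int,
                      seed: int = 0) -> ClusterResult:
    """Seeded k-means over mobile-unit positions; clusters sorted by size.

    Fractions are per-observation occupancies (percent of all observations)
    and sum to 100 by construction.
    """
    x = positions.positions if isinstance(positions, MobilePositionSet) \
        else np.asarray(positions, dtype=float)
    n = x.shape[0]
    if k < 1 or k > n:
        raise InputError(f"k={k} invalid for {n} observations")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(x)
    sizes = np.bincount(raw, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))  # size desc, stable
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    assignments = relabel[raw]
    centroids = km.cluster_centers_[order]
    fractions = 100.0 * sizes[order] / n
    return ClusterResult(centroids=centroids, assignments=assignments,
                         fractions_pct=fractions, algorithm="kmeans",
                         params={"k": k, "n_init": 10}, seed=seed)


def occupancy_report(result: ClusterResult, topology: Topology,
                     reference_coords: np.ndarray, set_name: str,
                     covering_threshold: float = 12.0) -> pd.DataFrame:
    """Proximity of each cluster centroid to a named special residue set.

    Reports, per cluster, the minimum centroid-to-C-alpha distance over the
    set (in the reference frame) and a ``covering`` flag when it falls below
    ``covering_threshold`` (default: 8 A contact cutoff + 4 A slack, since a
    domain centroid sits off the domain surface).
    """
    idx = np.asarray(topology.special_set(set_name)) - 1
    ref = np.asarray(reference_coords, dtype=float)
    rows = []
    for ci, centroid in enumerate(result.centroids):
        d = float(np.min(np.linalg.norm(ref[idx] - centroid, axis=1)))
        rows.append({
            "cluster_id": ci + 1,
            "fraction_pct": float(result.fractions_pct[ci]),
            "centroid_x": centroid[0], "centroid_y": centroid[1],
            "centroid_z": centroid[2],
            f"min_dist_to_{set_name}": d,
            "covering": d <= covering_threshold,
        })
    return pd.DataFrame(rows)


def assignments_table(positions: MobilePositionSet,
                      result: ClusterResult) -> pd.DataFrame:
    """Per-observation table: trajectory, frame, copy, cluster id (1-based)."""
    return pd.DataFrame({
        "trajectory": positions.labels,
        "frame": positions.frame_indices,
        "copy": positions.copy_ids,
        "cluster_id": result.assignments + 1,
    })
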