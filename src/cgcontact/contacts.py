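"""Residue-residue contact detection, probabilities, lifetimes, and maps.

A contact is defined on the C-alpha trace: two residues are in contact in a
frame when their C-alpha distance is at or below a cutoff (default 8.0 A —
a distance of exactly 8.0 A counts) and, if they belong to the same chain,
their local indices differ by at least a minimum sequence separation
(default 5).  Pairs on different chains are always eligible: for a dimer the
concatenated-index gap between protomers carries no sequence meaning.

Contact probability is the percentage of pooled frames (all trajectories,
equal weight per frame) in which the pair is in contact.  A contact *event*
is a maximal run of consecutive in-contact frames within one trajectory;
events touching a trajectory boundary are flagged censored but are included
in lifetime statistics (excluding them would bias against long-lived
contacts).  Lifetimes are reported in units of ``unit_steps`` simulation
steps (default 100,000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, TopologyLookupError, UndefinedStatisticError
from .topology import (HYDROPHOBIC, NEGATIVE, POLAR, POSITIVE, Topology)
from .trajectory import Frame, Trajectory, TrajectoryEnsemble, as_ensemble

#: Lifetime unit: contact durations are reported in multiples of this many
#: simulation steps.
DEFAULT_UNIT_STEPS = 100_000


@dataclass(frozen=True)
class ContactCriterion:
    """C-alpha distance cutoff plus intra-chain sequence-separation filter."""

    cutoff: float = 8.0
    min_sequence_separation: int = 5

    def __post_init__(self):
        if self.cutoff <= 0:
            raise InputError("cutoff must be > 0")
        if self.min_sequence_separation < 0:
            raise InputError("min_sequence_separation must be >= 0")


@dataclass(frozen=True)
class ContactEvent:
    """Maximal run of in-contact frames for one pair in one trajectory."""

    pair: tuple[int, int]
    trajectory_label: str
    start_frame: int
    length_frames: int
    censored: bool


@dataclass
class ContactPairStats:
    """Probability and lifetime summary for one residue pair."""

    pair: tuple[int, int]
    names: tuple[str, str]
    probability_pct: float
    lifetime_mean: float | None
    lifetime_sd: float | None
    n_events: int


@dataclass
class ContactMap:
    """Contact probabilities (%) over a rectangular residue-group product."""

    row_indices: tuple[int, ...]
    col_indices: tuple[int, ...]
    probability: np.ndarray  # percent, shape (len(rows), len(cols))
    transform: str = "linear"

    def transpose(self) -> "ContactMap":
        return ContactMap(self.col_indices, self.row_indices,
                          self.probability.T.copy(), self.transform)


# ---------------------------------------------------------------------------
# eligibility and per-frame detection

def _eligibility_matrix(topology: Topology, criterion: ContactCriterion
                        ) -> np.ndarray:
    """Boolean (N, N) matrix of pairs eligible under the separation rule."""
    chains = np.array([r.chain_id for r in topology.residues])
    local = np.array([r.local_index for r in topology.residues])
    same_chain = chains[:, None] == chains[None, :]
    sep = np.abs(local[:, None] - local[None, :])
    elig = ~same_chain | (sep >= criterion.min_sequence_separation)
    np.fill_diagonal(elig, False)
    return elig


def pair_eligible(topology: Topology, i: int, j: int,
                  criterion: ContactCriterion) -> bool:
    """Is (i, j) admissible under the intra-chain separation rule?"""
    ri, rj = topology.residue(i), topology.residue(j)
    if ri.chain_id != rj.chain_id:
        return i != j
    return abs(ri.local_index - rj.local_index) >= criterion.min_sequence_separation


def detect_contacts(frame: Frame, topology: Topology,
                    criterion: ContactCriterion = ContactCriterion()
                    ) -> set[tuple[int, int]]:
    """All residue pairs (i < j, concatenated 1-based) in contact in a frame."""
    if frame.n_residues != topology.n_residues:
        raise InputError(
            f"frame has {frame.n_residues} residues, topology "
            f"{topology.n_residues}")
    x = frame.coords
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    hit = (d2 <= criterion.cutoff ** 2) & _eligibility_matrix(topology, criterion)
    ii, jj = np.nonzero(np.triu(hit, k=1))
    return {(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)}


# ---------------------------------------------------------------------------
# batch series over ensembles

def _pair_distance_series(traj: Trajectory, pairs: np.ndarray) -> np.ndarray:
    """(n_frames, n_pairs) distances for 0-based index pairs."""
    xyz = traj.as_array()
    diff = xyz[:, pairs[:, 0], :] - xyz[:, pairs[:, 1], :]
    return np.linalg.norm(diff, axis=-1)


def contact_series(data: Trajectory | TrajectoryEnsemble, topology: Topology,
                   pairs: Sequence[tuple[int, int]],
                   criterion: ContactCriterion = ContactCriterion()
                   ) -> list[np.ndarray]:
    """Per-trajectory boolean arrays (n_frames, n_pairs) of contact state."""
    ensemble = as_ensemble(data)
    idx = np.asarray([(i - 1, j - 1) for i, j in pairs], dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= topology.n_residues):
        raise TopologyLookupError("pair index outside topology")
    out = []
    for traj in ensemble:
        if traj.n_residues != topology.n_residues:
            raise InputError("trajectory does not match topology")
        if idx.size == 0:
            out.append(np.zeros((traj.n_frames, 0), dtype=bool))
        else:
            out.append(_pair_distance_series(traj, idx) <= criterion.cutoff)
    return out


def contact_probability(data: Trajectory | TrajectoryEnsemble,
                        topology: Topology, pair: tuple[int, int],
                        criterion: ContactCriterion = ContactCriterion()
                        ) -> float:
    """Percent of pooled frames in which ``pair`` is in contact."""
    series = contact_series(data, topology, [pair], criterion)
    total = sum(s.shape[0] for s in series)
    hits = sum(int(s[:, 0].sum()) for s in series)
    return 100.0 * hits / total


def contact_map(data: Trajectory | TrajectoryEnsemble, topology: Topology,
                group_a: Sequence[int], group_b: Sequence[int],
                criterion: ContactCriterion = ContactCriterion()
                ) -> ContactMap:
    """Contact-probability matrix over ``group_a`` x ``group_b``.

    Pairs excluded by the sequence-separation rule (and the diagonal when the
    groups coincide) are reported as 0% — they can never be in contact by
    definition.
    """
    rows = tuple(int(i) for i in group_a)
    cols = tuple(int(j) for j in group_b)
    if not rows or not cols:
        raise InputError("contact map groups must be non-empty")
    ensemble = as_ensemble(data)
    r = np.asarray(rows) - 1
    c = np.asarray(cols) - 1
    elig = _eligibility_matrix(topology, criterion)[np.ix_(r, c)]
    counts = np.zeros((len(rows), len(cols)))
    total = 0
    for traj in ensemble:
        xyz = traj.as_array()
        d = np.linalg.norm(xyz[:, r, None, :] - xyz[:, None, c, :], axis=-1)
        counts += (d <= criterion.cutoff).sum(axis=0)
        total += traj.n_frames
    prob = 100.0 * counts / total
    prob[~elig] = 0.0
    return ContactMap(rows, cols, prob)


def log_percentage(cmap: ContactMap, floor_pct: float = 0.01) -> np.ndarray:
    """Display transform: log10 of probability (%), floored at ``floor_pct``.

    The floor keeps zero-probability cells representable on a log color bar.
    """
    if floor_pct <= 0:
        raise InputError("floor_pct must be > 0")
    return np.log10(np.maximum(cmap.probability, floor_pct))


# ---------------------------------------------------------------------------
# events and lifetimes

def events_from_bool_series(series: np.ndarray, pair: tuple[int, int],
                            label: str) -> list[ContactEvent]:
    """Maximal runs of True in a 1-D boolean series (one trajectory)."""
    s = np.asarray(series, dtype=bool)
    n = s.size
    if n == 0:
        return []
    padded = np.concatenate(([False], s, [False])).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]  # exclusive
    return [
        ContactEvent(pair=pair, trajectory_label=label, start_frame=int(a),
                     length_frames=int(b - a),
                     censored=bool(a == 0 or b == n))
        for a, b in zip(starts, ends)
    ]


def contact_events(data: Trajectory | TrajectoryEnsemble, topology: Topology,
                   pair: tuple[int, int],
                   criterion: ContactCriterion = ContactCriterion()
                   ) -> list[ContactEvent]:
    """Contact events for one pair; runs never span trajectory boundaries."""
    ensemble = as_ensemble(data)
    series = contact_series(ensemble, topology, [pair], criterion)
    events: list[ContactEvent] = []
    for traj, s in zip(ensemble, series):
        events.extend(events_from_bool_series(s[:, 0], pair, traj.label))
    return events


def lifetime_stats(events: Iterable[ContactEvent],
                   snapshot_interval_steps: int,
                   unit_steps: int = DEFAULT_UNIT_STEPS,
                   include_censored: bool = True,
                   ddof: int = 0) -> tuple[float, float]:
    """Mean and SD of event durations, in units of ``unit_steps`` steps.

    Duration of an event = length_frames x snapshot_interval_steps /
    unit_steps.  Censored events are included by default (dropping them
    biases against long-lived contacts); SD is the population SD (ddof=0).
    """
    if unit_steps <= 0 or snapshot_interval_steps <= 0:
        raise InputError("step counts must be positive")
    durations = np.array([
        ev.length_frames * snapshot_interval_steps / unit_steps
        for ev in events if include_censored or not ev.censored])
    if durations.size == 0:
        raise UndefinedStatisticError("no events: lifetime undefined")
    return float(durations.mean()), float(durations.std(ddof=ddof))


# ---------------------------------------------------------------------------
# pair statistics, ranking, classification

def candidate_pairs(topology: Topology, group_a: Sequence[int],
                    group_b: Sequence[int],
                    criterion: ContactCriterion = ContactCriterion()
                    ) -> list[tuple[int, int]]:
    """Eligible (i < j) pairs with one residue in each group."""
    pairs = set()
    for i in group_a:
        for j in group_b:
            if i == j:
                continue
            a, b = min(i, j), max(i, j)
            if pair_eligible(topology, a, b, criterion):
                pairs.add((a, b))
    return sorted(pairs)


def compute_pair_stats(data: Trajectory | TrajectoryEnsemble,
                       topology: Topology,
                       pairs: Sequence[tuple[int, int]],
                       criterion: ContactCriterion = ContactCriterion(),
                       unit_steps: int = DEFAULT_UNIT_STEPS
                       ) -> list[ContactPairStats]:
    """Probability + lifetime statistics for many pairs in one pass."""
    ensemble = as_ensemble(data)
    series = contact_series(ensemble, topology, pairs, criterion)
    total = sum(s.shape[0] for s in series)
    stats = []
    for k, pair in enumerate(pairs):
        hits = sum(int(s[:, k].sum()) for s in series)
        events: list[ContactEvent] = []
        for traj, s in zip(ensemble, series):
            events.extend(events_from_bool_series(s[:, k], pair, traj.label))
        if events:
            # per-event duration uses the snapshot interval of its own
            # trajectory, so mixed-interval ensembles stay correct
            interval = {t.label: t.snapshot_interval_steps for t in ensemble}
            durations = np.array([
                ev.length_frames * interval[ev.trajectory_label] / unit_steps
                for ev in events])
            mean, sd = float(durations.mean()), float(durations.std(ddof=0))
        else:
            mean = sd = None
        stats.append(ContactPairStats(
            pair=pair,
            names=(topology.name_of(pair[0]), topology.name_of(pair[1])),
            probability_pct=100.0 * hits / total,
            lifetime_mean=mean, lifetime_sd=sd, n_events=len(events)))
    return stats


def classify_interaction(pair: tuple[int, int], topology: Topology) -> str:
    """Interaction-type call from residue classes.

    ELECTROSTATIC: one positive + one negative residue; HYDROPHOBIC: both
    hydrophobic; POLAR: both polar; MIXED otherwise; UNKNOWN (with a warning)
    when a residue name is not in the hydropathy table.
    """
    classes = []
    for idx in pair:
        name = topology.name_of(idx)
        cls = topology.hydropathy.get(name)
        if cls is None:
            warnings.warn(f"residue {idx} ({name}) has no hydropathy class; "
                          f"classification UNKNOWN")
            return "UNKNOWN"
        classes.append(cls)
    a, b = classes
    if {a, b} == {POSITIVE, NEGATIVE}:
        return "ELECTROSTATIC"
    if a == b == HYDROPHOBIC:
        return "HYDROPHOBIC"
    if a == b == POLAR:
        return "POLAR"
    return "MIXED"


def top_pairs(stats: Iterable[ContactPairStats], topology: Topology,
              region_a: str, region_b: str, n: int = 10) -> pd.DataFrame:
    """Top-N pairs between two regions, ranked by contact probability.

    Ties break by lifetime mean (descending), then by (i, j) ascending.
    Returns a table mirroring published key-pair tables: residue indices and
    names, probability (%), lifetime mean +/- SD, event count, interaction
    class.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    wanted = {(region_a, region_b), (region_b, region_a)}
    rows = []
    for st in stats:
        regs = (topology.region_of(st.pair[0]), topology.region_of(st.pair[1]))
        if regs not in wanted:
            continue
        rows.append({
            "residue_1": st.pair[0], "name_1": st.names[0],
            "residue_2": st.pair[1], "name_2": st.names[1],
            "probability_pct": st.probability_pct,
            "lifetime_mean": st.lifetime_mean if st.lifetime_mean is not None
            else np.nan,
            "lifetime_sd": st.lifetime_sd if st.lifetime_sd is not None
            else np.nan,
            "n_events": st.n_events,
            "class": classify_interaction(st.pair, topology),
        })
    df = pd.DataFrame(rows, columns=[
        "residue_1", "name_1", "residue_2", "name_2", "probability_pct",
        "lifetime_mean", "lifetime_sd", "n_events", "class"])
    if df.empty:
        return df
    df = df.sort_values(
        by=["probability_pct", "lifetime_mean", "residue_1", "residue_2"],
        ascending=[False, False, True, True], kind="mergesort",
        na_position="last")
    return df.head(n).reset_index(drop=True)
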