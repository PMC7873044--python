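"""Tethered-domain Monte Carlo generator with known ground truth.

The generator emulates the architecture of a dimeric scaffold whose rigid
crescent-shaped reference body (a BAR-domain surrogate: a curved rod of beads
at 3.8 A spacing, held fixed) carries flexible chains: compact rigid mobile
bodies (PDZ surrogates) tethered by freely-jointed linkers, and/or bare
flexible tails (C-terminus surrogates).  Attractive square wells ("sticky
pairs") with known depth plant contact propensities; optional screened
Coulomb terms plant electrostatics.  Because every propensity is planted and
can be calibrated by an independent long run, every stage of the analysis
pipeline can be validated without external trajectory data.

Sampling is Metropolis Monte Carlo at unit kT with a bond-length-preserving
move set:

* kink (crankshaft): rotate one interior flexible bead about the axis
  through its two bonded neighbours;
* pivot: rotate the entire downstream segment of a chain (including an
  attached rigid body) about a flexible bead or the anchor bead on the rod.

Both moves are symmetric proposals and preserve all bond lengths exactly, so
the freely-jointed-chain limit holds exactly when all interactions vanish.
Energies are in kT; "time" is counted in attempted moves, which is suitable
for testing estimators but is not a model of physical kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .contacts import ContactCriterion, contact_probability
from .errors import ConfigurationError, ConstructionError, CalibrationWarning
from .topology import ResidueRecord, Topology
from .trajectory import Frame, Trajectory, TrajectoryEnsemble

# ---------------------------------------------------------------------------
# parameters


@dataclass
class RodParams:
    """Rigid reference body: beads on a circular arc (curved rod)."""

    n_beads: int = 40
    curvature_radius: float = 40.0  # Angstrom


@dataclass
class BodyParams:
    """One mobile compact body on a flexible linker, tethered to the rod."""

    n_beads: int = 8
    linker_length: int = 12
    attach: int = 1  # 1-based rod bead index


@dataclass
class TailParams:
    """One bare flexible tail tethered to the rod."""

    length: int = 15
    attach: int = 1


@dataclass
class StickyPair:
    """Square-well attraction between a rod bead and a mobile/tail bead.

    Indices are 1-based concatenated bead indices; energy is -eps (kT) when
    the pair distance is <= width (A), 0 otherwise.
    """

    ref_bead: int
    partner_bead: int
    eps: float = 2.0
    width: float = 8.0


@dataclass
class ChargeParams:
    """Screened-Coulomb term: strength * qi*qj * exp(-r/screening)/r (kT)."""

    values: dict[int, float] = field(default_factory=dict)  # 1-based bead -> q
    strength: float = 2.0       # kT * Angstrom
    screening_length: float = 10.0  # Angstrom


@dataclass
class SyntheticModelParams:
    """Full parameterization of the tethered-domain generator."""

    ref_body: RodParams = field(default_factory=RodParams)
    mobile_bodies: list[BodyParams] = field(default_factory=list)
    tails: list[TailParams] = field(default_factory=list)
    bond_length: float = 3.8
    bead_radius: float = 2.0  # hard-sphere; 0 disables excluded volume
    sticky_pairs: list[StickyPair] = field(default_factory=list)
    charges: ChargeParams | None = None
    temperature_factor: float = 1.0
    seed: int = 0
    n_steps: int = 50_000
    record_interval: int = 100
    equil_steps: int = 2_000
    label: str = "synthetic"

    # -- validation / bookkeeping -----------------------------------------
    @property
    def n_beads_total(self) -> int:
        return (self.ref_body.n_beads
                + sum(b.linker_length + b.n_beads for b in self.mobile_bodies)
                + sum(t.length for t in self.tails))

    def validate(self) -> None:
        if self.ref_body.n_beads < 1:
            raise ConfigurationError("rod needs at least one bead")
        if self.bond_length <= 0 or self.bead_radius < 0:
            raise ConfigurationError("bond_length > 0 and bead_radius >= 0 required")
        if self.record_interval < 1 or self.n_steps < 1 or self.equil_steps < 0:
            raise ConfigurationError("invalid step counts")
        if self.temperature_factor <= 0:
            raise ConfigurationError("temperature_factor must be > 0")
        for b in self.mobile_bodies:
            if b.n_beads < 2:
                raise ConfigurationError("mobile bodies need >= 2 beads")
            if b.linker_length < 1:
                raise ConfigurationError("linker_length must be >= 1")
            if not 1 <= b.attach <= self.ref_body.n_beads:
                raise ConfigurationError(f"attach bead {b.attach} not on rod")
        for t in self.tails:
            if t.length < 1:
                raise ConfigurationError("tail length must be >= 1")
            if not 1 <= t.attach <= self.ref_body.n_beads:
                raise ConfigurationError(f"attach bead {t.attach} not on rod")
        n = self.n_beads_total
        for sp in self.sticky_pairs:
            if sp.eps < 0 or sp.width <= 0:
                raise ConfigurationError("sticky pair needs eps >= 0, width > 0")
            for idx in (sp.ref_bead, sp.partner_bead):
                if not 1 <= idx <= n:
                    raise ConfigurationError(
                        f"sticky pair bead {idx} outside system (1-{n})")
        if self.charges:
            for idx in self.charges.values:
                if not 1 <= idx <= n:
                    raise ConfigurationError(f"charged bead {idx} outside system")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "ref_body": {"n_beads": self.ref_body.n_beads,
                         "curvature_radius": self.ref_body.curvature_radius},
            "mobile_bodies": [
                {"n_beads": b.n_beads, "linker_length": b.linker_length,
                 "attach": b.attach} for b in self.mobile_bodies],
            "tails": [{"length": t.length, "attach": t.attach}
                      for t in self.tails],
            "bond_length": self.bond_length,
            "bead_radius": self.bead_radius,
            "sticky_pairs": [
                {"ref_bead": s.ref_bead, "partner_bead": s.partner_bead,
                 "eps": s.eps, "width": s.width} for s in self.sticky_pairs],
            "temperature_factor": self.temperature_factor,
            "seed": self.seed, "n_steps": self.n_steps,
            "record_interval": self.record_interval,
            "equil_steps": self.equil_steps,
        }
        if self.charges:
            d["charges"] = {"values": dict(self.charges.values),
                            "strength": self.charges.strength,
                            "screening_length": self.charges.screening_length}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticModelParams":
        rod = d.get("ref_body") or {}
        charges = None
        if d.get("charges"):
            c = d["charges"]
            charges = ChargeParams(
                values={int(k): float(v) for k, v in (c.get("values") or {}).items()},
                strength=float(c.get("strength", 2.0)),
                screening_length=float(c.get("screening_length", 10.0)))
        params = cls(
            ref_body=RodParams(int(rod.get("n_beads", 40)),
                               float(rod.get("curvature_radius", 40.0))),
            mobile_bodies=[BodyParams(int(b["n_beads"]), int(b["linker_length"]),
                                      int(b.get("attach", 1)))
                           for b in d.get("mobile_bodies") or []],
            tails=[TailParams(int(t["length"]), int(t.get("attach", 1)))
                   for t in d.get("tails") or []],
            bond_length=float(d.get("bond_length", 3.8)),
            bead_radius=float(d.get("bead_radius", 2.0)),
            sticky_pairs=[StickyPair(int(s["ref_bead"]), int(s["partner_bead"]),
                                     float(s.get("eps", 2.0)),
                                     float(s.get("width", 8.0)))
                          for s in d.get("sticky_pairs") or []],
            charges=charges,
            temperature_factor=float(d.get("temperature_factor", 1.0)),
            seed=int(d.get("seed", 0)),
            n_steps=int(d.get("n_steps", 50_000)),
            record_interval=int(d.get("record_interval", 100)),
            equil_steps=int(d.get("equil_steps", 2_000)),
            label=str(d.get("label", "synthetic")),
        )
        params.validate()
        return params

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_preset(name: str) -> SyntheticModelParams:
    """Load a shipped preset ('system1-like', 'system2-like', 'two-state-toy')
    or a YAML file path."""
    from importlib import resources
    fname = name.replace("-", "_") + ".yaml"
    pkg_file = resources.files("cgcontact").joinpath("presets", fname)
    if pkg_file.is_file():
        return SyntheticModelParams.from_dict(yaml.safe_load(pkg_file.read_text()))
    if Path(name).is_file():
        return SyntheticModelParams.from_yaml(name)
    raise ConfigurationError(f"unknown preset or missing file: {name!r}")


@dataclass
class GroundTruth:
    """Calibrated planted-contact propensities from an independent run."""

    pair_probability_pct: dict[tuple[int, int], float]
    n_frames: int
    cluster_weights: dict[int, float] | None = None


# ---------------------------------------------------------------------------
# system construction


@dataclass
class _Move:
    kind: str                 # "kink" | "pivot"
    moved: np.ndarray         # 0-based bead indices that move
    origin: int               # pivot/kink anchor bead (0-based)
    axis_a: int = -1          # kink only: second axis bead
    others: np.ndarray = None
    excl_mask: np.ndarray = None       # (|S|, |O|) bonded-pair mask
    sticky: list = None                # [(si, oj, eps, width), ...]
    qprod: np.ndarray = None           # (|S|, |O|) charge products or None


@dataclass
class SyntheticSystem:
    """Built bead system: initial structure, topology, bonds, move tables."""

    params: SyntheticModelParams
    topology: Topology
    initial_frame: Frame
    bonds: list[tuple[int, int]]          # 0-based
    flexible: np.ndarray                  # 0-based flexible bead indices
    moves: list[_Move]

    @property
    def n_beads(self) -> int:
        return self.initial_frame.n_residues


def _rod_coords(rod: RodParams, b: float) -> np.ndarray:
    """Beads on a circular arc in the xy-plane (concave side faces origin)."""
    n, rc = rod.n_beads, rod.curvature_radius
    if n == 1:
        return np.array([[0.0, rc, 0.0]])
    dtheta = 2.0 * np.arcsin(min(b / (2.0 * rc), 1.0))
    thetas = np.pi / 2 + (np.arange(n) - (n - 1) / 2) * dtheta
    return np.column_stack([rc * np.cos(thetas), rc * np.sin(thetas),
                            np.zeros(n)])


def _perp_unit(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0])
    if abs(v @ w) > 0.9:
        w = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, w)
    return p / np.linalg.norm(p)


def _grow_chain(anchor: np.ndarray, direction: np.ndarray, n_linker: int,
                n_body: int, b: float) -> np.ndarray:
    """Straight linker along ``direction``; rigid body as a compact helix.

    The body helix uses 4 beads per turn with a 1.2 A rise, which keeps every
    non-bonded internal distance >= 4.8 A (clear of the 4 A hard-sphere
    contact distance) while staying compact (~5 A diameter).
    """
    direction = direction / np.linalg.norm(direction)
    beads = [anchor + (i + 1) * b * direction for i in range(n_linker)]
    if n_body:
        start = beads[-1] if beads else anchor
        bead0 = start + b * direction
        rise = 1.2
        dphi = np.pi / 2
        rho = np.sqrt(b ** 2 - rise ** 2) / (2.0 * np.sin(dphi / 2))
        e1 = _perp_unit(direction)
        e2 = np.cross(direction, e1)
        axis_pt = bead0 - rho * e1
        k = np.arange(n_body)
        helix = (axis_pt[None, :]
                 + rho * (np.cos(k * dphi)[:, None] * e1
                          + np.sin(k * dphi)[:, None] * e2)
                 + (k * rise)[:, None] * direction)
        beads.extend(helix)
    return np.asarray(beads)


def _min_nonbonded_distance(coords: np.ndarray,
                            bonds: set[tuple[int, int]]) -> float:
    n = coords.shape[0]
    if n < 2:
        return np.inf
    d = cdist(coords, coords)
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)
    for i, j in bonds:
        mask[i, j] = mask[j, i] = False
    return float(d[mask].min()) if mask.any() else np.inf


def build_system(params: SyntheticModelParams,
                 max_retries: int = 200) -> SyntheticSystem:
    """Place beads with no hard-sphere overlap and build the move tables.

    Chains grow perpendicular to the rod plane (alternating sides); if a
    placement clashes, new growth directions are drawn at random for a
    bounded number of retries before :class:`ConstructionError` is raised.
    """
    params.validate()
    b = params.bond_length
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 901]))
    rod_xyz = _rod_coords(params.ref_body, b)
    n_rod = params.ref_body.n_beads

    chain_specs = ([("M", m.attach, m.linker_length, m.n_beads)
                    for m in params.mobile_bodies]
                   + [("T", t.attach, t.length, 0) for t in params.tails])

    for attempt in range(max_retries):
        coords_list = [rod_xyz]
        bonds: set[tuple[int, int]] = set()
        records: list[ResidueRecord] = []
        flexible: list[int] = []
        chains_meta = []  # (chain bead idx list, rod anchor idx, n_linker, n_body)
        for i in range(n_rod):
            records.append(ResidueRecord(i + 1, "R", i + 1, "GLY", "BAR"))
            if i:
                bonds.add((i - 1, i))
        offset = n_rod
        for ci, (kind, attach, n_flex, n_body) in enumerate(chain_specs):
            anchor_idx = attach - 1
            if attempt == 0:
                direction = np.array([0.0, 0.0, 1.0 if ci % 2 == 0 else -1.0])
            else:
                v = rng.normal(size=3)
                direction = v / np.linalg.norm(v)
            chain_xyz = _grow_chain(rod_xyz[anchor_idx], direction,
                                    n_flex, n_body, b)
            n_chain = chain_xyz.shape[0]
            idxs = list(range(offset, offset + n_chain))
            cid = f"{kind}{ci + 1}"
            for li, gi in enumerate(idxs):
                if kind == "M":
                    region = "LINKER" if li < n_flex else "PDZ"
                else:
                    region = "C_TERM"
                records.append(ResidueRecord(gi + 1, cid, li + 1, "GLY", region))
            bonds.add((anchor_idx, idxs[0]))
            for a, bb in zip(idxs[:-1], idxs[1:]):
                bonds.add((a, bb))
            flexible.extend(idxs[:n_flex] if kind == "M" else idxs)
            chains_meta.append((idxs, anchor_idx, n_flex, n_body))
            coords_list.append(chain_xyz)
            offset += n_chain
        coords = np.vstack(coords_list)
        if (params.bead_radius == 0
                or _min_nonbonded_distance(coords, bonds)
                >= 2 * params.bead_radius):
            break
    else:
        raise ConstructionError(
            f"could not pack system without overlap in {max_retries} tries")

    topology = Topology(
        residues=records,
        special_sets=({"sticky_ref_beads": tuple(sorted(
            {sp.ref_bead for sp in params.sticky_pairs}))}
            if params.sticky_pairs else {}),
        restrained_regions=frozenset({"BAR", "PDZ"}),
        label=params.label,
    )

    system = SyntheticSystem(
        params=params, topology=topology, initial_frame=Frame(coords),
        bonds=sorted(bonds), flexible=np.asarray(sorted(flexible), dtype=int),
        moves=[])
    system.moves = _build_moves(system, chains_meta)
    return system


def _build_moves(system: SyntheticSystem, chains_meta) -> list[_Move]:
    params = system.params
    n = system.n_beads
    bonded = {i: set() for i in range(n)}
    for i, j in system.bonds:
        bonded[i].add(j)
        bonded[j].add(i)
    charges = np.zeros(n)
    if params.charges:
        for idx, q in params.charges.values.items():
            charges[idx - 1] = q

    moves: list[_Move] = []
    for idxs, anchor, n_flex, n_body in chains_meta:
        # kinks: flexible beads with two bonded neighbours
        for pos in range(n_flex):
            gi = idxs[pos]
            prev = idxs[pos - 1] if pos > 0 else anchor
            nxt = idxs[pos + 1] if pos + 1 < len(idxs) else None
            if nxt is not None:
                moves.append(_Move("kink", np.array([gi]), prev, nxt))
        # pivots: about rod anchor (whole chain) or a flexible bead
        for p, origin in enumerate([anchor] + [idxs[k] for k in range(n_flex)]):
            downstream = np.asarray(idxs[p:], dtype=int)
            if downstream.size == 0:
                continue
            moves.append(_Move("pivot", downstream, origin))

    all_idx = np.arange(n)
    for mv in moves:
        in_s = np.zeros(n, dtype=bool)
        in_s[mv.moved] = True
        mv.others = all_idx[~in_s]
        pos_s = {g: k for k, g in enumerate(mv.moved)}
        pos_o = {g: k for k, g in enumerate(mv.others)}
        mask = np.zeros((mv.moved.size, mv.others.size), dtype=bool)
        for i, j in system.bonds:
            if i in pos_s and j in pos_o:
                mask[pos_s[i], pos_o[j]] = True
            elif j in pos_s and i in pos_o:
                mask[pos_s[j], pos_o[i]] = True
        mv.excl_mask = mask
        mv.sticky = []
        for sp in params.sticky_pairs:
            a, c = sp.ref_bead - 1, sp.partner_bead - 1
            if a in pos_s and c in pos_o:
                mv.sticky.append((pos_s[a], pos_o[c], sp.eps, sp.width))
            elif c in pos_s and a in pos_o:
                mv.sticky.append((pos_s[c], pos_o[a], sp.eps, sp.width))
        if params.charges and np.any(charges != 0):
            qp = np.outer(charges[mv.moved], charges[mv.others])
            qp[mask] = 0.0
            mv.qprod = qp if np.any(qp != 0) else None
        else:
            mv.qprod = None
    return moves


# ---------------------------------------------------------------------------
# Monte Carlo engine


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    t = 1.0 - c
    return np.array([
        [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
        [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
        [t * x * z - s * y, t * y * z + s * x, t * z * z + c]])


def _interaction_energy(d: np.ndarray, mv: _Move, charges_on: bool,
                        strength: float, screening: float) -> float:
    e = 0.0
    for si, oj, eps, width in mv.sticky:
        if d[si, oj] <= width:
            e -= eps
    if charges_on and mv.qprod is not None:
        nz = mv.qprod != 0
        if np.any(nz):
            dd = d[nz]
            e += strength * float(np.sum(mv.qprod[nz] * np.exp(-dd / screening)
                                         / dd))
    return e


def run_mc(system: SyntheticSystem, params: SyntheticModelParams | None = None,
           seed: int | None = None, label: str | None = None,
           return_stats: bool = False):
    """Metropolis MC run; returns a :class:`Trajectory` (frames every
    ``record_interval`` moves after ``equil_steps`` of equilibration).

    Identical (system, params, seed) always yields a bit-identical
    trajectory.  With ``return_stats=True`` also returns a dict with the
    acceptance fraction.
    """
    params = params or system.params
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 313]))
    coords = system.initial_frame.coords.copy()
    moves = system.moves
    if not moves:
        raise ConstructionError("system has no movable beads")

    total = params.equil_steps + params.n_steps
    move_ids = rng.integers(0, len(moves), size=total)
    axes = rng.normal(size=(total, 3))
    angles = rng.uniform(-np.pi, np.pi, size=total)
    accept_u = rng.random(size=total)

    hs2 = (2.0 * params.bead_radius)
    charges_on = params.charges is not None
    strength = params.charges.strength if charges_on else 0.0
    screening = params.charges.screening_length if charges_on else 1.0
    kt = params.temperature_factor

    frames: list[Frame] = []
    accepted = 0
    for step in range(total):
        mv = moves[move_ids[step]]
        if mv.kind == "kink":
            axis = coords[mv.axis_a] - coords[mv.origin]
            if axis @ axis < 1e-16:
                axis = axes[step]
        else:
            axis = axes[step]
        rot = _rotation_matrix(axis, angles[step])
        origin = coords[mv.origin]
        new_s = (coords[mv.moved] - origin) @ rot.T + origin

        d_new = cdist(new_s, coords[mv.others])
        if hs2 > 0 and bool(np.any((d_new < hs2) & ~mv.excl_mask)):
            continue  # hard-sphere overlap: reject
        if mv.sticky or mv.qprod is not None:
            d_old = cdist(coords[mv.moved], coords[mv.others])
            de = (_interaction_energy(d_new, mv, charges_on, strength, screening)
                  - _interaction_energy(d_old, mv, charges_on, strength,
                                        screening))
        else:
            de = 0.0
        if de <= 0.0 or accept_u[step] < np.exp(-de / kt):
            coords[mv.moved] = new_s
            accepted += 1
        if step >= params.equil_steps and \
                (step - params.equil_steps + 1) % params.record_interval == 0:
            frames.append(Frame(coords.copy()))

    traj = Trajectory(frames, snapshot_interval_steps=params.record_interval,
                      label=label if label is not None else params.label)
    if return_stats:
        return traj, {"acceptance_fraction": accepted / total,
                      "n_attempted": total}
    return traj


def run_ensemble(params: SyntheticModelParams, n_trajectories: int,
                 system: SyntheticSystem | None = None) -> TrajectoryEnsemble:
    """Independent trajectories with per-trajectory seed streams derived
    deterministically from the root seed and the trajectory index."""
    system = system or build_system(params)
    trajs = []
    for t in range(n_trajectories):
        seed = int(np.random.SeedSequence([params.seed, 7001, t])
                   .generate_state(1)[0] % (2 ** 31))
        trajs.append(run_mc(system, params, seed=seed,
                            label=f"{params.label}-{t + 1}"))
    return TrajectoryEnsemble(trajs)


# ---------------------------------------------------------------------------
# ground-truth calibration


def calibrate_ground_truth(params: SyntheticModelParams,
                           length_factor: int = 2,
                           criterion: ContactCriterion = ContactCriterion()
                           ) -> GroundTruth:
    """Independent long reference run; per-sticky-pair contact probability.

    Uses a seed stream disjoint from any production run of the same params
    and ``length_factor`` x the production step count.
    """
    cal = SyntheticModelParams.from_dict(params.to_dict())
    cal.n_steps = params.n_steps * length_factor
    system = build_system(cal)
    cal_seed = int(np.random.SeedSequence([params.seed, 424243])
                   .generate_state(1)[0] % (2 ** 31))
    traj = run_mc(system, cal, seed=cal_seed, label=f"{params.label}-cal")
    probs = {}
    for sp in params.sticky_pairs:
        pair = (min(sp.ref_bead, sp.partner_bead),
                max(sp.ref_bead, sp.partner_bead))
        probs[pair] = contact_probability(traj, system.topology, pair, criterion)
    return GroundTruth(pair_probability_pct=probs, n_frames=traj.n_frames)


def calibrate_epsilon_grid(params: SyntheticModelParams, pair_index: int,
                           eps_grid: Sequence[float],
                           length_factor: int = 2) -> list[float]:
    """Calibrated contact probability of one sticky pair across a depth grid.

    Warns (:class:`CalibrationWarning`) if probabilities are non-monotone in
    the well depth beyond ~3 combined binomial standard errors.
    """
    probs = []
    n_frames = []
    for eps in eps_grid:
        p = SyntheticModelParams.from_dict(params.to_dict())
        p.sticky_pairs[pair_index].eps = float(eps)
        gt = calibrate_ground_truth(p, length_factor)
        sp = p.sticky_pairs[pair_index]
        pair = (min(sp.ref_bead, sp.partner_bead),
                max(sp.ref_bead, sp.partner_bead))
        probs.append(gt.pair_probability_pct[pair])
        n_frames.append(gt.n_frames)
    for k in range(1, len(probs)):
        p0, p1 = probs[k - 1] / 100, probs[k] / 100
        se = np.sqrt(p0 * (1 - p0) / n_frames[k - 1]
                     + p1 * (1 - p1) / n_frames[k]) * 100
        if probs[k] < probs[k - 1] - 3 * se:
            warnings.warn(
                f"calibration non-monotone: eps={eps_grid[k - 1]} -> "
                f"{probs[k - 1]:.2f}% but eps={eps_grid[k]} -> {probs[k]:.2f}%",
                CalibrationWarning)
    return probs


# ---------------------------------------------------------------------------
# closed-form validation helpers


def two_state_occupancy_theory(eps: float, r_core: float, r_well: float,
                               r_max: float) -> float:
    """Boltzmann two-state occupancy of a square well for a free bead
    confined to the shell r_core < r < r_max around a fixed partner:
    exp(eps) V_in / (exp(eps) V_in + V_out)."""
    v_in = r_well ** 3 - r_core ** 3
    v_out = r_max ** 3 - r_well ** 3
    w = np.exp(eps) * v_in
    return float(w / (w + v_out))


def run_two_state_toy(eps: float, r_core: float = 4.0, r_well: float = 8.0,
                      r_max: float = 12.0, n_steps: int = 200_000,
                      step_size: float = 2.0, seed: int = 0,
                      record_every: int = 10) -> np.ndarray:
    """Metropolis sampling of the 2-bead square-well toy.

    One bead fixed at the origin; the free bead moves in the shell between a
    hard core at ``r_core`` and a hard outer wall at ``r_max``; energy is
    -eps inside ``r_well``.  Returns a boolean in-well series sampled every
    ``record_every`` accepted-or-rejected steps.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    x = np.array([0.0, 0.0, (r_core + r_max) / 2])
    steps = rng.uniform(-step_size, step_size, size=(n_steps, 3))
    us = rng.random(n_steps)
    out = np.empty(n_steps // record_every, dtype=bool)
    k = 0
    in_well = np.linalg.norm(x) <= r_well
    for i in range(n_steps):
        xn = x + steps[i]
        r = np.sqrt(xn @ xn)
        if r_core < r <= r_max:
            new_in = r <= r_well
            de = -eps * (float(new_in) - float(in_well))
            if de <= 0 or us[i] < np.exp(-de):
                x, in_well = xn, new_in
        if (i + 1) % record_every == 0:
            out[k] = in_well
            k += 1
    return out


def planted_blobs(centers: Sequence[Sequence[float]],
                  weights: Sequence[float], sigma: float, n: int,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian position mixture with known weights.

    Returns (positions (n, 3), component labels).  Used as planted ground
    truth for cluster-fraction recovery tests.
    """
    centers = np.asarray(centers, dtype=float)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    labels = rng.choice(len(weights), size=n, p=weights)
    pos = centers[labels] + rng.normal(scale=sigma, size=(n, 3))
    return pos, labels
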