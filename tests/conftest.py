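"""Shared fixtures: small topologies and trajectory builders."""

from __future__ import annotations

import numpy as np
import pytest

from cgcontact.topology import Topology, ResidueRecord, build_topology
from cgcontact.trajectory import Frame, Trajectory, TrajectoryEnsemble


def make_chain_topology(lengths: dict[str, int],
                        names: dict[str, list[str]] | None = None,
                        regions: dict[str, str] | None = None) -> Topology:
    """Topology with the given chain lengths; every residue GLY / OTHER
    unless overridden."""
    residues = []
    idx = 0
    for cid, n in lengths.items():
        for li in range(1, n + 1):
            idx += 1
            name = names[cid][li - 1] if names else "GLY"
            residues.append(ResidueRecord(idx, cid, li, name,
                                          regions.get(cid, "OTHER")
                                          if regions else "OTHER"))
    return Topology(residues=residues)


def trajectory_from_distances(distances: np.ndarray,
                              label: str = "t") -> tuple[Trajectory, Topology]:
    """Two residues on different chains, separated by the given per-frame
    distances (so every pair is contact-eligible)."""
    topo = make_chain_topology({"A": 1, "B": 1})
    frames = [Frame(np.array([[0.0, 0.0, 0.0], [float(d), 0.0, 0.0]]))
              for d in distances]
    return Trajectory(frames, snapshot_interval_steps=10_000, label=label), topo


@pytest.fixture(scope="session")
def pick1_topology():
    """The shipped full-length dimer fixture (2 x 416 residues)."""
    from importlib import resources
    import yaml
    text = resources.files("cgcontact").joinpath(
        "data", "pick1_like.yaml").read_text()
    return build_topology(yaml.safe_load(text))


@pytest.fixture(scope="session")
def system1_topology():
    """The shipped truncated dimer fixture (2 x 357 residues)."""
    from importlib import resources
    import yaml
    text = resources.files("cgcontact").joinpath(
        "data", "pick1_system1_like.yaml").read_text()
    return build_topology(yaml.safe_load(text))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
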