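"""End-to-end analysis pipeline: config -> TSV report bundle + provenance.

A :class:`RunConfig` names the input (trajectory files plus a topology
config, or a synthetic preset to simulate), toggles the analysis stages, and
fixes every seed.  :func:`run_pipeline` executes the enabled stages in
order — contact map, key-pair table with lifetimes, RMSD/Rg, anchor
distances, mobile-position clusters — writing each result as TSV with a
provenance comment naming the config hash, plus a ``provenance.json`` echo.
Reruns with an identical config and seed produce byte-identical TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (assignments_table, cluster_positions, mobile_positions,
                         occupancy_report)
from .contacts import (ContactCriterion, candidate_pairs, compute_pair_stats,
                       contact_map, log_percentage, top_pairs)
from .errors import ConfigurationError, PipelineError
from .geometry import anchor_distance_series, make_distribution, rg_series, rmsd_series
from .synthetic import SyntheticModelParams, build_system, load_preset, run_ensemble
from .topology import Topology, load_topology
from .trajectory import (TrajectoryEnsemble, read_coordinate_table,
                         read_multimodel_pdb)

logger = logging.getLogger(__name__)

ANALYSES = ("contacts", "lifetimes", "map", "rmsd_rg", "distances", "clusters")


@dataclass
class RunConfig:
    """Parsed pipeline configuration (see ``RunConfig.from_dict`` for keys)."""

    raw: dict = field(default_factory=dict)
    topology_path: str | None = None
    trajectory_paths: list[str] = field(default_factory=list)
    synthetic_preset: str | None = None
    synthetic_n_trajectories: int = 2
    synthetic_overrides: dict = field(default_factory=dict)
    analyses: dict[str, bool] = field(
        default_factory=lambda: {a: True for a in ANALYSES})
    criterion: ContactCriterion = field(default_factory=ContactCriterion)
    map_rows: Any = "BAR"
    map_cols: Any = "PDZ"
    pair_region_a: str = "PDZ"
    pair_region_b: str = "BAR"
    top_n: int = 10
    cluster_k: int = 5
    cluster_mobile_region: str = "PDZ"
    cluster_ref_region: str = "BAR"
    cluster_special_set: str | None = None
    covering_threshold: float = 12.0
    anchors: list = field(default_factory=list)
    bins: int = 50
    log_floor_pct: float = 0.01
    seed: int = 0
    out_dir: str = "cgcontact_out"

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        cfg = cls(raw=dict(d))
        cfg.topology_path = d.get("topology")
        cfg.trajectory_paths = list(d.get("trajectories") or [])
        syn = d.get("synthetic") or {}
        cfg.synthetic_preset = syn.get("preset")
        cfg.synthetic_n_trajectories = int(syn.get("n_trajectories", 2))
        cfg.synthetic_overrides = dict(syn.get("overrides") or {})
        if "analyses" in d:
            toggles = {a: bool(v) for a, v in d["analyses"].items()}
            unknown = set(toggles) - set(ANALYSES)
            if unknown:
                raise ConfigurationError(f"unknown analyses: {sorted(unknown)}")
            cfg.analyses = {a: toggles.get(a, False) for a in ANALYSES}
        if not any(cfg.analyses.values()):
            raise ConfigurationError("no analysis enabled")
        c = d.get("contact") or {}
        cfg.criterion = ContactCriterion(
            cutoff=float(c.get("cutoff", 8.0)),
            min_sequence_separation=int(c.get("min_separation", 5)))
        m = d.get("map") or {}
        cfg.map_rows = m.get("rows", cfg.map_rows)
        cfg.map_cols = m.get("cols", cfg.map_cols)
        tp = d.get("top_pairs") or {}
        cfg.pair_region_a = tp.get("region_a", cfg.pair_region_a)
        cfg.pair_region_b = tp.get("region_b", cfg.pair_region_b)
        cfg.top_n = int(tp.get("n", cfg.top_n))
        cl = d.get("clusters") or {}
        cfg.cluster_k = int(cl.get("k", cfg.cluster_k))
        cfg.cluster_mobile_region = cl.get("mobile_region",
                                           cfg.cluster_mobile_region)
        cfg.cluster_ref_region = cl.get("ref_region", cfg.cluster_ref_region)
        cfg.cluster_special_set = cl.get("special_set")
        cfg.covering_threshold = float(cl.get("covering_threshold", 12.0))
        cfg.anchors = list(d.get("distances", {}).get("anchors", []) or [])
        cfg.bins = int(d.get("bins", 50))
        cfg.log_floor_pct = float(d.get("log_floor_pct", 0.01))
        cfg.seed = int(d.get("seed", 0))
        cfg.out_dir = str(d.get("out_dir", cfg.out_dir))
        if not cfg.trajectory_paths and not cfg.synthetic_preset:
            raise ConfigurationError(
                "config must give 'trajectories' or a 'synthetic' preset")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, Mapping):
            raise ConfigurationError(f"{path} is not a mapping")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        # hash the analysis parameters, not the output location
        hashed = {k: v for k, v in self.raw.items() if k != "out_dir"}
        blob = yaml.safe_dump(hashed, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _builtin_topology(name: str) -> Topology | None:
    fname = name.replace("-", "_") + ".yaml"
    ref = resources.files("cgcontact").joinpath("data", fname)
    if ref.is_file():
        import io
        cfg = yaml.safe_load(ref.read_text())
        from .topology import build_topology
        return build_topology(cfg)
    return None


def _load_inputs(config: RunConfig):
    if config.synthetic_preset:
        params = load_preset(config.synthetic_preset)
        for key, val in config.synthetic_overrides.items():
            if not hasattr(params, key):
                raise ConfigurationError(f"unknown synthetic override {key!r}")
            setattr(params, key, type(getattr(params, key))(val))
        params.seed = config.seed
        system = build_system(params)
        ensemble = run_ensemble(params, config.synthetic_n_trajectories,
                                system=system)
        return system.topology, ensemble, params
    if not config.topology_path:
        raise ConfigurationError("file-based runs need a 'topology' path")
    topology = (_builtin_topology(config.topology_path)
                or load_topology(config.topology_path))
    trajs = []
    for p in config.trajectory_paths:
        if str(p).endswith((".pdb", ".ent")):
            trajs.append(read_multimodel_pdb(p, topology))
        else:
            trajs.append(read_coordinate_table(p))
    return topology, TrajectoryEnsemble(trajs), None


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cgcontact {__version__} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g",
                  lineterminator="\n")


def _hist_frame(dist) -> pd.DataFrame:
    return pd.DataFrame({"bin_left": dist.bin_edges[:-1],
                         "bin_right": dist.bin_edges[1:],
                         "frequency": dist.frequency})


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run all enabled stages; returns a dict of output paths and results."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    outputs: dict[str, Any] = {"out_dir": str(out), "config_hash": h,
                               "files": []}
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    def _save(df, fname, index=False):
        path = out / fname
        _write_tsv(df, path, h, index=index)
        outputs["files"].append(fname)
        return path

    try:
        _stage("load")
        topology, ensemble, params = _load_inputs(config)
        _done("load")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    crit = config.criterion
    an = config.analyses

    def _region_group(spec):
        if isinstance(spec, str):
            idx = topology.indices_in_regions(spec)
        else:
            idx = [int(i) for i in spec]
        if not idx:
            raise ConfigurationError(f"empty residue group {spec!r}")
        return idx

    if an["map"]:
        try:
            _stage("map")
            rows = _region_group(config.map_rows)
            cols = _region_group(config.map_cols)
            cmap = contact_map(ensemble, topology, rows, cols, crit)
            mat = pd.DataFrame(cmap.probability, index=cmap.row_indices,
                               columns=cmap.col_indices)
            mat.index.name = "residue"
            _save(mat, "contact_map.tsv", index=True)
            logmat = pd.DataFrame(log_percentage(cmap, config.log_floor_pct),
                                  index=cmap.row_indices,
                                  columns=cmap.col_indices)
            logmat.index.name = "residue"
            _save(logmat, "contact_map_log10.tsv", index=True)
            outputs["contact_map"] = cmap
            _done("map")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("map", str(exc)) from exc

    if an["contacts"] or an["lifetimes"]:
        try:
            _stage("pairs")
            ga = _region_group(config.pair_region_a)
            gb = _region_group(config.pair_region_b)
            pairs = candidate_pairs(topology, ga, gb, crit)
            stats = compute_pair_stats(ensemble, topology, pairs, crit)
            table = top_pairs(stats, topology, config.pair_region_a,
                              config.pair_region_b, config.top_n)
            _save(table, "top_pairs.tsv")
            outputs["top_pairs"] = table
            _done("pairs")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("pairs", str(exc)) from exc

    if an["rmsd_rg"]:
        try:
            _stage("rmsd_rg")
            reference = ensemble.trajectories[0].frames[0]
            rmsd_rows, rg_rows = [], []
            rmsd_all, rg_all = [], []
            for traj in ensemble:
                r = rmsd_series(traj, reference, topology=topology)
                g = rg_series(traj)
                rmsd_all.append(r)
                rg_all.append(g)
                rmsd_rows.append(pd.DataFrame(
                    {"trajectory": traj.label,
                     "frame": np.arange(traj.n_frames), "rmsd": r}))
                rg_rows.append(pd.DataFrame(
                    {"trajectory": traj.label,
                     "frame": np.arange(traj.n_frames), "rg": g}))
            _save(pd.concat(rmsd_rows, ignore_index=True), "rmsd_series.tsv")
            _save(pd.concat(rg_rows, ignore_index=True), "rg_series.tsv")
            rmsd_dist = make_distribution(np.concatenate(rmsd_all), config.bins)
            rg_dist = make_distribution(np.concatenate(rg_all), config.bins)
            _save(_hist_frame(rmsd_dist), "rmsd_hist.tsv")
            _save(_hist_frame(rg_dist), "rg_hist.tsv")
            outputs["rmsd_median"] = rmsd_dist.median
            outputs["rg_range"] = (rg_dist.vmin, rg_dist.vmax)
            _done("rmsd_rg")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("rmsd_rg", str(exc)) from exc

    if an["distances"]:
        try:
            _stage("distances")
            anchors = config.anchors or list(topology.anchor_pairs)
            for spec in anchors:
                if isinstance(spec, str):
                    name, key = spec, spec
                else:
                    i, j = int(spec[0]), int(spec[1])
                    name, key = f"{i}_{j}", (i, j)
                values = np.concatenate([
                    anchor_distance_series(t, topology, key) for t in ensemble])
                dist = make_distribution(values, config.bins)
                _save(_hist_frame(dist), f"distance_{name}_hist.tsv")
                outputs.setdefault("distance_medians", {})[name] = dist.median
            _done("distances")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("distances", str(exc)) from exc

    if an["clusters"]:
        try:
            _stage("clusters")
            positions = mobile_positions(ensemble, topology,
                                         config.cluster_mobile_region,
                                         config.cluster_ref_region)
            result = cluster_positions(positions, config.cluster_k,
                                       seed=config.seed)
            set_name = config.cluster_special_set
            if set_name is None and "sticky_ref_beads" in topology.special_sets:
                set_name = "sticky_ref_beads"
            if set_name:
                report = occupancy_report(result, topology,
                                          positions.reference_coords, set_name,
                                          config.covering_threshold)
            else:
                report = pd.DataFrame({
                    "cluster_id": np.arange(1, config.cluster_k + 1),
                    "fraction_pct": result.fractions_pct,
                    "centroid_x": result.centroids[:, 0],
                    "centroid_y": result.centroids[:, 1],
                    "centroid_z": result.centroids[:, 2]})
            _save(report, "clusters.tsv")
            _save(assignments_table(positions, result),
                  "cluster_assignments.tsv")
            outputs["cluster_fractions"] = result.fractions_pct
            _done("clusters")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("clusters", str(exc)) from exc

    provenance = {
        "tool": "cgcontact",
        "version": __version__,
        "config_hash": h,
        "seed": config.seed,
        "config": config.raw,
        "n_trajectories": len(ensemble.trajectories),
        "n_frames_total": ensemble.n_frames_total,
        "n_residues": topology.n_residues,
        "outputs": outputs["files"],
        "stage_seconds": timings,
    }
    if params is not None:
        provenance["synthetic_params"] = params.to_dict()
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                    sort_keys=True))
    outputs["provenance"] = provenance
    return outputs
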