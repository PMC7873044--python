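"""Residue-level system annotation: chains, regions, special residue sets.

A :class:`Topology` describes a (possibly multi-chain) coarse-grained protein
system at residue resolution.  Residues carry a single *concatenated* 1-based
index that runs across chains in declaration order — the convention used by
contact tables of dimeric systems, where an index larger than one protomer's
length identifies the partner protomer.  Regions (PDZ, LINKER, BAR, ...) are
declared as inclusive local-index ranges and must partition each chain;
residues not covered by any declared range fall in region ``OTHER``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigurationError, TopologyLookupError

#: Region labels recognised throughout the package.
REGION_LABELS = ("N_TERM", "PDZ", "LINKER", "LINKER_HELIX", "BAR", "C_TERM", "OTHER")

#: Hydropathy / charge classes used for interaction-type calls.
HYDROPHOBIC = "HYDROPHOBIC"
POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
POLAR = "POLAR"

#: Default residue-class table.  Chosen so that Tyr/Cys-containing pairs are
#: classed hydrophobic and Lys–Asp pairs electrostatic, matching how such
#: contacts are conventionally described; override per-topology via
#: ``hydropathy_override`` in the config.
DEFAULT_HYDROPATHY: dict[str, str] = {
    **{aa: HYDROPHOBIC for aa in
       ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY", "CYS", "TYR")},
    **{aa: POSITIVE for aa in ("LYS", "ARG", "HIS")},
    **{aa: NEGATIVE for aa in ("ASP", "GLU")},
    **{aa: POLAR for aa in ("SER", "THR", "ASN", "GLN")},
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}
VALID_NAMES = frozenset(_ONE_TO_THREE.values())


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of the system.

    ``index`` is the 1-based concatenated index over all chains;
    ``local_index`` is 1-based within ``chain_id``.
    """

    index: int
    chain_id: str
    local_index: int
    name: str
    region: str


@dataclass
class Topology:
    """Ordered residues plus named residue sets and rigid-core regions."""

    residues: list[ResidueRecord]
    special_sets: dict[str, tuple[int, ...]] = field(default_factory=dict)
    restrained_regions: frozenset[str] = frozenset()
    hydropathy: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_HYDROPATHY))
    anchor_pairs: dict[str, tuple[int, int]] = field(default_factory=dict)
    label: str = ""

    # -- basic accessors ---------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> ResidueRecord:
        if not 1 <= index <= self.n_residues:
            raise TopologyLookupError(
                f"residue index {index} outside 1..{self.n_residues}")
        return self.residues[index - 1]

    def region_of(self, index: int) -> str:
        """Region label of the residue at concatenated ``index``."""
        return self.residue(index).region

    def name_of(self, index: int) -> str:
        return self.residue(index).name

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if not seen or seen[-1] != r.chain_id:
                seen.append(r.chain_id)
        return seen

    def chain_length(self, chain_id: str) -> int:
        n = sum(1 for r in self.residues if r.chain_id == chain_id)
        if n == 0:
            raise TopologyLookupError(f"unknown chain {chain_id!r}")
        return n

    def split_dimer_index(self, index: int) -> tuple[str, int]:
        """Map a concatenated index to ``(chain_id, local_index)``.

        Inverse of the concatenation convention: e.g. with two 357-residue
        protomers, index 608 resolves to position 251 of the second chain.
        """
        r = self.residue(index)
        return r.chain_id, r.local_index

    def concat_index(self, chain_id: str, local_index: int) -> int:
        """Inverse of :meth:`split_dimer_index`."""
        for r in self.residues:
            if r.chain_id == chain_id and r.local_index == local_index:
                return r.index
        raise TopologyLookupError(f"no residue {local_index} in chain {chain_id!r}")

    def indices_in_regions(self, regions: Iterable[str] | str) -> list[int]:
        if isinstance(regions, str):
            regions = (regions,)
        wanted = set(regions)
        return [r.index for r in self.residues if r.region in wanted]

    def special_set(self, name: str) -> tuple[int, ...]:
        try:
            return self.special_sets[name]
        except KeyError:
            raise TopologyLookupError(f"unknown special set {name!r}") from None

    def anchor_pair(self, name: str) -> tuple[int, int]:
        try:
            return self.anchor_pairs[name]
        except KeyError:
            raise TopologyLookupError(f"unknown anchor pair {name!r}") from None

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        chains = []
        for cid in self.chain_ids:
            seq = [r.name for r in self.residues if r.chain_id == cid]
            chains.append({"id": cid, "sequence": seq})
        regions = []
        for cid in self.chain_ids:
            recs = [r for r in self.residues if r.chain_id == cid]
            start = 0
            for i, r in enumerate(recs):
                last = i == len(recs) - 1
                if last or recs[i + 1].region != r.region:
                    regions.append({"label": r.region, "chain": cid,
                                    "start": recs[start].local_index,
                                    "end": r.local_index})
                    start = i + 1
        return {
            "label": self.label,
            "chains": chains,
            "regions": regions,
            "special_sets": {k: list(v) for k, v in self.special_sets.items()},
            "restrained_regions": sorted(self.restrained_regions),
            "hydropathy_override": {
                k: v for k, v in self.hydropathy.items()
                if DEFAULT_HYDROPATHY.get(k) != v},
            "anchor_pairs": {k: list(v) for k, v in self.anchor_pairs.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def __eq__(self, other: object) -> bool:  # value semantics for round-trips
        if not isinstance(other, Topology):
            return NotImplemented
        return (self.residues == other.residues
                and self.special_sets == other.special_sets
                and self.restrained_regions == other.restrained_regions
                and self.hydropathy == other.hydropathy
                and self.anchor_pairs == other.anchor_pairs)


# ---------------------------------------------------------------------------
# construction

def _expand_sequence(spec, length: int | None, chain_id: str) -> list[str]:
    """Accept a 1-letter string, list of strings, or list of 3-letter codes."""
    if spec is None:
        if length is None:
            raise ConfigurationError(
                f"chain {chain_id!r}: need 'sequence' or 'length'")
        return ["UNK"] * length
    if isinstance(spec, str):
        letters = spec.replace(" ", "").replace("\n", "")
        names = []
        for ch in letters.upper():
            if ch not in _ONE_TO_THREE:
                raise ConfigurationError(
                    f"chain {chain_id!r}: unknown residue letter {ch!r}")
            names.append(_ONE_TO_THREE[ch])
    elif isinstance(spec, Sequence):
        if spec and all(isinstance(s, str) and len(s) == 3 for s in spec):
            names = [s.upper() for s in spec]
            bad = [s for s in names if s not in VALID_NAMES]
            if bad:
                raise ConfigurationError(
                    f"chain {chain_id!r}: invalid residue codes {bad}")
        else:  # list of 1-letter chunks
            return _expand_sequence("".join(spec), length, chain_id)
    else:
        raise ConfigurationError(f"chain {chain_id!r}: unreadable sequence")
    if length is not None and len(names) != length:
        raise ConfigurationError(
            f"chain {chain_id!r}: sequence length {len(names)} != declared {length}")
    return names


def build_topology(config: Mapping) -> Topology:
    """Build a validated :class:`Topology` from a parsed config mapping."""
    chains_cfg = config.get("chains")
    if not chains_cfg:
        raise ConfigurationError("config has no 'chains'")

    names_by_chain: dict[str, list[str]] = {}
    order: list[str] = []
    for c in chains_cfg:
        cid = str(c["id"])
        if cid in names_by_chain:
            raise ConfigurationError(f"duplicate chain id {cid!r}")
        names_by_chain[cid] = _expand_sequence(
            c.get("sequence"), c.get("length"), cid)
        order.append(cid)

    # region ranges per chain, with overlap detection
    region_by_chain: dict[str, dict[int, str]] = {cid: {} for cid in order}
    ranges_seen: dict[str, list[tuple[int, int, str]]] = {cid: [] for cid in order}
    for reg in config.get("regions", []):
        label = str(reg["label"]).upper()
        if label not in REGION_LABELS:
            raise ConfigurationError(f"unknown region label {label!r}")
        targets = reg.get("chains") or [reg.get("chain") or order[0]]
        start, end = int(reg["start"]), int(reg["end"])
        for cid in targets:
            cid = str(cid)
            if cid not in names_by_chain:
                raise ConfigurationError(f"region {label}: unknown chain {cid!r}")
            n = len(names_by_chain[cid])
            if not (1 <= start <= end <= n):
                raise ConfigurationError(
                    f"region {label}: range {start}-{end} outside chain "
                    f"{cid!r} (1-{n})")
            for s0, e0, l0 in ranges_seen[cid]:
                if start <= e0 and s0 <= end:
                    raise ConfigurationError(
                        f"overlapping region ranges on chain {cid!r}: "
                        f"{l0} {s0}-{e0} vs {label} {start}-{end}")
            ranges_seen[cid].append((start, end, label))
            for i in range(start, end + 1):
                region_by_chain[cid][i] = label

    residues: list[ResidueRecord] = []
    idx = 0
    for cid in order:
        for li, name in enumerate(names_by_chain[cid], start=1):
            idx += 1
            residues.append(ResidueRecord(
                index=idx, chain_id=cid, local_index=li, name=name,
                region=region_by_chain[cid].get(li, "OTHER")))

    n_total = idx
    offsets = {}
    off = 0
    for cid in order:
        offsets[cid] = off
        off += len(names_by_chain[cid])

    # special sets: either concatenated 'indices' or per-chain 'local_indices'
    special: dict[str, tuple[int, ...]] = {}
    for name, spec in (config.get("special_sets") or {}).items():
        if isinstance(spec, Mapping):
            chains = spec.get("chains") or order
            locals_ = spec.get("local_indices")
            concat = list(spec.get("indices") or [])
            if locals_:
                for cid in chains:
                    if cid not in offsets:
                        raise ConfigurationError(
                            f"special set {name!r}: unknown chain {cid!r}")
                    concat += [offsets[str(cid)] + int(i) for i in locals_]
        else:
            concat = [int(i) for i in spec]
        bad = [i for i in concat if not 1 <= i <= n_total]
        if bad:
            raise ConfigurationError(
                f"special set {name!r}: indices {bad} outside any chain "
                f"(1-{n_total})")
        special[name] = tuple(sorted(set(int(i) for i in concat)))

    hydropathy = dict(DEFAULT_HYDROPATHY)
    for code, cls in (config.get("hydropathy_override") or {}).items():
        cls = str(cls).upper()
        if cls not in (HYDROPHOBIC, POSITIVE, NEGATIVE, POLAR):
            raise ConfigurationError(f"unknown hydropathy class {cls!r}")
        hydropathy[str(code).upper()] = cls

    anchors: dict[str, tuple[int, int]] = {}
    for name, pair in (config.get("anchor_pairs") or {}).items():
        i, j = int(pair[0]), int(pair[1])
        for k in (i, j):
            if not 1 <= k <= n_total:
                raise ConfigurationError(
                    f"anchor pair {name!r}: index {k} outside any chain")
        anchors[name] = (i, j)

    return Topology(
        residues=residues,
        special_sets=special,
        restrained_regions=frozenset(
            str(r).upper() for r in config.get("restrained_regions", [])),
        hydropathy=hydropathy,
        anchor_pairs=anchors,
        label=str(config.get("label", "")),
    )


def region_of(topology: Topology, index: int) -> str:
    """Region label of the residue at concatenated ``index``."""
    return topology.region_of(index)


def split_dimer_index(topology: Topology, index: int) -> tuple[str, int]:
    """Map a concatenated index to ``(chain_id, local_index)``."""
    return topology.split_dimer_index(index)


def load_topology(config_path: str | Path) -> Topology:
    """Load and validate a topology from a YAML config file."""
    path = Path(config_path)
    try:
        config = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(config, Mapping):
        raise ConfigurationError(f"{path} is not a mapping")
    return build_topology(config)
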