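"""Config-driven end-to-end reports.

Two pipelines tie the analysis modules together:

* ``topology_report`` - element enumeration, the junction/feasibility
  table measured on a structure, classification against a comparator
  order, and optional permutant sequence design;
* ``capsid_report`` - lattice census, symmetry expansion, maximum
  diameter, quasi-equivalent conformer RMSD matrix, interface tables and
  the chainmail catenation graph.

Configuration is a TOML document validated strictly (unknown keys are
rejected before any computation). Reports carry machine-readable TSV
tables - each row tagged with the module operation that produced it - and
a short human-readable summary; rerunning with the same config and seed
reproduces the TSV payloads byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import capsid_lattice, chainmail, fold_topology, interfaces, synthetic
from .errors import ValidationError
from .structures import (
    BACKBONE_ATOMS,
    Structure,
    conformer_rmsd_matrix,
    read_fasta,
    read_structure,
)

__all__ = ["AnalysisConfig", "Report", "load_config", "topology_report", "capsid_report"]

logger = logging.getLogger("capsidkit.workbench")


@dataclass
class Report:
    """Deterministic TSV tables plus a human-readable summary."""

    name: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary_lines: list[str] = field(default_factory=list)

    @property
    def summary(self) -> str:
        return "\n".join(self.summary_lines)

    def write(self, output_dir: str | Path) -> list[Path]:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for key in sorted(self.tables):
            path = out / f"{self.name}_{key}.tsv"
            self.tables[key].to_csv(path, sep="\t", index=False)
            written.append(path)
        path = out / f"{self.name}_summary.txt"
        path.write_text(self.summary + "\n")
        written.append(path)
        return written


_SCHEMA = {
    "seed": int,
    "output_dir": str,
    "topology": {
        "structure": str,
        "fixture": dict,
        "partition": list,
        "chain_length": int,
        "d_max": float,
        "compare_order": list,
        "permutant_order": list,
        "sequence_fasta": str,
    },
    "capsid": {
        "structure": str,
        "fixture": dict,
        "h": int,
        "k": int,
        "expand": bool,
        "convention": str,
        "rmsd_chains": list,
        "rmsd_range": list,
        "contact_chains_a": list,
        "contact_chains_b": list,
        "contact_cutoff": float,
        "salt_bridge_cutoff": float,
        "rings": list,
        "ring_fixture": str,
    },
}


def _check_keys(data: dict, schema: dict, path: str = "") -> None:
    for key, value in data.items():
        if key not in schema:
            raise ValidationError(f"unknown config key {path + key!r}")
        expected = schema[key]
        if isinstance(expected, dict) and expected is not dict:
            if not isinstance(value, dict):
                raise ValidationError(f"config key {path + key!r} must be a table")
            if expected:  # typed sub-schema
                _check_keys(value, expected, path + key + ".")
        elif expected in (int, float):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValidationError(f"config key {path + key!r} must be a number")
        elif expected is bool:
            if not isinstance(value, bool):
                raise ValidationError(f"config key {path + key!r} must be a boolean")
        elif expected is str:
            if not isinstance(value, str):
                raise ValidationError(f"config key {path + key!r} must be a string")
        elif expected is list:
            if not isinstance(value, list):
                raise ValidationError(f"config key {path + key!r} must be a list")


@dataclass
class AnalysisConfig:
    """Validated analysis configuration (see the TOML schema in docs)."""

    seed: int = 0
    output_dir: str = "."
    topology: dict = field(default_factory=dict)
    capsid: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(source: str | Path | dict) -> AnalysisConfig:
    """Load and strictly validate a TOML config (path or pre-parsed dict)."""
    if isinstance(source, dict):
        data = source
    else:
        with open(source, "rb") as fh:
            data = tomllib.load(fh)
    _check_keys(data, {k: v for k, v in _SCHEMA.items()})
    cfg = AnalysisConfig(
        seed=data.get("seed", 0),
        output_dir=data.get("output_dir", "."),
        topology=data.get("topology", {}),
        capsid=data.get("capsid", {}),
        raw=data,
    )
    logger.info("config loaded (hash %s)", cfg.config_hash)
    return cfg


# ---------------------------------------------------------------------------


def _topology_inputs(cfg: AnalysisConfig):
    t = cfg.topology
    if not t:
        raise ValidationError("config has no [topology] section")
    if "structure" in t:
        structure = read_structure(t["structure"])
        if "partition" not in t:
            raise ValidationError("[topology] with a structure path needs a partition")
        boundaries = [(lab, (int(lo), int(hi))) for lab, lo, hi in t["partition"]]
        chain_length = int(t.get("chain_length", max(hi for _, (_, hi) in boundaries)))
        chain_id = structure.chains[0].chain_id
        partition = fold_topology.make_partition(chain_length, boundaries, chain_id)
    else:
        fixture = dict(t.get("fixture", {}))
        fixture.setdefault("seed", cfg.seed)
        structure, partition = synthetic.make_three_element_fold(**fixture)
    return structure, partition


def topology_report(config: AnalysisConfig | dict | str | Path) -> Report:
    """Enumerate, measure and prune Johnson-fold topologies for one chain."""
    cfg = config if isinstance(config, AnalysisConfig) else load_config(config)
    structure, partition = _topology_inputs(cfg)
    t = cfg.topology
    d_max = float(t.get("d_max", fold_topology.DEFAULT_D_MAX))
    orders = fold_topology.enumerate_orders(partition)
    feasible = fold_topology.feasible_orders(structure, partition, d_max)
    feasible_set = {o.labels for o in feasible}
    rows = []
    for order in orders:
        table = fold_topology.junction_distances(structure, partition, order, d_max)
        for j in table.junctions:
            rows.append(
                {
                    "order": str(order),
                    "junction": f"{j.preceding}->{j.following}",
                    "distance_A": round(j.distance, 3),
                    "feasible": j.feasible,
                    "order_feasible": order.labels in feasible_set,
                    "provenance": "fold_topology.junction_distances",
                }
            )
    report = Report(name="topology")
    report.tables["junctions"] = pd.DataFrame(rows)
    report.summary_lines.append(
        f"{len(feasible)} feasible of {len(orders)} topologies at d_max {d_max} A: "
        + ", ".join(str(o) for o in feasible)
    )
    if "compare_order" in t:
        comp = fold_topology.TopologyOrder(tuple(t["compare_order"]))
        relation = fold_topology.classify_relation(partition.native_order, comp)
        report.tables["classification"] = pd.DataFrame(
            [
                {
                    "order_a": str(partition.native_order),
                    "order_b": str(comp),
                    "relation": relation,
                    "provenance": "fold_topology.classify_relation",
                }
            ]
        )
        report.summary_lines.append(
            f"{partition.native_order} vs {comp}: {relation}"
        )
    if "permutant_order" in t:
        order = fold_topology.TopologyOrder(tuple(t["permutant_order"]))
        if "sequence_fasta" in t:
            sequence = next(iter(read_fasta(t["sequence_fasta"]).values()))
        else:
            chain_len = max(hi for _, (_, hi) in partition.elements)
            sequence = synthetic.make_sequence(chain_len, seed=cfg.seed)
        design = fold_topology.design_permutant(sequence, partition, order)
        report.tables["permutant_map"] = pd.DataFrame(
            [
                {
                    "position": i + 1,
                    "source_element": lab,
                    "source_seq_id": sid,
                    "residue": design.sequence[i],
                    "provenance": "fold_topology.design_permutant",
                }
                for i, (lab, sid) in enumerate(design.segment_map)
            ]
        )
        report.summary_lines.append(
            f"permutant {order}: {len(design.sequence)} residues"
        )
    logger.info("topology report: %s", report.summary_lines[0])
    return report


def _capsid_inputs(cfg: AnalysisConfig) -> Structure:
    c = cfg.capsid
    if "structure" in c:
        return read_structure(c["structure"])
    fixture = dict(c.get("fixture", {}))
    fixture.setdefault("seed", cfg.seed)
    return synthetic.make_toy_capsid(**fixture)


def capsid_report(config: AnalysisConfig | dict | str | Path) -> Report:
    """Census, expansion, diameter, conformer RMSDs, interfaces, chainmail."""
    cfg = config if isinstance(config, AnalysisConfig) else load_config(config)
    c = cfg.capsid
    if not c:
        raise ValidationError("config has no [capsid] section")
    report = Report(name="capsid")
    structure = _capsid_inputs(cfg)

    h, k = int(c.get("h", 1)), int(c.get("k", 2))
    t = capsid_lattice.t_number(h, k)
    census = capsid_lattice.capsid_census(t)
    report.tables["census"] = pd.DataFrame(
        [{"h": h, "k": k, "t_number": t, **census, "provenance": "capsid_lattice.capsid_census"}]
    )
    report.summary_lines.append(
        f"T = {t} lattice: {census['subunits']} subunits, {census['pentons']} pentons, "
        f"{census['hexons']} hexons, {census['subunits_per_asym_unit']} per asymmetric unit"
    )

    if c.get("expand", False):
        ops = capsid_lattice.icosahedral_operators(c.get("convention", "I222"))
        structure = capsid_lattice.expand_asymmetric_unit(structure, ops)
        diameter = capsid_lattice.max_diameter(structure)
        report.summary_lines.append(
            f"expanded to {len(structure.chains)} chains; max diameter {diameter:.1f} A"
        )
        report.tables["capsid"] = pd.DataFrame(
            [
                {
                    "chains": len(structure.chains),
                    "atoms": structure.n_atoms(),
                    "max_diameter_A": round(diameter, 2),
                    "provenance": "capsid_lattice.expand_asymmetric_unit/max_diameter",
                }
            ]
        )

    if "rmsd_chains" in c:
        lo, hi = (int(v) for v in c.get("rmsd_range", [1, 10**6]))
        mat, labels = conformer_rmsd_matrix(
            structure, c["rmsd_chains"], (lo, hi), BACKBONE_ATOMS
        )
        df = pd.DataFrame(mat, columns=labels)
        df.insert(0, "chain", labels)
        df["provenance"] = "structures.pairwise_rmsd"
        report.tables["conformer_rmsd"] = df
        report.summary_lines.append(
            f"conformer RMSD over {len(labels)} chains: max {float(np.max(mat)):.3f} A"
        )

    if "contact_chains_a" in c and "contact_chains_b" in c:
        cutoff = float(c.get("contact_cutoff", 4.0))
        contacts = interfaces.find_contacts(
            structure, set(c["contact_chains_a"]), set(c["contact_chains_b"]), cutoff
        )
        report.tables["contacts"] = pd.DataFrame(
            [
                {
                    "chain_a": x.chain_a, "seq_id_a": x.seq_id_a, "atom_a": x.atom_a,
                    "chain_b": x.chain_b, "seq_id_b": x.seq_id_b, "atom_b": x.atom_b,
                    "distance_A": round(x.distance, 3), "category": "contact",
                    "provenance": "interfaces.find_contacts",
                }
                for x in contacts
            ]
        )
        report.summary_lines.append(f"{len(contacts)} contacts at {cutoff} A")
        bridges = interfaces.find_salt_bridges(
            structure, float(c.get("salt_bridge_cutoff", 4.0))
        )
        report.tables["salt_bridges"] = pd.DataFrame(
            [
                {
                    "chain_a": x.basic_chain, "seq_id_a": x.basic_seq_id, "atom_a": x.basic_atom,
                    "chain_b": x.acidic_chain, "seq_id_b": x.acidic_seq_id, "atom_b": x.acidic_atom,
                    "distance_A": round(x.distance, 3), "category": "salt_bridge",
                    "provenance": "interfaces.find_salt_bridges",
                }
                for x in bridges
            ]
        )
        report.summary_lines.append(f"{len(bridges)} salt bridges")

    rings = None
    if "ring_fixture" in c:
        rings = synthetic.make_ring_set(c["ring_fixture"], seed=cfg.seed)
    elif "rings" in c:
        rings = [
            chainmail.build_ring(
                structure,
                [(m[0], (int(m[1]), int(m[2]))) for m in spec["members"]],
                label=spec.get("label", f"ring{i + 1}"),
            )
            for i, spec in enumerate(c["rings"])
        ]
    if rings is not None:
        graph = chainmail.catenation_graph(rings)
        report.tables["catenation"] = pd.DataFrame(
            [
                {
                    "ring_a": a, "ring_b": b,
                    "linking_number": d["linking_number"],
                    "provenance": "chainmail.linking_number",
                }
                for a, b, d in graph.graph.edges(data=True)
            ]
        )
        report.summary_lines.append(
            f"catenation: {graph.n_rings} rings, {graph.n_links} links, "
            f"{'one interlocked network' if graph.is_single_component else 'fragmented'}"
        )
    logger.info("capsid report: %d tables", len(report.tables))
    return report
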