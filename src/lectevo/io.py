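"""Readers and writers for the formats the pipeline exchanges.

Sequences travel as gapped FASTA alignments whose reference sequence is
gap-free (its columns define the numbering); region maps and hydropathy
scales are YAML; K_d tables and occupancy matrices are CSV/TSV; toy
trajectories are multi-model PDB; networks export to edge-list TSV and
GraphML.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .binding import KdTable
from .hbnet import CooperativityNetwork, OccupancyMatrix, TrajectoryFrames
from .sequences import AlignedSequence, RegionDefinition

__all__ = [
    "read_alignment_fasta",
    "write_fasta",
    "load_region_config",
    "load_hydropathy_scale",
    "load_glycan_annotations",
    "read_occupancy_tsv",
    "write_occupancy_tsv",
    "write_multimodel_pdb",
    "read_multimodel_pdb",
    "write_network",
    "packaged_path",
    "load_packaged_kd_table",
    "load_packaged_printed_table",
    "load_packaged_sequences",
    "load_packaged_region_config",
]

_DATA = importlib.resources.files("lectevo") / "data"


def packaged_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    return Path(str(_DATA / name))


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def read_alignment_fasta(path, reference_id: str) -> dict[str, AlignedSequence]:
    """Read a gapped FASTA alignment keyed to a gap-free reference.

    Column ``i`` of the alignment is reference position ``i + 1``; the
    reference record must contain no gaps.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if reference_id not in records:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref = records[reference_id]
    if "-" in ref:
        raise ValueError("reference sequence must be gap-free")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ValueError("alignment records differ in length")
    return {
        rid: AlignedSequence.from_gapped(rid, gapped) for rid, gapped in records.items()
    }


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in sequences.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def load_region_config(path) -> dict:
    """Region map plus graft-component and MD-group metadata.

    Returns a dict with keys: ``reference``, ``regions`` (name ->
    RegionDefinition), ``graft_components``, ``component_order``,
    ``ligand_residues``, ``md_loops``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    regions = {
        name: RegionDefinition(name, int(lo), int(hi))
        for name, (lo, hi) in raw["regions"].items()
    }
    if len(regions) != len(raw["regions"]):
        raise ValueError("duplicate region names")
    return {
        "reference": raw.get("reference"),
        "regions": regions,
        "graft_components": raw.get("graft_components", {}),
        "component_order": raw.get("component_order", []),
        "ligand_residues": {
            int(k): v for k, v in raw.get("ligand_residues", {}).items()
        },
        "md_loops": raw.get("md_loops", []),
    }


def load_hydropathy_scale(path) -> dict[str, float]:
    with open(path) as fh:
        scale = yaml.safe_load(fh)
    scale = {str(k): float(v) for k, v in scale.items()}
    if len(scale) != 20:
        raise ValueError("hydropathy scale must cover all 20 residues")
    return scale


def load_glycan_annotations(path) -> dict[str, set[str]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {str(k): set(v or []) for k, v in raw.items()}


# ---------------------------------------------------------------------------
# Occupancy matrices
# ---------------------------------------------------------------------------

def write_occupancy_tsv(occ: OccupancyMatrix, path) -> None:
    df = pd.DataFrame(occ.data, index=list(occ.bonds))
    df.index.name = f"bond[interval_ps={occ.interval_ps:g}]"
    df.to_csv(path, sep="\t")


def read_occupancy_tsv(path) -> OccupancyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    name = df.index.name or ""
    interval = 10.0
    if "interval_ps=" in name:
        interval = float(name.split("interval_ps=")[1].rstrip("]"))
    return OccupancyMatrix(
        bonds=tuple(df.index), data=df.to_numpy(dtype=np.uint8), interval_ps=interval
    )


# ---------------------------------------------------------------------------
# Toy trajectories (multi-model PDB)
# ---------------------------------------------------------------------------

def write_multimodel_pdb(frames: TrajectoryFrames, path) -> None:
    atoms = frames.atoms
    with open(path, "w") as fh:
        fh.write(f"REMARK interval_ps {frames.interval_ps:g}\n")
        for f in range(frames.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, row in enumerate(atoms.itertuples(index=False)):
                x, y, z = frames.coords[f, i]
                name = row.name if len(row.name) < 4 else row.name[:4]
                fh.write(
                    f"ATOM  {i + 1:5d} {name:^4s} {row.resname:>3s} {row.chain:1s}"
                    f"{row.resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {row.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_multimodel_pdb(path, interval_ps: float | None = None) -> TrajectoryFrames:
    """Load a multi-model PDB as a trajectory (models are snapshots)."""
    import warnings

    import MDAnalysis as mda

    if interval_ps is None:
        interval_ps = 10.0
        with open(path) as fh:
            for line in fh:
                if line.startswith("REMARK interval_ps"):
                    interval_ps = float(line.split()[-1])
                    break
                if line.startswith(("ATOM", "MODEL")):
                    break
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        atoms = pd.DataFrame(
            {
                "name": u.atoms.names,
                "element": [
                    e if e else _guess_element(n)
                    for e, n in zip(_elements_or_blank(u), u.atoms.names)
                ],
                "resid": u.atoms.resids,
                "resname": u.atoms.resnames,
                "chain": [s if s else "A" for s in u.atoms.chainIDs]
                if hasattr(u.atoms, "chainIDs")
                else ["A"] * len(u.atoms),
            }
        )
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
    return TrajectoryFrames(coords.astype(float), atoms, interval_ps)


def _elements_or_blank(u) -> list[str]:
    try:
        return [str(e).strip() for e in u.atoms.elements]
    except Exception:
        return [""] * len(u.atoms)


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def write_network(network: CooperativityNetwork, edgelist_path=None, graphml_path=None) -> None:
    if edgelist_path is not None:
        network.to_edgelist().to_csv(edgelist_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(network.graph, str(graphml_path))


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def load_packaged_kd_table() -> KdTable:
    """The packaged lectin x glycan K_d fixture with suppression flags."""
    return KdTable.from_csv(
        packaged_path("kd_table.csv"), packaged_path("kd_table_suppressed.csv")
    )


def load_packaged_printed_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Printed K_d strings and printed ratio strings for reconciliation."""
    kd = pd.read_csv(packaged_path("kd_table.csv"), index_col=0, dtype=str)
    kd.index = kd.index.astype(str)
    ratios = pd.read_csv(packaged_path("kd_printed_ratios.csv"), index_col=0, dtype=str)
    ratios.index = ratios.index.astype(str)
    return kd, ratios


def load_packaged_sequences() -> dict[str, AlignedSequence]:
    cfg = load_packaged_region_config()
    return read_alignment_fasta(packaged_path("sequences.fasta"), cfg["reference"])


def load_packaged_region_config() -> dict:
    return load_region_config(packaged_path("regions.yaml"))
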