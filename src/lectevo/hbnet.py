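"""Hydrogen-bond cooperativity networks from MD trajectories.

The chain is: detect per-snapshot H-bond presence (geometric criteria),
keep bonds with an overall formation rate in a 10-90% band (dropping the
transient and the permanent ones), average presence inside consecutive
200-ps time bins, correlate the bin-rate vectors of every bond pair
(Pearson product-moment), and average the coefficients within and between
structural-element groups (loops, inter-loop pairs, ligand contacts) into a
signed network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryFrames",
    "HBondDefinition",
    "OccupancyMatrix",
    "BinnedRates",
    "GroupAssignment",
    "CooperativityNetwork",
    "detect_hbonds",
    "overall_formation_rate",
    "filter_informative_bonds",
    "bin_formation_rates",
    "pairwise_correlation",
    "assign_groups",
    "group_average_correlation",
]

DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}
H_COVALENT_CUTOFF = 1.25  # Angstrom, hydrogen attachment to its heavy atom


@dataclass(frozen=True)
class TrajectoryFrames:
    """Snapshots of a constant atom set.

    coords: (n_frames, n_atoms, 3) in Angstrom. atoms: one row per atom
    with columns name, element, resid, resname, chain; resid is in the
    shared reference numbering.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    interval_ps: float

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table does not match coordinate array")
        if self.interval_ps <= 0:
            raise ValueError("snapshot interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class HBondDefinition:
    """Donor heavy atom / donor hydrogen / acceptor triple with a label."""

    donor_resid: int
    donor_atom: str
    donor_chain: str
    acceptor_resid: int
    acceptor_atom: str
    acceptor_chain: str
    donor_resname: str = ""
    acceptor_resname: str = ""
    donor_hydrogen: str | None = None

    def __post_init__(self) -> None:
        if (
            self.donor_resid == self.acceptor_resid
            and self.donor_chain == self.acceptor_chain
            and self.donor_atom == self.acceptor_atom
        ):
            raise ValueError("donor and acceptor must differ")

    @property
    def label(self) -> str:
        return (
            f"{self.donor_chain}:{self.donor_resname}{self.donor_resid}@{self.donor_atom}"
            f"->{self.acceptor_chain}:{self.acceptor_resname}{self.acceptor_resid}"
            f"@{self.acceptor_atom}"
        )


@dataclass(frozen=True)
class OccupancyMatrix:
    """Binary bond presence, bonds x snapshots."""

    bonds: tuple[str, ...]
    data: np.ndarray  # uint8, shape (n_bonds, n_snapshots)
    interval_ps: float

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.bonds):
            raise ValueError("data shape does not match bond labels")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")

    @property
    def n_snapshots(self) -> int:
        return self.data.shape[1]

    def row(self, bond: str) -> np.ndarray:
        try:
            i = self.bonds.index(bond)
        except ValueError:
            raise KeyError(f"unknown bond: {bond}") from None
        return self.data[i]


@dataclass(frozen=True)
class BinnedRates:
    """Per-bond formation rate within consecutive equal-size time bins."""

    bonds: tuple[str, ...]
    rates: np.ndarray  # float, shape (n_bonds, n_bins)
    bin_width_ps: float
    snapshots_per_bin: int

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]


@dataclass
class GroupAssignment:
    """bond label -> group label; unassigned bonds are recorded separately."""

    groups: dict[str, str] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for bond, group in self.groups.items():
            out.setdefault(group, []).append(bond)
        return out


@dataclass
class CooperativityNetwork:
    """Signed mean correlations between structural-element groups."""

    graph: nx.Graph
    n_undefined_pairs: int = 0

    def edge_r(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["r_mean"]

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {
                "group_a": a,
                "group_b": b,
                "r_mean": d["r_mean"],
                "n_pairs": d["n_pairs"],
                "sign": "+" if d["r_mean"] >= 0 else "-",
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _candidate_bonds(
    frames: TrajectoryFrames, distance_only: bool
) -> list[tuple[int, int | None, int]]:
    """(donor index, hydrogen index or None, acceptor index) candidates.

    Donors/acceptors are N or O atoms; in geometric mode a donor must have
    a hydrogen within covalent range in the first frame. Same-residue pairs
    are excluded.
    """
    atoms = frames.atoms
    heavy = atoms.index[atoms["element"].isin(DONOR_ACCEPTOR_ELEMENTS)].to_numpy()
    hydrogens = atoms.index[atoms["element"] == "H"].to_numpy()
    x0 = frames.coords[0]

    donor_h: dict[int, list[int]] = {i: [] for i in heavy}
    if not distance_only and hydrogens.size:
        d = np.linalg.norm(x0[heavy][:, None, :] - x0[hydrogens][None, :, :], axis=2)
        for hi, hj in zip(*np.nonzero(d <= H_COVALENT_CUTOFF)):
            donor_h[heavy[hi]].append(hydrogens[hj])

    key = atoms[["resid", "chain"]].apply(tuple, axis=1)
    candidates = []
    for di in heavy:
        h_atoms = donor_h[di] if not distance_only else [None]
        if not h_atoms:
            continue
        for ai in heavy:
            if ai == di or key[di] == key[ai]:
                continue
            for h in h_atoms:
                candidates.append((di, h, ai))
    return candidates


def detect_hbonds(
    frames: TrajectoryFrames,
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
    distance_only: bool = False,
    candidates: Sequence[HBondDefinition] | None = None,
) -> tuple[list[HBondDefinition], OccupancyMatrix]:
    """Per-frame H-bond presence from geometric criteria.

    A bond is present in a frame iff the donor-acceptor distance is
    <= ``d_cut`` and (unless ``distance_only``) the donor-H...acceptor angle
    at the hydrogen is >= ``angle_cut`` degrees. The returned bond list is
    the union over frames (bonds present in at least one frame).
    """
    atoms = frames.atoms
    if candidates is None:
        triples = _candidate_bonds(frames, distance_only)
    else:
        triples = [_resolve_candidate(atoms, c, distance_only) for c in candidates]
    if not triples:
        raise ValueError("no donor/acceptor atoms resolvable")

    di = np.array([t[0] for t in triples])
    ai = np.array([t[2] for t in triples])
    xyz = frames.coords
    dist = np.linalg.norm(xyz[:, di, :] - xyz[:, ai, :], axis=2)  # (F, C)
    present = dist <= d_cut
    if not distance_only:
        hi = np.array([t[1] for t in triples])
        v1 = xyz[:, di, :] - xyz[:, hi, :]
        v2 = xyz[:, ai, :] - xyz[:, hi, :]
        cosang = np.einsum("fij,fij->fi", v1, v2)
        norms = np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.clip(cosang / np.where(norms == 0, np.nan, norms), -1, 1)
        angles = np.degrees(np.arccos(cosang))
        present &= angles >= angle_cut

    keep = present.any(axis=0)
    bonds: list[HBondDefinition] = []
    for j in np.nonzero(keep)[0]:
        d_idx, h_idx, a_idx = triples[j]
        da, aa = atoms.iloc[d_idx], atoms.iloc[a_idx]
        bonds.append(
            HBondDefinition(
                donor_resid=int(da["resid"]),
                donor_atom=str(da["name"]),
                donor_chain=str(da["chain"]),
                acceptor_resid=int(aa["resid"]),
                acceptor_atom=str(aa["name"]),
                acceptor_chain=str(aa["chain"]),
                donor_resname=str(da.get("resname", "")),
                acceptor_resname=str(aa.get("resname", "")),
                donor_hydrogen=(
                    None if h_idx is None else str(atoms.iloc[h_idx]["name"])
                ),
            )
        )
    occ = OccupancyMatrix(
        bonds=tuple(b.label for b in bonds),
        data=present[:, keep].T.astype(np.uint8),
        interval_ps=frames.interval_ps,
    )
    return bonds, occ


def _resolve_candidate(
    atoms: pd.DataFrame, bond: HBondDefinition, distance_only: bool
) -> tuple[int, int | None, int]:
    def find(resid, chain, name) -> int:
        sel = atoms.index[
            (atoms["resid"] == resid) & (atoms["chain"] == chain) & (atoms["name"] == name)
        ]
        if len(sel) != 1:
            raise ValueError(f"cannot resolve atom {chain}:{resid}@{name}")
        return int(sel[0])

    d = find(bond.donor_resid, bond.donor_chain, bond.donor_atom)
    a = find(bond.acceptor_resid, bond.acceptor_chain, bond.acceptor_atom)
    h = None
    if not distance_only:
        if bond.donor_hydrogen is None:
            raise ValueError(f"candidate {bond.label} lacks a donor hydrogen")
        h = find(bond.donor_resid, bond.donor_chain, bond.donor_hydrogen)
    return d, h, a


# ---------------------------------------------------------------------------
# Rates, filtering, binning, correlation
# ---------------------------------------------------------------------------

def overall_formation_rate(occ: OccupancyMatrix, bond: str) -> float:
    """Fraction of analysed snapshots in which the bond is present."""
    if occ.n_snapshots == 0:
        raise ValueError("empty occupancy matrix")
    return float(occ.row(bond).mean())


def filter_informative_bonds(
    occ: OccupancyMatrix, low: float = 0.10, high: float = 0.90
) -> OccupancyMatrix:
    """Keep bonds whose overall formation rate lies in [low, high].

    Drops the transiently formed (rate < low) and the permanently formed
    (rate > high) bonds; bond order is preserved.
    """
    if not (0 <= low < high <= 1):
        raise ValueError("require 0 <= low < high <= 1")
    if len(occ.bonds) == 0:
        return occ
    rates = occ.data.mean(axis=1)
    keep = (rates >= low) & (rates <= high)
    return OccupancyMatrix(
        bonds=tuple(b for b, k in zip(occ.bonds, keep) if k),
        data=occ.data[keep],
        interval_ps=occ.interval_ps,
    )


def bin_formation_rates(
    occ: OccupancyMatrix,
    bin_width_ps: float = 200.0,
    analysis_span_ps: float = 3000.0,
) -> BinnedRates:
    """Mean occupancy within consecutive equal bins of the truncated series.

    The series is truncated to the first ``analysis_span_ps``, then split
    into bins of ``bin_width_ps`` (a multiple of the snapshot interval); a
    trailing partial bin is dropped. Defaults give 15 bins of 20 snapshots
    for 10-ps snapshots.
    """
    per_bin_f = bin_width_ps / occ.interval_ps
    if abs(per_bin_f - round(per_bin_f)) > 1e-9:
        raise ValueError("bin width must be a multiple of the snapshot interval")
    per_bin = int(round(per_bin_f))
    n_take = min(occ.n_snapshots, int(analysis_span_ps / occ.interval_ps))
    n_bins = n_take // per_bin
    if n_bins == 0:
        raise ValueError("analysis span shorter than one bin")
    trimmed = occ.data[:, : n_bins * per_bin]
    rates = trimmed.reshape(len(occ.bonds), n_bins, per_bin).mean(axis=2)
    return BinnedRates(occ.bonds, rates, bin_width_ps, per_bin)


def pairwise_correlation(rates: BinnedRates) -> pd.DataFrame:
    """Pearson product-moment correlation of bin-rate vectors per bond pair.

    r = sum((x_i - xbar)(y_i - ybar)) / sqrt(sum((x_i - xbar)^2) *
    sum((y_i - ybar)^2)) over time bins i. Pairs where either vector has
    zero variance are NaN (undefined) and are excluded from downstream
    averaging.
    """
    if rates.n_bins < 3:
        raise ValueError("need at least 3 bins to correlate")
    x = rates.rates - rates.rates.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", x, x)
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (x @ x.T) / denom
    corr[:, ss == 0] = np.nan
    corr[ss == 0, :] = np.nan
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=list(rates.bonds), columns=list(rates.bonds))


# ---------------------------------------------------------------------------
# Grouping and network assembly
# ---------------------------------------------------------------------------

def assign_groups(
    bonds: Iterable[HBondDefinition],
    loop_ranges: Mapping[str, tuple[int, int]],
    ligand_residues: Mapping[int, str] | None = None,
    ligand_resnames: Iterable[str] = ("LAC", "GAL", "GLC", "BGC", "LIG"),
    pair_separator: str = "-",
) -> GroupAssignment:
    """Assign each bond to one structural-element group.

    Both residues inside one loop -> that loop; residues in two different
    loops -> the inter-loop pair group (names sorted); a bond between a
    ligand residue (recognised by resname) and a listed binding residue ->
    its ligand group (e.g. Lac-R28). Anything else is tagged unassigned.
    """
    if ligand_residues is None:
        ligand_residues = {28: "Lac-R28", 47: "Lac-R47"}
    ranges = sorted(loop_ranges.items(), key=lambda kv: kv[1])
    for (na, (sa, ea)), (nb, (sb, eb)) in zip(ranges, ranges[1:]):
        if sb <= ea:
            raise ValueError(f"overlapping loop ranges: {na} and {nb}")
    ligand_resnames = set(ligand_resnames)

    def loop_of(resid: int) -> str | None:
        for name, (s, e) in loop_ranges.items():
            if s <= resid <= e:
                return name
        return None

    assignment = GroupAssignment()
    for bond in bonds:
        d_lig = bond.donor_resname in ligand_resnames
        a_lig = bond.acceptor_resname in ligand_resnames
        group: str | None = None
        if d_lig != a_lig:
            protein_resid = bond.acceptor_resid if d_lig else bond.donor_resid
            group = ligand_residues.get(protein_resid)
        elif not d_lig and not a_lig:
            ld, la = loop_of(bond.donor_resid), loop_of(bond.acceptor_resid)
            if ld is not None and la is not None:
                group = ld if ld == la else pair_separator.join(sorted((ld, la)))
        if group is None:
            assignment.unassigned.append(bond.label)
        else:
            assignment.groups[bond.label] = group
    return assignment


def group_average_correlation(
    corr: pd.DataFrame, assignment: GroupAssignment | Mapping[str, str]
) -> CooperativityNetwork:
    """Average pairwise r within and between groups into a signed network.

    The edge between groups A and B carries the mean of the defined r over
    all bond pairs (a in A, b in B, a != b); A == B gives the within-group
    self-edge. Undefined (NaN) pairs are excluded and counted; an edge with
    no defined pair is omitted.
    """
    mapping = assignment.groups if isinstance(assignment, GroupAssignment) else dict(assignment)
    members: dict[str, list[str]] = {}
    for bond, group in mapping.items():
        if bond in corr.index:
            members.setdefault(group, []).append(bond)
    empty = [g for g, m in members.items() if not m]
    if empty or not members:
        raise ValueError(f"groups without bonds: {empty or 'all'}")

    graph = nx.Graph()
    graph.add_nodes_from(members)
    n_undefined = 0
    names = sorted(members)
    for i, ga in enumerate(names):
        for gb in names[i:]:
            vals = []
            for a in members[ga]:
                for b in members[gb]:
                    if ga == gb and a >= b:
                        continue
                    r = corr.loc[a, b]
                    if np.isnan(r):
                        n_undefined += 1
                    else:
                        vals.append(float(r))
            if vals:
                graph.add_edge(ga, gb, r_mean=float(np.mean(vals)), n_pairs=len(vals))
    return CooperativityNetwork(graph, n_undefined_pairs=n_undefined)
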