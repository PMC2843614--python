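"""Seeded generators for every fixture the analysis stages consume.

Each generator returns the data together with its ground truth so recovery
tests are sharp: binary H-bond series come from a thresholded latent
Gaussian factor model (planted correlations map analytically to loadings),
inactivation curves from a logistic decay with known midpoint, K_d tables
from planted multiplicative region effects, and toy trajectories from
explicit donor-acceptor distance schedules with collinear hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import KdTable
from .hbnet import OccupancyMatrix, TrajectoryFrames
from .thermo import InactivationCurve

__all__ = [
    "OccupancySpec",
    "CurveSpec",
    "KdTableSpec",
    "ToyTrajectorySpec",
    "OccupancyTruth",
    "gen_occupancy",
    "gen_inactivation_curve",
    "gen_kd_table",
    "gen_toy_trajectory",
    "two_factor_occupancy_spec",
]


# ---------------------------------------------------------------------------
# H-bond occupancy with planted factor structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccupancySpec:
    """Latent-factor model for binary bond series.

    groups: group label -> bond count. factor_of: group -> factor index.
    loadings: group -> loading in [-1, 1] on its factor. factor_corr:
    inter-factor correlation matrix (identity if omitted). rate_targets:
    group -> marginal formation rate in (0, 1) (0.5 default). ar_phi sets
    the factors' AR(1) autocorrelation so that 200-ps bins retain signal.
    """

    groups: Mapping[str, int]
    factor_of: Mapping[str, int]
    loadings: Mapping[str, float]
    factor_corr: np.ndarray | None = None
    rate_targets: Mapping[str, float] = field(default_factory=dict)
    n_snapshots: int = 3000
    interval_ps: float = 10.0
    ar_phi: float = 0.9
    seed: int = 0

    def n_factors(self) -> int:
        return max(self.factor_of.values()) + 1

    def validate(self) -> None:
        for g, lam in self.loadings.items():
            if not -1 <= lam <= 1:
                raise ValueError(f"loading of {g} outside [-1, 1]")
        for g, p in self.rate_targets.items():
            if not 0 < p < 1:
                raise ValueError(f"rate target of {g} outside (0, 1)")
        if set(self.groups) != set(self.factor_of) or set(self.groups) != set(self.loadings):
            raise ValueError("groups, factor_of and loadings must share keys")


@dataclass
class OccupancyTruth:
    assignment: dict[str, str]  # bond label -> group
    factors: np.ndarray  # (n_snapshots, n_factors)
    rates: dict[str, float]  # bond label -> target marginal rate


def gen_occupancy(spec: OccupancySpec) -> tuple[OccupancyMatrix, OccupancyTruth]:
    """Binary series via probit-thresholded latent factors.

    Bond latent: z = loading * F_group + sqrt(1 - loading^2) * eps with
    AR(1) factors of unit stationary variance; occupancy thresholds z at
    its empirical target quantile, so each marginal rate matches its target
    to within 1/n_snapshots while group correlation signs follow the
    loadings and the inter-factor correlation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k = spec.n_factors()
    corr = np.eye(k) if spec.factor_corr is None else np.asarray(spec.factor_corr, float)
    if corr.shape != (k, k):
        raise ValueError("factor_corr shape does not match the number of factors")
    chol = np.linalg.cholesky(corr)

    # AR(1) factors, stationary unit variance, cross-correlated innovations
    t_n = spec.n_snapshots
    innov = rng.standard_normal((t_n, k)) @ chol.T
    factors = np.empty((t_n, k))
    factors[0] = innov[0]
    phi = spec.ar_phi
    scale = np.sqrt(1 - phi**2)
    for t in range(1, t_n):
        factors[t] = phi * factors[t - 1] + scale * innov[t]

    labels: list[str] = []
    rows: list[np.ndarray] = []
    truth = OccupancyTruth(assignment={}, factors=factors, rates={})
    for group in spec.groups:
        lam = spec.loadings[group]
        target = spec.rate_targets.get(group, 0.5)
        f = factors[:, spec.factor_of[group]]
        for j in range(spec.groups[group]):
            eps = rng.standard_normal(t_n)
            z = lam * f + np.sqrt(1 - lam**2) * eps
            cut = np.quantile(z, target)
            row = (z <= cut).astype(np.uint8)
            label = f"{group}/b{j}"
            labels.append(label)
            rows.append(row)
            truth.assignment[label] = group
            truth.rates[label] = target
    occ = OccupancyMatrix(tuple(labels), np.vstack(rows), spec.interval_ps)
    return occ, truth


def two_factor_occupancy_spec(seed: int = 0, n_snapshots: int = 3000) -> OccupancySpec:
    """Default planted structure mirroring the loop-network finding.

    Factor 0 drives the L3/L5 bonds and the ligand contacts; factor 1
    drives L2/L4/L6; the factors are anti-correlated, so the recovered
    network should show positive edges within {L3, L5, Lac-*} and negative
    edges between {L2, L4, L6} and the ligand groups.
    """
    groups = {"L2": 3, "L3": 4, "L4": 3, "L5": 4, "L6": 3, "Lac-R28": 2, "Lac-R47": 2}
    factor_of = {"L3": 0, "L5": 0, "Lac-R28": 0, "Lac-R47": 0, "L2": 1, "L4": 1, "L6": 1}
    # moderate loadings on slow factors: the planted signal then lives in
    # the temporal structure (bin-level co-movement) rather than in
    # same-snapshot coupling, so a global time-shuffle erases it
    loadings = {g: 0.55 for g in groups}
    rates = {"L2": 0.35, "L3": 0.5, "L4": 0.6, "L5": 0.45, "L6": 0.55,
             "Lac-R28": 0.5, "Lac-R47": 0.4}
    corr = np.array([[1.0, -0.75], [-0.75, 1.0]])
    return OccupancySpec(
        groups=groups,
        factor_of=factor_of,
        loadings=loadings,
        factor_corr=corr,
        rate_targets=rates,
        n_snapshots=n_snapshots,
        ar_phi=0.95,
        seed=seed,
    )


def gen_frontal_elution(kd_um: float, bt_nmol: float = 1.0, v0_ml: float = 1.0):
    """Frontal-elution readout that a column with the given K_d would show.

    Inverse of the frontal relation K_d = Bt/(V - V0): V = V0 + Bt/K_d.
    """
    from .binding import FrontalElution

    if kd_um <= 0:
        raise ValueError("K_d must be positive")
    return FrontalElution(v=v0_ml + bt_nmol / kd_um, v0=v0_ml, bt=bt_nmol)


# ---------------------------------------------------------------------------
# Thermal inactivation curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSpec:
    """Logistic decay with midpoint/steepness plus truncated noise."""

    midpoint: float
    steepness: float = 0.8
    temperatures: Sequence[float] = tuple(range(38, 63, 2))
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.temperatures, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be increasing")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def gen_inactivation_curve(spec: CurveSpec) -> InactivationCurve:
    """activity(T) = 1/(1 + exp(steepness * (T - midpoint))), clipped to [0, 1]."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.temperatures, float)
    act = 1.0 / (1.0 + np.exp(spec.steepness * (t - spec.midpoint)))
    if spec.noise_sd > 0:
        act = act + rng.normal(0.0, spec.noise_sd, size=act.shape)
    act = np.clip(act, 0.0, 1.0)
    return InactivationCurve(tuple(t), tuple(float(a) for a in act))


# ---------------------------------------------------------------------------
# K_d tables with planted region effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KdTableSpec:
    """Planted multiplicative affinity effects of grafted regions.

    baseline: glycan -> K_d (uM) of the ungrafted base lectin.
    glycan_class: glycan -> class label. lectin_regions: lectin -> grafted
    region names. effects: region -> {class -> fold affinity gain}
    (K_d divides by the product of applicable folds). missing: explicit
    (lectin, glycan) no-binding cells.
    """

    baseline: Mapping[str, float]
    glycan_class: Mapping[str, str]
    lectin_regions: Mapping[str, Sequence[str]]
    effects: Mapping[str, Mapping[str, float]]
    noise_sd: float = 0.0  # lognormal sigma
    missing: Sequence[tuple[str, str]] = ()
    seed: int = 0

    def validate(self) -> None:
        if any(v <= 0 for v in self.baseline.values()):
            raise ValueError("baseline K_d must be positive")
        for region, by_class in self.effects.items():
            if any(f <= 0 for f in by_class.values()):
                raise ValueError(f"effects of {region} must be positive")


def gen_kd_table(spec: KdTableSpec) -> tuple[KdTable, pd.DataFrame]:
    """K_d = baseline / prod(region effects on the glycan's class) * noise.

    Returns the table and the ground-truth fold-effect matrix
    (lectin x glycan, the noise-free total fold applied to the baseline).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    glycans = list(spec.baseline)
    lectins = list(spec.lectin_regions)
    kd = pd.DataFrame(index=pd.Index(glycans, name="glycan"), columns=lectins, dtype=float)
    folds = pd.DataFrame(1.0, index=kd.index, columns=lectins)
    missing = set(map(tuple, spec.missing))
    for lectin in lectins:
        for glycan in glycans:
            fold = 1.0
            for region in spec.lectin_regions[lectin]:
                fold *= spec.effects.get(region, {}).get(spec.glycan_class[glycan], 1.0)
            folds.loc[glycan, lectin] = fold
            if (lectin, glycan) in missing:
                kd.loc[glycan, lectin] = np.nan
                continue
            noise = np.exp(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 1.0
            kd.loc[glycan, lectin] = spec.baseline[glycan] / fold * noise
    return KdTable(kd), folds


# ---------------------------------------------------------------------------
# Toy coordinate trajectories with closed-form H-bond truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyTrajectorySpec:
    """Donor-acceptor pairs whose distances follow explicit schedules.

    schedules: (n_pairs, n_frames) distances in Angstrom. Each pair is
    isolated in space (donor N + its H + acceptor O on a line, pairs offset
    far apart), so geometric detection has closed-form truth.
    """

    schedules: np.ndarray
    interval_ps: float = 10.0
    pair_spacing: float = 50.0

    def validate(self) -> None:
        s = np.asarray(self.schedules, float)
        if s.ndim != 2:
            raise ValueError("schedules must be (n_pairs, n_frames)")
        # below ~2.25 A the collinear hydrogen would sit within covalent
        # range of the acceptor and the closed-form truth breaks down
        if np.any(s <= 2.3):
            raise ValueError("scheduled distances must exceed 2.3 A")


def gen_toy_trajectory(
    spec: ToyTrajectorySpec, d_cut: float = 3.5
) -> tuple[TrajectoryFrames, np.ndarray]:
    """Frames realising the schedules exactly, plus the schedule-derived truth.

    Per pair i: donor N of residue 2i+1 at the pair origin, its hydrogen
    1.0 A towards the acceptor (angle exactly 180 degrees), acceptor O of
    residue 2i+2 at the scheduled distance. Truth is schedule <= d_cut.
    """
    spec.validate()
    sched = np.asarray(spec.schedules, float)
    n_pairs, n_frames = sched.shape
    records = []
    for i in range(n_pairs):
        base = i * spec.pair_spacing
        records.append({"name": "N", "element": "N", "resid": 2 * i + 1,
                        "resname": "DON", "chain": "A", "offset": base})
        records.append({"name": "H", "element": "H", "resid": 2 * i + 1,
                        "resname": "DON", "chain": "A", "offset": base})
        records.append({"name": "O", "element": "O", "resid": 2 * i + 2,
                        "resname": "ACC", "chain": "A", "offset": base})
    atoms = pd.DataFrame(records).drop(columns="offset")

    coords = np.zeros((n_frames, 3 * n_pairs, 3))
    for i in range(n_pairs):
        base = i * spec.pair_spacing
        coords[:, 3 * i, 0] = base  # donor N
        coords[:, 3 * i + 1, 0] = base + 1.0  # hydrogen, collinear
        coords[:, 3 * i + 2, 0] = base + sched[i]  # acceptor O
    frames = TrajectoryFrames(coords, atoms, spec.interval_ps)
    truth = (sched <= d_cut).astype(np.uint8)
    return frames, truth
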