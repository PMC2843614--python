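"""Comparative glycan-binding analysis over lectin x glycan K_d tables.

K_d values come from frontal affinity chromatography: the retardation of
the elution front on an immobilised-lectin column gives K_d = Bt/(V - V0)
in the ligand-excess regime. Cells with no detectable retardation are a
distinct no-binding state (never 0 or infinity). Relative binding activity
of a lectin against a reference is K_d(reference)/K_d(lectin) per glycan;
ratios of those between two glycans isolate specificity from affinity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FrontalElution",
    "KdTable",
    "RelativeActivity",
    "fac_kd",
    "relative_activity",
    "ratio_columns",
    "sugar_pair_ratio",
    "differential_features",
    "binding_loss_calls",
    "round_sig",
    "format_sig",
    "printed_value_interval",
    "diff_against_printed",
]

NO_BINDING = "-"


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, ndigits)


def format_sig(x: float, sig: int) -> str:
    """Format at ``sig`` significant figures without exponent notation."""
    if x == 0 or not math.isfinite(x):
        return str(x)
    ndigits = sig - 1 - math.floor(math.log10(abs(x)))
    y = round(x, ndigits)
    if ndigits <= 0:
        return str(int(y))
    return f"{y:.{ndigits}f}"


@dataclass(frozen=True)
class FrontalElution:
    """Frontal-chromatography readout for one lectin/glycan pair.

    v: elution front volume (mL); v0: front volume without retardation
    (mL); bt: immobilised ligand content (nmol).
    """

    v: float
    v0: float
    bt: float

    def __post_init__(self) -> None:
        if self.v0 < 0 or self.v < self.v0:
            raise ValueError("require V >= V0 >= 0")
        if self.bt <= 0:
            raise ValueError("Bt must be positive")


def fac_kd(elution: FrontalElution) -> float | None:
    """K_d (uM) from frontal analysis: Bt/(V - V0); nmol/mL gives uM.

    Zero retardation (V == V0) means no detectable binding and returns
    ``None`` rather than a numeric value.
    """
    dv = elution.v - elution.v0
    if dv == 0:
        return None
    return elution.bt / dv


class KdTable:
    """Lectin x glycan dissociation constants with explicit no-binding cells.

    Internally a glycan-indexed DataFrame (columns = lectins, NaN = no
    binding). ``suppressed`` marks cells whose K_d was measurable but whose
    binding activity is reported as undetectable (printed tables sometimes
    carry a K_d with a dash in every activity column); the ``as-printed``
    convention treats those as no-binding.
    """

    def __init__(
        self,
        kd: pd.DataFrame,
        suppressed: pd.DataFrame | None = None,
        method: str = "FAC",
    ) -> None:
        if kd.columns.duplicated().any() or kd.index.duplicated().any():
            raise ValueError("lectin and glycan labels must be unique")
        if (kd.to_numpy(dtype=float) <= 0).any():
            raise ValueError("K_d values must be positive where present")
        self.kd = kd.astype(float)
        if suppressed is None:
            suppressed = pd.DataFrame(False, index=kd.index, columns=kd.columns)
        self.suppressed = suppressed.reindex_like(kd).fillna(False).astype(bool)
        self.method = method

    @property
    def lectins(self) -> list[str]:
        return list(self.kd.columns)

    @property
    def glycans(self) -> list[str]:
        return list(self.kd.index)

    def values_for(self, lectin: str, convention: str = "strict") -> pd.Series:
        """K_d column with the chosen no-binding convention applied."""
        if lectin not in self.kd.columns:
            raise KeyError(f"unknown lectin: {lectin}")
        col = self.kd[lectin].copy()
        if convention == "as-printed":
            col[self.suppressed[lectin]] = np.nan
        elif convention != "strict":
            raise ValueError(f"unknown convention: {convention}")
        return col

    @classmethod
    def from_csv(cls, path, suppressed_path=None, **kwargs) -> "KdTable":
        kd = pd.read_csv(path, index_col=0, dtype=str, **kwargs)
        kd.index = kd.index.astype(str)
        values = kd.apply(lambda c: pd.to_numeric(c.replace(NO_BINDING, np.nan)))
        suppressed = None
        if suppressed_path is not None:
            sup = pd.read_csv(suppressed_path, index_col=0)
            sup.index = sup.index.astype(str)
            suppressed = sup.astype(bool)
        return cls(values, suppressed)

    def to_csv(self, path) -> None:
        out = self.kd.copy().astype(object)
        out[self.kd.isna()] = NO_BINDING
        out.to_csv(path)


@dataclass
class RelativeActivity:
    """Per-glycan binding activity of ``lectin`` relative to ``reference``."""

    lectin: str
    reference: str
    ratios: pd.Series  # K_d(reference)/K_d(lectin); NaN where undefined
    undefined: dict[str, str] = field(default_factory=dict)  # glycan -> missing side

    def defined(self) -> pd.Series:
        return self.ratios.dropna()


def relative_activity(
    table: KdTable,
    lectin: str,
    reference: str,
    convention: str = "strict",
) -> RelativeActivity:
    """Ratio K_d(reference)/K_d(lectin) per glycan.

    A no-binding cell on either side yields an undefined entry recording
    which side was missing; undefined entries are excluded from summaries.
    """
    kd_lec = table.values_for(lectin, convention)
    kd_ref = table.values_for(reference, convention)
    ratios = kd_ref / kd_lec
    undefined = {}
    for g in table.glycans:
        miss_l, miss_r = pd.isna(kd_lec[g]), pd.isna(kd_ref[g])
        if miss_l or miss_r:
            undefined[g] = (
                "both" if (miss_l and miss_r) else ("lectin" if miss_l else "reference")
            )
    return RelativeActivity(lectin, reference, ratios, undefined)


def ratio_columns(
    table: KdTable,
    references: Iterable[str],
    sig: int = 2,
    convention: str = "strict",
) -> pd.DataFrame:
    """Presentation table: per lectin, K_d plus one ratio column per reference.

    Ratios are rounded to ``sig`` significant figures at this layer only;
    undefined cells carry the no-binding marker.
    """
    references = list(references)
    blocks = {}
    for lectin in table.lectins:
        kd = table.values_for(lectin, convention)
        block = {"K_d (uM)": kd}
        for ref in references:
            rel = relative_activity(table, lectin, ref, convention)
            block[f"ratio to {ref}"] = rel.ratios.map(
                lambda x: np.nan if pd.isna(x) else round_sig(x, sig)
            )
        blocks[lectin] = pd.DataFrame(block)
    out = pd.concat(blocks, axis=1)
    out.index.name = "glycan"
    return out


def sugar_pair_ratio(
    table: KdTable,
    lectin: str,
    reference: str,
    glycan_a: str,
    glycan_b: str,
    convention: str = "strict",
) -> float | None:
    """Specificity shift between two glycans:

    [K_d(ref, a)/K_d(lectin, a)] / [K_d(ref, b)/K_d(lectin, b)],

    computed from the K_d cells directly (never from pre-rounded ratio
    columns). Returns ``None`` if any of the four cells is no-binding.
    """
    kd_lec = table.values_for(lectin, convention)
    kd_ref = table.values_for(reference, convention)
    cells = [kd_ref.get(glycan_a), kd_lec.get(glycan_a), kd_ref.get(glycan_b), kd_lec.get(glycan_b)]
    if any(c is None or pd.isna(c) for c in cells):
        return None
    ra, la, rb, lb = cells
    return (ra / la) / (rb / lb)


def differential_features(
    annotations: Mapping[str, Iterable[str]],
    glycan_a: str,
    glycan_b: str,
) -> dict[str, set[str]]:
    """Structural motifs distinguishing two glycans.

    Returns ``{"only_a": ..., "only_b": ...}`` — the symmetric difference of
    the two motif sets, split by direction.
    """
    for g in (glycan_a, glycan_b):
        if g not in annotations:
            raise KeyError(f"glycan {g} is not annotated")
    set_a = set(annotations[glycan_a])
    set_b = set(annotations[glycan_b])
    return {"only_a": set_a - set_b, "only_b": set_b - set_a}


def binding_loss_calls(
    table: KdTable,
    lectin: str,
    reference: str,
    convention: str = "strict",
) -> pd.Series:
    """Per-glycan gain/loss/retained labels for ``lectin`` vs ``reference``.

    "lost": reference binds and the lectin does not; "gained": the
    converse; "retained" otherwise (including glycans neither binds).
    """
    kd_lec = table.values_for(lectin, convention)
    kd_ref = table.values_for(reference, convention)
    labels = {}
    for g in table.glycans:
        has_l, has_r = not pd.isna(kd_lec[g]), not pd.isna(kd_ref[g])
        if has_r and not has_l:
            labels[g] = "lost"
        elif has_l and not has_r:
            labels[g] = "gained"
        else:
            labels[g] = "retained"
    return pd.Series(labels, name=f"{lectin} vs {reference}")


# ---------------------------------------------------------------------------
# Reconciliation against a printed (pre-rounded) ratio table
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"^\s*\d*\.?\d+\s*$")


def printed_value_interval(text: str) -> tuple[float, float, float]:
    """(low, high, ulp) consistent with a printed decimal string.

    A printed "17" stands for a true value in [16.5, 17.5) with a last-digit
    unit of 1; "0.31" stands for [0.305, 0.315) with a unit of 0.01.
    """
    text = text.strip()
    if not _NUM_RE.match(text):
        raise ValueError(f"not a printed number: {text!r}")
    decimals = len(text.split(".")[1]) if "." in text else 0
    ulp = 10.0 ** (-decimals)
    value = float(text)
    return value - ulp / 2, value + ulp / 2, ulp


def diff_against_printed(
    table: KdTable,
    printed_kd: pd.DataFrame,
    printed_ratios: pd.DataFrame,
) -> pd.DataFrame:
    """Cell-by-cell reconciliation of recomputed vs printed ratio columns.

    ``printed_kd`` holds the K_d cells as printed strings; ``printed_ratios``
    has MultiIndex-ish flat columns ``"<lectin>|ratio to <reference>"`` with
    printed ratio strings ("-" for absent). Each printed ratio cell is
    classified:

    - ``exact``: recomputed ratio rounds to the printed string at its
      printed precision;
    - ``rounding_consistent``: not exact, but some pair of true K_d values
      within the rounding intervals of the printed K_d cells reproduces the
      printed ratio (the printed table was evidently computed from
      unrounded K_d);
    - ``inconsistent``: unexplainable by rounding alone;
    - ``printed_only`` / ``recomputed_only``: defined on one side only.
    """
    rows = []
    for col in printed_ratios.columns:
        lectin, _, ref_part = col.partition("|")
        reference = ref_part.replace("ratio to ", "").strip()
        rel = relative_activity(table, lectin, reference)
        for glycan in printed_ratios.index:
            printed = str(printed_ratios.loc[glycan, col]).strip()
            recomputed = rel.ratios.get(glycan, np.nan)
            has_printed = printed not in ("", NO_BINDING, "nan")
            has_recomputed = not pd.isna(recomputed)
            if not has_printed and not has_recomputed:
                continue
            if has_printed and not has_recomputed:
                status = "printed_only"
            elif has_recomputed and not has_printed:
                status = "recomputed_only"
            else:
                lo_p, hi_p, ulp = printed_value_interval(printed)
                decimals = max(0, -int(round(math.log10(ulp))))
                rounded = f"{recomputed:.{decimals}f}"
                if float(rounded) == float(printed):
                    status = "exact"
                else:
                    lo_r, hi_r = _ratio_interval(
                        str(printed_kd.loc[glycan, reference]),
                        str(printed_kd.loc[glycan, lectin]),
                    )
                    status = (
                        "rounding_consistent"
                        if (lo_r < hi_p and lo_p < hi_r)
                        else "inconsistent"
                    )
            rows.append(
                {
                    "glycan": glycan,
                    "lectin": lectin,
                    "reference": reference,
                    "printed": printed if has_printed else None,
                    "recomputed": float(recomputed) if has_recomputed else None,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)


def _ratio_interval(ref_text: str, lec_text: str) -> tuple[float, float]:
    lo_r, hi_r, _ = printed_value_interval(ref_text)
    lo_l, hi_l, _ = printed_value_interval(lec_text)
    return lo_r / hi_l, hi_r / max(lo_l, 1e-12)
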