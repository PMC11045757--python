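"""Dose-response screen analytics.

The comparative statistic is the per-cell-line ratio of median-normalized
AUCs between a bromodomain inhibitor (CCS1477-like) and a HAT inhibitor
(A485-like): AUC per curve, per-compound median normalization across lines,
then ratio = norm_auc(BRD)/norm_auc(HAT). Ratios below ``lo`` flag lines
preferentially sensitive to bromodomain inhibition, above ``hi`` to HAT
inhibition. Lineage summaries keep tumor types with >= 3 lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import BRD_COMPOUND, CLASS_BRD, CLASS_HAT, CLASS_NEUTRAL, HAT_COMPOUND

logger = logging.getLogger(__name__)

VIABILITY_CAP = 1.2  # clip growth-stimulation artifacts


@dataclass(frozen=True)
class DoseResponseSeries:
    """One cell line x compound viability curve over an increasing dose grid."""

    cell_line: str
    lineage: str
    compound: str
    doses: np.ndarray
    viability: np.ndarray

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        viab = np.asarray(self.viability, dtype=float)
        if len(doses) != len(viab):
            raise ValueError("doses and viability must have equal length")
        if len(doses) < 2:
            raise ValueError("need >= 2 doses to integrate a curve")
        if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be positive and strictly increasing")
        if not np.all(np.isfinite(viab)):
            raise ValueError("viability must be finite")
        if np.any(viab < 0):
            raise ValueError("viability must be >= 0 (fraction of control)")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "viability", viab)


def compute_auc(series: DoseResponseSeries, cap: float = VIABILITY_CAP) -> float:
    """Normalized trapezoidal AUC of viability over log10(dose).

    The integral is divided by the log10-dose range so an unaffected line
    (viability 1 everywhere) scores exactly 1.0 and a fully killed line 0.0.
    Viability is clipped to [0, cap] before integration.
    """
    x = np.log10(series.doses)
    y = np.clip(series.viability, 0.0, cap)
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def auc_table(viability: pd.DataFrame, cap: float = VIABILITY_CAP) -> pd.DataFrame:
    """Per (cell_line, compound) raw and median-normalized AUC.

    ``viability`` is the long-format screen table with columns cell_line,
    lineage, compound, dose_molar, viability. Normalization is per compound
    across all lines present for that compound.
    """
    required = {"cell_line", "lineage", "compound", "dose_molar", "viability"}
    missing = required - set(viability.columns)
    if missing:
        raise ValueError(f"viability table missing columns: {sorted(missing)}")
    records = []
    for (line, lineage, compound), grp in viability.groupby(
        ["cell_line", "lineage", "compound"], sort=True
    ):
        grp = grp.sort_values("dose_molar")
        series = DoseResponseSeries(
            line, lineage, compound, grp["dose_molar"].to_numpy(), grp["viability"].to_numpy()
        )
        records.append((line, lineage, compound, compute_auc(series, cap=cap)))
    table = pd.DataFrame(records, columns=["cell_line", "lineage", "compound", "raw_auc"])
    table["norm_auc"] = np.nan
    for compound, grp in table.groupby("compound"):
        table.loc[grp.index, "norm_auc"] = median_normalize(grp["raw_auc"].to_numpy())
    return table


def median_normalize(values: np.ndarray) -> np.ndarray:
    """Divide by the median so the normalized vector has median exactly 1."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("median normalization needs >= 1 finite value")
    med = float(np.median(finite))
    if med == 0:
        raise ValueError("median is zero; screen is degenerate")
    return values / med


def compute_ratio_table(
    auc: pd.DataFrame,
    brd_compound: str = BRD_COMPOUND,
    hat_compound: str = HAT_COMPOUND,
    hi: float = 1.2,
    lo: float = 0.8,
) -> pd.DataFrame:
    """Per-line BRD/HAT normalized-AUC ratio with preferential-class calls.

    Lines present for only one compound are dropped with a warning; lines
    whose HAT normalized AUC is zero are flagged invalid and excluded.
    """
    wide = auc.pivot_table(index="cell_line", columns="compound", values="norm_auc")
    for compound in (brd_compound, hat_compound):
        if compound not in wide.columns:
            raise ValueError(f"compound {compound!r} absent from AUC table")
    lineage_map = auc.drop_duplicates("cell_line").set_index("cell_line")["lineage"]

    unmatched = wide.index[wide[[brd_compound, hat_compound]].isna().any(axis=1)]
    if len(unmatched):
        logger.warning(
            "dropping %d cell line(s) present for only one compound: %s",
            len(unmatched),
            ", ".join(unmatched[:5]),
        )
    wide = wide.dropna(subset=[brd_compound, hat_compound])

    invalid = wide.index[wide[hat_compound] == 0]
    if len(invalid):
        logger.warning("excluding %d line(s) with zero HAT normalized AUC", len(invalid))
        wide = wide.drop(index=invalid)

    ratio = wide[brd_compound] / wide[hat_compound]
    out = pd.DataFrame(
        {
            "cell_line": ratio.index,
            "lineage": lineage_map.reindex(ratio.index).to_numpy(),
            "ratio": ratio.to_numpy(),
        }
    )
    out["class"] = [classify_ratio(r, hi=hi, lo=lo) for r in out["ratio"]]
    return out.reset_index(drop=True)


def classify_ratio(ratio: float, hi: float = 1.2, lo: float = 0.8) -> str:
    """Classify a BRD/HAT normalized AUC ratio.

    Strictly below ``lo`` means the BRD inhibitor suppressed growth
    relatively more (brd_preferential); strictly above ``hi`` the HAT
    inhibitor did (hat_preferential); boundary values are neutral.
    """
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValueError("ratio must be positive and finite")
    if ratio > hi:
        return CLASS_HAT
    if ratio < lo:
        return CLASS_BRD
    return CLASS_NEUTRAL


def summarize_lineages(
    ratio_table: pd.DataFrame,
    lineage_map: pd.Series | dict | None = None,
    min_n: int = 3,
) -> tuple[pd.DataFrame, int]:
    """Per-lineage median ratio, excluding lineages with fewer than min_n lines.

    Returns the summary table (all lineages, with a ``retained`` flag) and
    the total number of cell lines in retained lineages.
    """
    table = ratio_table.copy()
    if lineage_map is not None:
        mapping = pd.Series(lineage_map)
        unmapped = sorted(set(table["cell_line"]) - set(mapping.index))
        if unmapped:
            raise ValueError(f"cell lines without lineage assignment: {unmapped[:10]}")
        table["lineage"] = mapping.reindex(table["cell_line"]).to_numpy()
    elif table["lineage"].isna().any():
        offenders = sorted(table.loc[table["lineage"].isna(), "cell_line"])
        raise ValueError(f"cell lines without lineage assignment: {offenders[:10]}")

    rows = []
    for lineage, grp in table.groupby("lineage", sort=True):
        rows.append((lineage, len(grp), float(grp["ratio"].median()), len(grp) >= min_n))
    summary = pd.DataFrame(rows, columns=["lineage", "n_lines", "median_ratio", "retained"])
    summary = summary.sort_values("median_ratio").reset_index(drop=True)
    retained_lines = int(summary.loc[summary["retained"], "n_lines"].sum())
    return summary, retained_lines


def pairwise_r2(auc_a: np.ndarray, auc_b: np.ndarray) -> float:
    """Squared Pearson correlation over paired finite values."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must be paired")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need >= 3 paired finite values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the vectors")
    r = stats.pearsonr(a, b).statistic
    return float(r**2)
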