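"""Differential-entity calling for genes and miRNAs over the stress design.

The experimental frame is a repeated hyperosmotic stress time course sampled
at 0/24/48/96/120/144 h (control, first stress S1 at 24–48 h, recovery R at
96 h, second stress S2 at 120–144 h) with replicate counts 6/4/6/4/4/3.

External per-contrast statistics tables (from any DE caller) are first-class
inputs; :func:`simple_de_test` is a built-in caller used for synthetic runs
(median-of-ratios normalization, Welch t on log2(normalized + 0.5), BH
adjustment) and makes no claim of equivalence with shrinkage-based tools.
Differential entities pass |log2FC| > 1 and adjusted p < 0.05 (both strict).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .stats import benjamini_hochberg

__all__ = [
    "TIME_POINTS",
    "DEFAULT_REPLICATES",
    "STAGE_OF_TIME",
    "DesignError",
    "DifferentialSet",
    "make_sample_sheet",
    "read_sample_sheet",
    "validate_sample_sheet",
    "default_contrasts",
    "call_differential",
    "simple_de_test",
    "read_counts",
    "read_diffstat",
]

TIME_POINTS = (0, 24, 48, 96, 120, 144)
DEFAULT_REPLICATES = (6, 4, 6, 4, 4, 3)
STAGE_OF_TIME = {0: "control", 24: "S1", 48: "S1", 96: "R", 120: "S2", 144: "S2"}

DIFFSTAT_COLUMNS = ["entity_id", "ref_time", "test_time", "log2fc", "p_value", "p_adj"]


class DesignError(ValueError):
    """Sample sheet or contrast inconsistent with the study design."""


@dataclass(frozen=True)
class DifferentialSet:
    """Entities passing both thresholds for one contrast."""

    contrast: tuple[int, int]
    entity_ids: frozenset[str]
    lfc_min: float = 1.0
    alpha: float = 0.05

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.entity_ids

    def __len__(self) -> int:
        return len(self.entity_ids)


def make_sample_sheet(
    replicates: Sequence[int] = DEFAULT_REPLICATES,
    time_points: Sequence[int] = TIME_POINTS,
) -> pd.DataFrame:
    """Build the design sheet: one row per sample with time, stage, replicate."""
    rows = []
    for t, n in zip(time_points, replicates):
        for r in range(1, n + 1):
            rows.append(
                {
                    "sample_id": f"t{t}_r{r}",
                    "time_h": t,
                    "stage": STAGE_OF_TIME[t],
                    "replicate": r,
                }
            )
    return pd.DataFrame(rows)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "time_h", "stage", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise DesignError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise DesignError("duplicate sample_id in sample sheet")
    for _, row in sheet.iterrows():
        t = int(row["time_h"])
        if t not in STAGE_OF_TIME:
            raise DesignError(f"unknown time point {t} h")
        if row["stage"] != STAGE_OF_TIME[t]:
            raise DesignError(
                f"sample {row['sample_id']}: stage {row['stage']!r} inconsistent "
                f"with {t} h (expected {STAGE_OF_TIME[t]!r})"
            )
    return sheet


def read_sample_sheet(source: "str | io.TextIOBase") -> pd.DataFrame:
    sheet = pd.read_csv(source, sep="\t", comment="#")
    return validate_sample_sheet(sheet)


def read_counts(source: "str | io.TextIOBase") -> pd.DataFrame:
    """Counts TSV: first column entity_id, remaining columns sample ids."""
    df = pd.read_csv(source, sep="\t", comment="#")
    return df.set_index(df.columns[0])


def read_diffstat(source: "str | io.TextIOBase") -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", comment="#")
    missing = set(DIFFSTAT_COLUMNS) - set(df.columns)
    if missing:
        raise DesignError(f"DiffStat table missing columns: {sorted(missing)}")
    return df


def default_contrasts(time_points: Sequence[int] = TIME_POINTS) -> list[tuple[int, int]]:
    """0 h against every later point, plus recovery (96 h) vs second stress."""
    out = [(0, t) for t in time_points if t != 0]
    for t in (120, 144):
        if t in time_points and 96 in time_points:
            out.append((96, t))
    return out


def call_differential(
    stats: pd.DataFrame, lfc_min: float = 1.0, alpha: float = 0.05
) -> DifferentialSet:
    """Apply the strict |log2FC| > lfc_min AND p_adj < alpha filter.

    ``stats`` must hold a single contrast; duplicate entities are an error.
    """
    contrasts = stats[["ref_time", "test_time"]].drop_duplicates()
    if len(contrasts) != 1:
        raise DesignError("call_differential expects a single contrast per table")
    if stats["entity_id"].duplicated().any():
        dupes = stats.loc[stats["entity_id"].duplicated(), "entity_id"].tolist()
        raise DesignError(f"duplicate entity rows for contrast: {dupes[:5]}")
    keep = (stats["log2fc"].abs() > lfc_min) & (stats["p_adj"] < alpha)
    contrast = (int(contrasts.iloc[0, 0]), int(contrasts.iloc[0, 1]))
    return DifferentialSet(
        contrast=contrast,
        entity_ids=frozenset(stats.loc[keep, "entity_id"]),
        lfc_min=lfc_min,
        alpha=alpha,
    )


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over genes with all-positive counts."""
    logc = np.log(counts, where=counts > 0, out=np.full_like(counts, np.nan, dtype=float))
    usable = np.all(counts > 0, axis=1)
    if not usable.any():
        return np.ones(counts.shape[1])
    log_ref = logc[usable].mean(axis=1)
    sf = np.exp(np.median(logc[usable] - log_ref[:, None], axis=0))
    return sf


def simple_de_test(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    contrast: tuple[int, int],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-entity differential test between two time points.

    log2FC is computed on median-of-ratios-normalized group means with the
    pseudocount; p-values come from Welch's t on log2(normalized + pseudocount)
    and are BH-adjusted. Returns a DiffStat table.
    """
    ref_time, test_time = contrast
    sheet = validate_sample_sheet(sheet)
    ref_samples = sheet.loc[sheet["time_h"] == ref_time, "sample_id"].tolist()
    test_samples = sheet.loc[sheet["time_h"] == test_time, "sample_id"].tolist()
    if len(ref_samples) < 2 or len(test_samples) < 2:
        raise DesignError(
            f"contrast {ref_time}h vs {test_time}h needs >= 2 samples per group"
        )
    sub = counts[ref_samples + test_samples]
    if not np.issubdtype(sub.values.dtype, np.number):
        raise DesignError("counts must be numeric")
    mat = sub.to_numpy(dtype=float)
    sf = _size_factors(mat)
    norm = mat / sf
    n_ref = len(ref_samples)
    ref_mean = norm[:, :n_ref].mean(axis=1)
    test_mean = norm[:, n_ref:].mean(axis=1)
    log2fc = np.log2(test_mean + pseudocount) - np.log2(ref_mean + pseudocount)

    log_norm = np.log2(norm + pseudocount)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a harmless precision warning; they get p = 1
        warnings.simplefilter("ignore", RuntimeWarning)
        p = ttest_ind(
            log_norm[:, n_ref:], log_norm[:, :n_ref], axis=1, equal_var=False
        ).pvalue
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance-in-both-groups rows
    return pd.DataFrame(
        {
            "entity_id": counts.index,
            "ref_time": ref_time,
            "test_time": test_time,
            "log2fc": log2fc,
            "p_value": p,
            "p_adj": benjamini_hochberg(p),
        }
    ).reset_index(drop=True)
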