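"""miRNA→gene target pairs: two-tool intersection, regions, correlations.

A (miRNA, gene) relation counts as a true target pair only when both
prediction sources report it and the duplex free energy passes the
≤ −20 kcal/mol stability threshold. The retained pair carries the binding
interval of the more stable (lower-energy) source, the transcript-compartment
label from the gene model, and the Pearson correlation of the miRNA and gene
expression profiles over the time course.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation import BindingRegion, GeneCatalog, assign_binding_region
from .differential import DifferentialSet
from .stats import CorrelationResult, pearson

__all__ = [
    "TargetPrediction",
    "TargetPair",
    "TargetingError",
    "read_predictions",
    "intersect_predictions",
    "assign_regions",
    "attach_correlation",
    "binding_region_distribution",
    "pairs_active_at",
    "pairs_to_frame",
]

PREDICTION_COLUMNS = ["mirna_id", "gene_id", "t_start", "t_end", "energy_kcal_mol", "tool"]


class TargetingError(ValueError):
    """Invalid prediction input or missing expression profile."""


@dataclass(frozen=True)
class TargetPrediction:
    """One binding-site prediction from one tool (transcript coordinates)."""

    mirna_id: str
    gene_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    energy: float  # kcal/mol, negative = stable duplex
    source: str

    def __post_init__(self):
        if not self.start < self.end:
            raise TargetingError(
                f"{self.mirna_id}->{self.gene_id}: empty binding interval"
            )
        if not (self.energy == self.energy and abs(self.energy) != float("inf")):
            raise TargetingError("energy must be finite")

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


@dataclass(frozen=True)
class TargetPair:
    """A consensus (miRNA, gene) pair supported by both prediction tools."""

    mirna_id: str
    gene_id: str
    binding: tuple[int, int]
    energy_best: float
    n_sites: int = 1  # binding sites passing the filter across both sources
    region: Optional[BindingRegion] = None
    correlation: Optional[CorrelationResult] = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)

    @property
    def sign(self) -> Optional[str]:
        return None if self.correlation is None else self.correlation.sign


def read_predictions(source: "str | io.TextIOBase") -> list[TargetPrediction]:
    """Canonical prediction TSV -> predictions.

    Columns: mirna_id, gene_id, t_start (0-based), t_end, energy_kcal_mol,
    tool. Native RNAhybrid/miRanda report parsing is out of scope; see
    :func:`native_report_converter_stub` for the expected field mapping.
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise TargetingError(f"prediction table missing columns: {sorted(missing)}")
    return [
        TargetPrediction(
            mirna_id=row.mirna_id,
            gene_id=row.gene_id,
            start=int(row.t_start),
            end=int(row.t_end),
            energy=float(row.energy_kcal_mol),
            source=row.tool,
        )
        for row in df.itertuples()
    ]


def native_report_converter_stub() -> Mapping[str, str]:
    """Field mapping a converter from native tool reports would implement.

    RNAhybrid: target/miRNA ids, 'position' (1-based target start) and
    duplex 'mfe'; miRanda: the '>>' summary lines' query/ref ids, alignment
    start/end, and 'Energy'. Both convert to the canonical TSV dialect; the
    conversion itself is deliberately not implemented here.
    """
    return {
        "mirna_id": "query id",
        "gene_id": "target/reference id",
        "t_start": "alignment start - 1",
        "t_end": "alignment end",
        "energy_kcal_mol": "mfe / Energy",
        "tool": "rnahybrid | miranda",
    }


def _best_per_pair(
    preds: Iterable[TargetPrediction], energy_max: float
) -> dict[tuple[str, str], list[TargetPrediction]]:
    """Pair key -> predictions passing the energy filter, best energy first."""
    out: dict[tuple[str, str], list[TargetPrediction]] = {}
    for p in preds:
        if p.energy <= energy_max:
            out.setdefault(p.key, []).append(p)
    for sites in out.values():
        sites.sort(key=lambda p: (p.energy, p.start, p.end))
    return out


def intersect_predictions(
    preds_a: Iterable[TargetPrediction],
    preds_b: Iterable[TargetPrediction],
    energy_max: float = -20.0,
    per_source: bool = True,
) -> list[TargetPair]:
    """Consensus pairs present in both sources with acceptable energy.

    Overlap is taken at the (miRNA, gene) level, not at binding coordinates.
    With ``per_source=True`` (default) each source must independently pass
    ``energy <= energy_max``; with ``per_source=False`` only the best source
    must. The retained binding interval and energy come from the source with
    the lower (more negative) energy.
    """
    preds_a, preds_b = list(preds_a), list(preds_b)
    if per_source:
        a = _best_per_pair(preds_a, energy_max)
        b = _best_per_pair(preds_b, energy_max)
    else:
        a = _best_per_pair(preds_a, float("inf"))
        b = _best_per_pair(preds_b, float("inf"))
    pairs = []
    for key in sorted(set(a) & set(b)):
        sites = sorted(a[key] + b[key], key=lambda p: (p.energy, p.start, p.end))
        best = sites[0]
        if best.energy > energy_max:
            continue
        pairs.append(
            TargetPair(
                mirna_id=key[0],
                gene_id=key[1],
                binding=(best.start, best.end),
                energy_best=best.energy,
                n_sites=len({(p.start, p.end) for p in sites}),
            )
        )
    return pairs


def assign_regions(pairs: Iterable[TargetPair], catalog: GeneCatalog) -> list[TargetPair]:
    """Label each pair's binding interval with its transcript compartment."""
    out = []
    for p in pairs:
        gene = catalog[p.gene_id]
        out.append(replace(p, region=assign_binding_region(p.binding, gene)))
    return out


def attach_correlation(
    pairs: Iterable[TargetPair],
    mirna_profiles: pd.DataFrame,
    gene_profiles: pd.DataFrame,
) -> list[TargetPair]:
    """Attach the Pearson correlation of the per-time mean profiles.

    Profiles are DataFrames indexed by entity id with one column per time
    point (same ordered time points, n >= 3).
    """
    if list(mirna_profiles.columns) != list(gene_profiles.columns):
        raise TargetingError("miRNA and gene profiles must share time points")
    out = []
    for p in pairs:
        if p.mirna_id not in mirna_profiles.index:
            raise TargetingError(f"no expression profile for miRNA {p.mirna_id!r}")
        if p.gene_id not in gene_profiles.index:
            raise TargetingError(f"no expression profile for gene {p.gene_id!r}")
        corr = pearson(
            mirna_profiles.loc[p.mirna_id].to_numpy(),
            gene_profiles.loc[p.gene_id].to_numpy(),
        )
        out.append(replace(p, correlation=corr))
    return out


def binding_region_distribution(pairs: Sequence[TargetPair]) -> pd.DataFrame:
    """Per-region counts, proportions and correlation-sign fractions.

    Sign fractions are computed over pairs with a nonzero correlation sign;
    an empty pair set yields an all-zero table rather than an error.
    """
    regions = ["utr5", "cds", "utr3"]
    rows = []
    total = len(pairs)
    for region in regions:
        sub = [p for p in pairs if p.region == region]
        signed = [p for p in sub if p.sign in ("positive", "negative")]
        n_pos = sum(1 for p in signed if p.sign == "positive")
        rows.append(
            {
                "region": region,
                "count": len(sub),
                "proportion": len(sub) / total if total else 0.0,
                "positive_frac": n_pos / len(signed) if signed else 0.0,
                "negative_frac": (len(signed) - n_pos) / len(signed) if signed else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def pairs_active_at(
    pairs: Iterable[TargetPair],
    time_h: int,
    demirnas: DifferentialSet,
    degs: DifferentialSet,
) -> list[TargetPair]:
    """Pairs whose miRNA AND target gene are both differential at ``time_h``."""
    for dset, what in ((demirnas, "miRNA"), (degs, "gene")):
        if dset.contrast[1] != time_h:
            raise TargetingError(
                f"{what} differential set is for {dset.contrast[1]} h, not {time_h} h"
            )
    return [p for p in pairs if p.mirna_id in demirnas and p.gene_id in degs]


def pairs_to_frame(pairs: Sequence[TargetPair]) -> pd.DataFrame:
    """Target-pair output table: one row per pair."""
    return pd.DataFrame(
        {
            "mirna_id": [p.mirna_id for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "t_start": [p.binding[0] for p in pairs],
            "t_end": [p.binding[1] for p in pairs],
            "region": [p.region for p in pairs],
            "energy_best": [p.energy_best for p in pairs],
            "n_sites": [p.n_sites for p in pairs],
            "r": [p.correlation.r if p.correlation else float("nan") for p in pairs],
            "p": [p.correlation.p_value if p.correlation else float("nan") for p in pairs],
            "sign": [p.sign for p in pairs],
        }
    )
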