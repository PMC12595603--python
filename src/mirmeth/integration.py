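"""Joint analysis of miRNA targeting and DNA methylation evidence.

This is the synthesis layer: per-time-point regulation-mode classification
(miRNA-only / methylation-only / dual / none) of stress-responsive functional
genes, mode proportions, the permutation test for non-random dual regulation,
structural-complementarity comparisons (methylation level and CpG site count
of miRNA-targeted vs non-targeted genes), and |log2FC| contrasts between
regulation groups.

The permutation null redraws both gene sets uniformly without replacement
each iteration, preserving their sizes; the overlap of two such sets is
hypergeometric, which the test suite uses as the analytic oracle. Empirical
p-values follow the add-one convention (1 + #{null >= observed}) /
(iterations + 1), so they are never zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import RankTestResult, significance_stars, wilcoxon_rank_sum
from .targeting import TargetPair

__all__ = [
    "MODES",
    "IntegrationError",
    "RegulationCall",
    "PermutationResult",
    "ComplementarityReport",
    "classify_regulation",
    "mode_proportions",
    "dual_regulation_permutation",
    "structural_complementarity",
    "lfc_group_comparison",
    "mutual_regulation_report",
    "term_enrichment",
    "DEFAULT_WATCHLIST",
]

MODES = ("mirna_only", "methylation_only", "dual", "none")
DEFAULT_WATCHLIST = ("MBD2", "DGCR8", "DNMT", "DICER", "DROSHA")


class IntegrationError(ValueError):
    """Inconsistent inputs to the integration stage."""


@dataclass(frozen=True)
class RegulationCall:
    gene_id: str
    time_h: int
    mode: str
    mirna_evidence: tuple = ()  # (mirna_id, gene_id) pair keys
    meth_evidence: tuple = ()  # (chrom, pos) site keys

    def __post_init__(self):
        has_mirna, has_meth = bool(self.mirna_evidence), bool(self.meth_evidence)
        expected = {
            (True, True): "dual",
            (True, False): "mirna_only",
            (False, True): "methylation_only",
            (False, False): "none",
        }[(has_mirna, has_meth)]
        if self.mode != expected:
            raise IntegrationError(
                f"{self.gene_id}@{self.time_h}h: mode {self.mode!r} inconsistent "
                f"with evidence"
            )


@dataclass(frozen=True)
class PermutationResult:
    universe_size: int
    n_mirna: int
    n_meth: int
    observed_overlap: int
    iterations: int
    null_overlaps: tuple[int, ...]
    p_empirical: float
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "n_mirna": self.n_mirna,
            "n_meth": self.n_meth,
            "observed_overlap": self.observed_overlap,
            "iterations": self.iterations,
            "p_empirical": self.p_empirical,
            "seed": self.seed,
            "null_overlaps": list(self.null_overlaps),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class ComplementarityReport:
    """Per-time methylation-level comparison plus the site-count contrast."""

    levels: pd.DataFrame  # one row per compared time point
    site_count_test: Optional[RankTestResult]
    site_count_means: tuple[float, float] = (float("nan"), float("nan"))
    skipped_times: list[int] = field(default_factory=list)


def classify_regulation(
    time_h: int,
    degs: Iterable[str],
    active_pairs: Sequence[TargetPair],
    dmsgs: pd.DataFrame,
    functional_genes: Iterable[str],
    cohort: str = "de",
) -> list[RegulationCall]:
    """Regulation mode of each functional gene at one time point.

    miRNA evidence: the gene is the target of an active pair at ``time_h``;
    methylation evidence: the gene carries a differential site for the
    0 h-vs-``time_h`` contrast. The default cohort is functional genes that
    are differentially expressed at ``time_h`` (genes whose expression did
    not change have no regulated response to explain); ``cohort='all'``
    widens it to every functional gene.
    """
    if cohort not in ("de", "all"):
        raise IntegrationError(f"unknown cohort {cohort!r}")
    functional = set(functional_genes)
    deg_set = set(degs)
    cohort_genes = sorted(functional & deg_set if cohort == "de" else functional)

    pair_keys: dict[str, list] = {}
    for p in active_pairs:
        pair_keys.setdefault(p.gene_id, []).append(p.key)
    site_keys: dict[str, list] = {}
    if len(dmsgs):
        relevant = dmsgs
        if "test_time" in dmsgs.columns and dmsgs["test_time"].notna().any():
            relevant = dmsgs[dmsgs["test_time"] == time_h]
        for row in relevant.itertuples():
            site_keys.setdefault(row.gene_id, []).append((row.chrom, row.pos))

    calls = []
    for gid in cohort_genes:
        mirna_ev = tuple(sorted(pair_keys.get(gid, [])))
        meth_ev = tuple(sorted(site_keys.get(gid, [])))
        if mirna_ev and meth_ev:
            mode = "dual"
        elif mirna_ev:
            mode = "mirna_only"
        elif meth_ev:
            mode = "methylation_only"
        else:
            mode = "none"
        calls.append(
            RegulationCall(
                gene_id=gid,
                time_h=time_h,
                mode=mode,
                mirna_evidence=mirna_ev,
                meth_evidence=meth_ev,
            )
        )
    return calls


def mode_proportions(calls: Sequence[RegulationCall]) -> dict:
    """Fractions of miRNA-only / methylation-only / dual among genes with
    evidence, plus the count of evidence-free genes."""
    times = {c.time_h for c in calls}
    if len(times) > 1:
        raise IntegrationError("mode_proportions expects calls from one time point")
    n_none = sum(1 for c in calls if c.mode == "none")
    with_evidence = [c for c in calls if c.mode != "none"]
    total = len(with_evidence)
    props = {
        mode: (sum(1 for c in with_evidence if c.mode == mode) / total if total else 0.0)
        for mode in ("mirna_only", "methylation_only", "dual")
    }
    return {"proportions": props, "n_with_evidence": total, "n_none": n_none}


def dual_regulation_permutation(
    universe: Iterable[str],
    set_mirna: Iterable[str],
    set_meth: Iterable[str],
    iterations: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """Permutation test: is the miRNA/methylation gene-set overlap non-random?

    Each iteration independently redraws two uniform without-replacement sets
    of the observed sizes from the universe and records their overlap;
    the add-one empirical p is the upper tail at the observed overlap.
    """
    ids = sorted(set(universe))
    set_a = set(set_mirna)
    set_b = set(set_meth)
    if not set_a <= set(ids) or not set_b <= set(ids):
        raise IntegrationError("regulated sets must be subsets of the universe")
    n = len(ids)
    n_a, n_b = len(set_a), len(set_b)
    if iterations < 1:
        raise IntegrationError("iterations must be >= 1")
    k_obs = len(set_a & set_b)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(iterations, dtype=np.int64)
    mask = np.zeros(n, dtype=bool)
    for i in range(iterations):
        a_idx = rng.choice(n, size=n_a, replace=False)
        b_idx = rng.choice(n, size=n_b, replace=False)
        mask[:] = False
        mask[a_idx] = True
        null[i] = int(mask[b_idx].sum())
    p = (1 + int((null >= k_obs).sum())) / (iterations + 1)
    return PermutationResult(
        universe_size=n,
        n_mirna=n_a,
        n_meth=n_b,
        observed_overlap=k_obs,
        iterations=iterations,
        null_overlaps=tuple(int(v) for v in null),
        p_empirical=p,
        seed=seed,
    )


def structural_complementarity(
    targeted_genes: Iterable[str],
    other_genes: Iterable[str],
    levels_by_time: pd.DataFrame,
    site_counts: Optional[pd.Series] = None,
) -> ComplementarityReport:
    """Compare methylation of miRNA-targeted vs non-targeted genes.

    ``levels_by_time`` is a gene-by-time matrix of methylation levels (NaN
    marks genes without covered sites; they are excluded and counted).
    Per time point the report holds group means ± sd and the two-sided
    rank-sum p with its significance stars; ``site_counts`` adds the single
    across-gene CpG site-count comparison. Times where either group is empty
    are skipped and listed.
    """
    targeted = [g for g in targeted_genes if g in levels_by_time.index]
    others = [g for g in other_genes if g in levels_by_time.index]
    rows, skipped = [], []
    for t in levels_by_time.columns:
        lv_t = levels_by_time.loc[targeted, t].dropna()
        lv_o = levels_by_time.loc[others, t].dropna()
        if len(lv_t) == 0 or len(lv_o) == 0:
            skipped.append(t)
            continue
        test = wilcoxon_rank_sum(lv_t.to_numpy(), lv_o.to_numpy())
        rows.append(
            {
                "time_h": t,
                "n_targeted": len(lv_t),
                "n_other": len(lv_o),
                "n_missing": (len(targeted) - len(lv_t)) + (len(others) - len(lv_o)),
                "targeted_mean": lv_t.mean(),
                "targeted_sd": lv_t.std(ddof=1),
                "other_mean": lv_o.mean(),
                "other_sd": lv_o.std(ddof=1),
                "p_value": test.p_value,
                "stars": significance_stars(test.p_value),
            }
        )
    site_test, site_means = None, (float("nan"), float("nan"))
    if site_counts is not None:
        ct = site_counts.reindex(targeted).dropna()
        co = site_counts.reindex(others).dropna()
        if len(ct) and len(co):
            site_test = wilcoxon_rank_sum(ct.to_numpy(), co.to_numpy())
            site_means = (float(ct.mean()), float(co.mean()))
    return ComplementarityReport(
        levels=pd.DataFrame(rows),
        site_count_test=site_test,
        site_count_means=site_means,
        skipped_times=skipped,
    )


def lfc_group_comparison(
    calls: Sequence[RegulationCall], gene_lfc: pd.Series
) -> dict[str, Optional[RankTestResult]]:
    """|log2FC| contrasts: miRNA-only vs dual and methylation-only vs dual.

    ``gene_lfc`` maps gene -> log2 fold change at the calls' time point.
    A comparison with an empty group is reported as None (not computable).
    """
    groups = {
        mode: [c.gene_id for c in calls if c.mode == mode]
        for mode in ("mirna_only", "methylation_only", "dual")
    }
    lfc = {
        mode: gene_lfc.reindex(genes).abs().dropna().to_numpy()
        for mode, genes in groups.items()
    }
    out: dict[str, Optional[RankTestResult]] = {}
    for mode, label in (
        ("mirna_only", "mirna_only_vs_dual"),
        ("methylation_only", "methylation_only_vs_dual"),
    ):
        if len(lfc[mode]) and len(lfc["dual"]):
            out[label] = wilcoxon_rank_sum(lfc[mode], lfc["dual"])
        else:
            out[label] = None
    return out


def mutual_regulation_report(
    pairs: Sequence[TargetPair],
    dmsgs: pd.DataFrame,
    catalog_symbols: Mapping[str, Optional[str]],
    watchlist: Sequence[str] = DEFAULT_WATCHLIST,
) -> pd.DataFrame:
    """Cross-layer hits on machinery genes of the other layer.

    Lists watchlist genes (miRNA-pathway and methylation-pathway machinery,
    e.g. MBD2, DGCR8) that appear as miRNA targets (with binding region and
    correlation sign) or as DMSGs (with site count and directions). Matching
    is by symbol prefix, case-insensitive, so DNMT matches DNMT1/DNMT3A.
    """
    watch = [w.upper() for w in watchlist]

    def match(symbol: Optional[str]) -> Optional[str]:
        if not symbol:
            return None
        s = symbol.upper()
        for w in watch:
            if s.startswith(w):
                return w
        return None

    rows = []
    for p in pairs:
        hit = match(catalog_symbols.get(p.gene_id))
        if hit:
            rows.append(
                {
                    "watch_gene": hit,
                    "gene_id": p.gene_id,
                    "symbol": catalog_symbols.get(p.gene_id),
                    "layer": "mirna",
                    "partner": p.mirna_id,
                    "region": p.region,
                    "sign": p.sign,
                    "site_count": None,
                    "direction": None,
                }
            )
    if len(dmsgs):
        for gid, sub in dmsgs.groupby("gene_id"):
            symbol = sub["symbol"].iloc[0]
            hit = match(symbol)
            if hit:
                rows.append(
                    {
                        "watch_gene": hit,
                        "gene_id": gid,
                        "symbol": symbol,
                        "layer": "methylation",
                        "partner": None,
                        "region": sub["location"].mode().iloc[0],
                        "sign": None,
                        "site_count": int(sub[["chrom", "pos"]].drop_duplicates().shape[0]),
                        "direction": ",".join(sorted(sub["direction"].unique())),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "watch_gene", "gene_id", "symbol", "layer", "partner", "region",
            "sign", "site_count", "direction",
        ],
    )


def term_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    gene_terms: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Optional hook: one-sided hypergeometric enrichment of a user-supplied
    gene -> terms map (e.g. pathway annotations) within ``gene_set``."""
    from scipy.stats import hypergeom

    uni = sorted(set(universe))
    hits = set(gene_set) & set(uni)
    term_genes: dict[str, set] = {}
    for g in uni:
        for term in gene_terms.get(g, ()):  # genes without terms contribute nothing
            term_genes.setdefault(term, set()).add(g)
    rows = []
    n, k = len(uni), len(hits)
    for term, members in sorted(term_genes.items()):
        overlap = len(members & hits)
        p = float(hypergeom.sf(overlap - 1, n, len(members), k))
        rows.append(
            {"term": term, "term_size": len(members), "overlap": overlap, "p_value": p}
        )
    return pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_value"])
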