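"""CpG differential methylation and DMSG construction.

Per-sample CpG call tables (chrom, 1-based pos, strand, methylated count,
unmethylated count) are merged into a coverage-filtered site-by-sample table.
Differential sites between two sample groups are called on pooled counts
with the conditional (Fisher) exact test, BH-adjusted, and filtered at
|Δ methylation| ≥ 25 percentage points and q < 0.01 — the package defaults,
all configurable. Genes carrying a differential site in their promoter
(2 kb upstream of the TSS) or gene body (TSS→TES) are the DNA
methylation-related stress-responsive genes (DMSGs).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneCatalog, GeneModel, gene_body_interval, promoter_interval
from .stats import benjamini_hochberg, fisher_exact, pearson

__all__ = [
    "MethylationError",
    "MethylationTable",
    "read_cpg_calls",
    "load_methylation_calls",
    "filter_coverage",
    "diff_methylation",
    "site_gene_index",
    "build_dmsgs",
    "methylation_expression_direction",
    "gene_methylation_level",
    "gene_methylation_levels",
    "gene_site_counts",
]

CPG_COLUMNS = ["chrom", "pos", "strand", "meth_count", "unmeth_count"]


class MethylationError(ValueError):
    """Inconsistent methylation input."""


@dataclass
class MethylationTable:
    """Site-by-sample methylated/unmethylated counts.

    ``meth`` and ``unmeth`` share a (chrom, pos, strand) MultiIndex and one
    column per sample; missing observations are zero-coverage.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame

    def __post_init__(self):
        if not self.meth.index.equals(self.unmeth.index) or list(
            self.meth.columns
        ) != list(self.unmeth.columns):
            raise MethylationError("meth and unmeth tables must be aligned")

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def sites(self) -> pd.MultiIndex:
        return self.meth.index

    def coverage(self, samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
        cols = list(samples) if samples is not None else self.samples
        return self.meth[cols] + self.unmeth[cols]

    def pooled_rate(self, samples: Sequence[str]) -> pd.Series:
        m = self.meth[list(samples)].sum(axis=1)
        u = self.unmeth[list(samples)].sum(axis=1)
        return m / (m + u)


def read_cpg_calls(source: "str | io.TextIOBase") -> pd.DataFrame:
    """One sample's CpG TSV: chrom, pos (1-based), strand, meth/unmeth counts."""
    df = pd.read_csv(source, sep="\t", comment="#")
    missing = set(CPG_COLUMNS) - set(df.columns)
    if missing:
        raise MethylationError(f"CpG table missing columns: {sorted(missing)}")
    if (df["meth_count"] < 0).any() or (df["unmeth_count"] < 0).any():
        raise MethylationError("negative counts in CpG table")
    return df


def read_bedgraph_calls(source: "str | io.TextIOBase") -> pd.DataFrame:
    """bedGraph importer: chrom, start (0-based), end, percent methylation,
    plus companion meth_count/unmeth_count coverage columns."""
    df = pd.read_csv(
        source,
        sep="\t",
        comment="#",
        names=["chrom", "start", "end", "percent", "meth_count", "unmeth_count"],
    )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"] + 1,
            "strand": "+",
            "meth_count": df["meth_count"],
            "unmeth_count": df["unmeth_count"],
        }
    )


def load_methylation_calls(
    per_sample: Mapping[str, "pd.DataFrame | str | io.TextIOBase"],
    min_coverage: int = 10,
    required_samples: Optional[Sequence[str]] = None,
    merge_strands: bool = False,
) -> MethylationTable:
    """Merge per-sample CpG calls into one coverage-filtered table.

    A site is retained only if its coverage reaches ``min_coverage`` in every
    sample of ``required_samples`` (default: all samples). With
    ``merge_strands`` the − strand call at position p+1 is summed into the +
    strand call at p (symmetric CpG collapsing); a strand conflict at one
    coordinate is an error.
    """
    meth_cols, unmeth_cols = {}, {}
    strand_seen: dict[tuple[str, int], str] = {}
    for sample_id, src in per_sample.items():
        df = src if isinstance(src, pd.DataFrame) else read_cpg_calls(src)
        df = df.copy()
        if merge_strands:
            minus = df["strand"] == "-"
            df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
            df["strand"] = "+"
            df = (
                df.groupby(["chrom", "pos", "strand"], as_index=False)[
                    ["meth_count", "unmeth_count"]
                ].sum()
            )
        for chrom, pos, strand in zip(df["chrom"], df["pos"], df["strand"]):
            prev = strand_seen.setdefault((chrom, int(pos)), strand)
            if prev != strand:
                raise MethylationError(
                    f"conflicting strand for site {chrom}:{pos} across samples"
                )
        idx = pd.MultiIndex.from_frame(
            df[["chrom", "pos", "strand"]], names=["chrom", "pos", "strand"]
        )
        meth_cols[sample_id] = pd.Series(df["meth_count"].to_numpy(), index=idx)
        unmeth_cols[sample_id] = pd.Series(df["unmeth_count"].to_numpy(), index=idx)
    meth = pd.DataFrame(meth_cols).fillna(0).astype(int).sort_index()
    unmeth = pd.DataFrame(unmeth_cols).fillna(0).astype(int).sort_index()
    table = MethylationTable(meth=meth, unmeth=unmeth)
    return filter_coverage(table, min_coverage, required_samples)


def filter_coverage(
    table: MethylationTable,
    min_coverage: int = 10,
    samples: Optional[Sequence[str]] = None,
) -> MethylationTable:
    """Keep sites covered >= min_coverage in every one of ``samples``."""
    cov = table.coverage(samples)
    keep = (cov >= min_coverage).all(axis=1)
    return MethylationTable(meth=table.meth.loc[keep], unmeth=table.unmeth.loc[keep])


def diff_methylation(
    table: MethylationTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    diff_min: float = 25.0,
    q_max: float = 0.01,
    contrast: Optional[tuple[int, int]] = None,
) -> pd.DataFrame:
    """Differentially methylated sites between groups A (reference) and B.

    Per site, counts are pooled within each group, tested with the two-sided
    conditional exact test, BH-adjusted; ``meth_diff`` is
    100·(rate_B − rate_A) in percentage points, direction up iff positive.
    """
    if len(group_a) < 1 or len(group_b) < 1:
        raise MethylationError("each contrast group needs at least one sample")
    ma = table.meth[list(group_a)].sum(axis=1).to_numpy()
    ua = table.unmeth[list(group_a)].sum(axis=1).to_numpy()
    mb = table.meth[list(group_b)].sum(axis=1).to_numpy()
    ub = table.unmeth[list(group_b)].sum(axis=1).to_numpy()
    with np.errstate(invalid="ignore"):
        rate_a = ma / (ma + ua)
        rate_b = mb / (mb + ub)
    meth_diff = 100.0 * (rate_b - rate_a)
    p = np.array(
        [fisher_exact([[mbi, ubi], [mai, uai]]) for mbi, ubi, mai, uai in zip(mb, ub, ma, ua)]
    )
    q = benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "chrom": table.sites.get_level_values("chrom"),
            "pos": table.sites.get_level_values("pos"),
            "strand": table.sites.get_level_values("strand"),
            "meth_diff": meth_diff,
            "p_value": p,
            "q_value": q,
        }
    )
    if contrast is not None:
        out["ref_time"], out["test_time"] = contrast
    keep = (out["meth_diff"].abs() >= diff_min) & (out["q_value"] < q_max)
    out = out.loc[keep].reset_index(drop=True)
    out["direction"] = np.where(out["meth_diff"] > 0, "up", "down")
    return out


def site_gene_index(
    catalog: GeneCatalog, upstream_bp: int = 2000, strand_aware: bool = True
) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over promoter and gene-body windows."""
    trees: dict[str, IntervalTree] = {}
    for gene in catalog:
        chrom_length = catalog.chrom_lengths.get(gene.span.chrom)
        body = gene_body_interval(gene)
        prom = promoter_interval(gene, upstream_bp, chrom_length, strand_aware)
        tree = trees.setdefault(gene.span.chrom, IntervalTree())
        if len(body):
            tree.addi(body.start, body.end, (gene.gene_id, "gene_body"))
        if len(prom):
            tree.addi(prom.start, prom.end, (gene.gene_id, "promoter"))
    return trees


def build_dmsgs(
    diff_sites: pd.DataFrame,
    catalog: GeneCatalog,
    functional_list: Optional[Mapping[str, str]] = None,
    upstream_bp: int = 2000,
    strand_aware: bool = True,
    top_site_only: bool = False,
) -> pd.DataFrame:
    """DMSG records: one row per (gene, differential site) overlap.

    A site falling in the promoter of one gene and the body of an overlapping
    neighbour yields one record per gene. ``top_site_only`` collapses each
    gene to its site with the largest |meth_diff| (report mode mirroring a
    one-site-per-gene table). ``function_label`` comes from
    ``functional_list`` where available.
    """
    trees = site_gene_index(catalog, upstream_bp, strand_aware)
    functional_list = functional_list or {}
    rows = []
    for row in diff_sites.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        pos0 = int(row.pos) - 1
        for hit in sorted(tree.at(pos0), key=lambda h: h.data):
            gene_id, location = hit.data
            gene = catalog[gene_id]
            # gene body wins over the promoter of the same gene
            if location == "promoter" and gene.span.contains(pos0):
                continue
            rows.append(
                {
                    "gene_id": gene_id,
                    "symbol": gene.symbol,
                    "chrom": row.chrom,
                    "pos": int(row.pos),
                    "location": location,
                    "meth_diff": row.meth_diff,
                    "direction": row.direction,
                    "ref_time": getattr(row, "ref_time", None),
                    "test_time": getattr(row, "test_time", None),
                    "function_label": functional_list.get(gene_id),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "symbol", "chrom", "pos", "location", "meth_diff",
            "direction", "ref_time", "test_time", "function_label",
        ],
    )
    if top_site_only and len(out):
        out = (
            out.assign(_abs=out["meth_diff"].abs())
            .sort_values(["gene_id", "_abs"], ascending=[True, False])
            .drop_duplicates("gene_id")
            .drop(columns="_abs")
        )
    return out.sort_values(["gene_id", "pos"]).reset_index(drop=True)


def methylation_expression_direction(
    site_meth_profile: Sequence[float], gene_expr_profile: Sequence[float]
) -> str:
    """Sign of the Pearson correlation between per-time methylation level and
    per-time mean expression ('positive'/'negative'/'zero')."""
    return pearson(site_meth_profile, gene_expr_profile).sign


def gene_methylation_level(
    gene: GeneModel,
    table: MethylationTable,
    samples: Sequence[str],
    upstream_bp: int = 2000,
    strand_aware: bool = True,
    coverage_weighted: bool = False,
) -> float:
    """Mean methylation level of a gene's promoter ∪ gene-body sites in [0,1].

    Default is the unweighted mean over sites of the pooled rate
    meth/(meth+unmeth); ``coverage_weighted`` pools counts across sites
    instead. NaN when the gene has no covered site.
    """
    chrom = gene.span.chrom
    sites = table.sites
    on_chrom = sites.get_level_values("chrom") == chrom
    if not on_chrom.any():
        return float("nan")
    pos0 = sites.get_level_values("pos").to_numpy() - 1
    prom = promoter_interval(gene, upstream_bp, None, strand_aware)
    in_gene = on_chrom & (
        ((pos0 >= gene.span.start) & (pos0 < gene.span.end))
        | ((pos0 >= prom.start) & (pos0 < prom.end))
    )
    if not in_gene.any():
        return float("nan")
    m = table.meth.loc[in_gene, list(samples)].sum(axis=1)
    u = table.unmeth.loc[in_gene, list(samples)].sum(axis=1)
    covered = (m + u) > 0
    if not covered.any():
        return float("nan")
    if coverage_weighted:
        return float(m[covered].sum() / (m[covered].sum() + u[covered].sum()))
    return float((m[covered] / (m[covered] + u[covered])).mean())


def gene_methylation_levels(
    catalog: GeneCatalog,
    table: MethylationTable,
    samples_by_time: Mapping[int, Sequence[str]],
    upstream_bp: int = 2000,
    genes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Gene-by-time matrix of pooled methylation levels (NaN = no sites)."""
    gene_ids = list(genes) if genes is not None else [g.gene_id for g in catalog]
    data = {
        t: [
            gene_methylation_level(catalog[g], table, samples, upstream_bp)
            for g in gene_ids
        ]
        for t, samples in samples_by_time.items()
    }
    return pd.DataFrame(data, index=gene_ids)


def gene_site_counts(
    catalog: GeneCatalog,
    table: MethylationTable,
    upstream_bp: int = 2000,
    genes: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Number of covered CpG sites in each gene's promoter ∪ gene body."""
    gene_ids = list(genes) if genes is not None else [g.gene_id for g in catalog]
    sites = table.sites
    chroms = sites.get_level_values("chrom").to_numpy()
    pos0 = sites.get_level_values("pos").to_numpy() - 1
    counts = []
    for gid in gene_ids:
        gene = catalog[gid]
        prom = promoter_interval(gene, upstream_bp, catalog.chrom_lengths.get(gene.span.chrom))
        mask = (chroms == gene.span.chrom) & (
            ((pos0 >= gene.span.start) & (pos0 < gene.span.end))
            | ((pos0 >= prom.start) & (pos0 < prom.end))
        )
        counts.append(int(mask.sum()))
    return pd.Series(counts, index=gene_ids, name="n_sites")
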