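"""Coverage filtering, differential methylation and DMSG construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from mirmeth.annotation import GeneCatalog, GeneModel, GenomicInterval, load_annotation
from mirmeth.methylome import (
    MethylationError,
    MethylationTable,
    build_dmsgs,
    diff_methylation,
    gene_methylation_level,
    gene_site_counts,
    load_methylation_calls,
    methylation_expression_direction,
)


def calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth_count", "unmeth_count"])


def site_table(site_specs, samples):
    """site_specs: {(chrom,pos): {sample: (meth, unmeth)}}"""
    idx = pd.MultiIndex.from_tuples(
        [(c, p, "+") for c, p in site_specs], names=["chrom", "pos", "strand"]
    )
    meth = pd.DataFrame(
        {s: [site_specs[k][s][0] for k in site_specs] for s in samples}, index=idx
    )
    unmeth = pd.DataFrame(
        {s: [site_specs[k][s][1] for k in site_specs] for s in samples}, index=idx
    )
    return MethylationTable(meth=meth, unmeth=unmeth)


class TestLoadAndFilter:
    def test_low_coverage_site_excluded(self):
        per_sample = {
            "s1": calls([("Chr1", 100, "+", 4, 5)]),  # coverage 9
            "s2": calls([("Chr1", 100, "+", 8, 8)]),
        }
        table = load_methylation_calls(per_sample, min_coverage=10)
        assert len(table.sites) == 0

    def test_all_covered_sites_retained(self):
        per_sample = {
            "s1": calls([("Chr1", 100, "+", 6, 6), ("Chr1", 200, "+", 10, 2)]),
            "s2": calls([("Chr1", 100, "+", 5, 7), ("Chr1", 200, "+", 3, 9)]),
        }
        table = load_methylation_calls(per_sample, min_coverage=10)
        assert len(table.sites) == 2

    def test_twenty_site_hand_filtered_list(self, rng):
        specs = {}
        expected = []
        for i in range(20):
            pos = 100 + 10 * i
            cov1 = int(rng.integers(5, 30))
            cov2 = int(rng.integers(5, 30))
            specs[("Chr1", pos)] = {"s1": (cov1 // 2, cov1 - cov1 // 2),
                                    "s2": (cov2 // 2, cov2 - cov2 // 2)}
            if cov1 >= 10 and cov2 >= 10:
                expected.append(pos)
        per_sample = {
            s: calls([("Chr1", p, "+", *specs[("Chr1", p)][s]) for _, p in specs])
            for s in ("s1", "s2")
        }
        table = load_methylation_calls(per_sample, min_coverage=10)
        assert sorted(table.sites.get_level_values("pos")) == sorted(expected)

    def test_strand_merge_sums_symmetric_pair(self):
        per_sample = {
            "s1": calls(
                [("Chr1", 100, "+", 6, 6), ("Chr1", 101, "-", 4, 8)]
            )
        }
        table = load_methylation_calls(per_sample, min_coverage=10, merge_strands=True)
        assert len(table.sites) == 1
        assert int(table.meth.iloc[0, 0]) == 10 and int(table.unmeth.iloc[0, 0]) == 14

    def test_conflicting_strands_rejected(self):
        per_sample = {
            "s1": calls([("Chr1", 100, "+", 6, 6)]),
            "s2": calls([("Chr1", 100, "-", 6, 6)]),
        }
        with pytest.raises(MethylationError, match="strand"):
            load_methylation_calls(per_sample, min_coverage=1)


class TestDiffMethylation:
    def test_identical_rates_excluded(self):
        table = site_table(
            {("Chr1", 100): {"a": (30, 70), "b": (30, 70)}}, ["a", "b"]
        )
        out = diff_methylation(table, ["a"], ["b"])
        assert len(out) == 0

    def test_large_shift_direction_and_reference_p(self):
        table = site_table(
            {("Chr1", 100): {"a": (5, 95), "b": (60, 40)}}, ["a", "b"]
        )
        out = diff_methylation(table, ["a"], ["b"], diff_min=25, q_max=0.05)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["meth_diff"] == pytest.approx(55.0)
        assert row["direction"] == "up"
        ref_p = ss.fisher_exact([[60, 40], [5, 95]])[1]
        assert row["p_value"] == pytest.approx(ref_p, abs=1e-12)

    def test_antisymmetric_under_group_swap(self, rng):
        specs = {
            ("Chr1", 100 + i): {
                "a": (int(rng.integers(0, 40)), int(rng.integers(1, 40))),
                "b": (int(rng.integers(0, 40)), int(rng.integers(1, 40))),
            }
            for i in range(30)
        }
        table = site_table(specs, ["a", "b"])
        fwd = diff_methylation(table, ["a"], ["b"], diff_min=0, q_max=1.01)
        rev = diff_methylation(table, ["b"], ["a"], diff_min=0, q_max=1.01)
        merged = fwd.merge(rev, on=["chrom", "pos"], suffixes=("_f", "_r"))
        assert np.allclose(merged["meth_diff_f"], -merged["meth_diff_r"])
        assert np.allclose(merged["q_value_f"], merged["q_value_r"])

    def test_thresholds_are_monotone_filters(self, rng):
        specs = {
            ("Chr1", 100 + i): {
                "a": (int(rng.integers(0, 60)), int(rng.integers(1, 60))),
                "b": (int(rng.integers(0, 60)), int(rng.integers(1, 60))),
            }
            for i in range(100)
        }
        table = site_table(specs, ["a", "b"])
        loose = diff_methylation(table, ["a"], ["b"], diff_min=10, q_max=0.2)
        tight_diff = diff_methylation(table, ["a"], ["b"], diff_min=30, q_max=0.2)
        tight_q = diff_methylation(table, ["a"], ["b"], diff_min=10, q_max=0.01)
        assert len(tight_diff) <= len(loose) and len(tight_q) <= len(loose)

    def test_null_beta_binomial_fdr_controlled(self):
        """Equal-rate groups: the q < 0.01 discovery fraction stays near zero."""
        fracs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n_sites = 2000
            theta = rng.beta(0.2 * 25, 0.8 * 25, size=n_sites)
            specs = {}
            meth = {}
            unmeth = {}
            for grp in ("a1", "a2", "b1", "b2"):
                cov = rng.poisson(30, size=n_sites) + 10
                p = rng.beta(theta * 60, (1 - theta) * 60)
                m = rng.binomial(cov, p)
                meth[grp] = m
                unmeth[grp] = cov - m
            idx = pd.MultiIndex.from_tuples(
                [("Chr1", 100 + i, "+") for i in range(n_sites)],
                names=["chrom", "pos", "strand"],
            )
            table = MethylationTable(
                meth=pd.DataFrame(meth, index=idx),
                unmeth=pd.DataFrame(unmeth, index=idx),
            )
            out = diff_methylation(table, ["a1", "a2"], ["b1", "b2"], diff_min=0, q_max=0.01)
            fracs.append(len(out) / n_sites)
        assert np.mean(fracs) <= 0.01


def fixture_catalog_and_sites():
    """Re-express the packaged 22-row reference table as a catalog + sites.

    Each gene is synthesized so its transcribed site lands in the labelled
    compartment (promoter sites 1 bp upstream of the TSS).
    """
    from mirmeth.pipeline import load_table1_fixture

    df = load_table1_fixture()
    genes = {}
    site_rows = []
    for row in df.itertuples():
        chrom, pos = row.methy_site.split(":")
        pos = int(pos)
        if row.location == "Gene body":
            start = max(0, pos - 50)
            end = start + 500
        else:  # promoter: site 1 bp upstream of the TSS
            start = pos
            end = start + 500
        span = GenomicInterval(chrom, start, end, "+")
        genes[row.gene_id] = GeneModel(
            gene_id=row.gene_id,
            span=span,
            symbol=row.gene_name,
            utr5=[GenomicInterval(chrom, start, start + 100, "+")],
            cds=[GenomicInterval(chrom, start + 100, start + 400, "+")],
            utr3=[GenomicInterval(chrom, start + 400, end, "+")],
        )
        site_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": "+",
                "meth_diff": 30.0 if row.diff_methy == "Up" else -30.0,
                "p_value": 1e-6,
                "q_value": 1e-5,
                "direction": "up" if row.diff_methy == "Up" else "down",
            }
        )
    catalog = GeneCatalog(genes=genes)
    functional = dict(zip(df["gene_id"], df["pathway"]))
    return catalog, pd.DataFrame(site_rows), functional, df


class TestBuildDmsgs:
    def test_reference_table_counts_recovered(self):
        catalog, sites, functional, df = fixture_catalog_and_sites()
        dmsgs = build_dmsgs(sites, catalog, functional)
        by_pathway = dmsgs.groupby("function_label")["gene_id"].nunique()
        assert by_pathway["ion_transport"] == 14
        assert by_pathway["faa"] == 8
        ion = dmsgs[dmsgs["function_label"] == "ion_transport"]
        assert round(100 * (ion["location"] == "gene_body").mean()) == 64
        # location labels match the table row by row
        merged = dmsgs.merge(df, on="gene_id")
        expected = merged["location_y"].map({"Gene body": "gene_body", "Promoter": "promoter"})
        assert (merged["location_x"] == expected).all()

    def test_intergenic_site_contributes_nothing(self, toy_catalog):
        sites = pd.DataFrame(
            [{"chrom": "Chr1", "pos": 50_000, "strand": "+", "meth_diff": 40.0,
              "p_value": 1e-5, "q_value": 1e-4, "direction": "up"}]
        )
        assert len(build_dmsgs(sites, toy_catalog)) == 0

    def test_site_shared_by_two_overlapping_genes(self):
        # promoter of gA (+ strand, span 5000..5500) covers 3000..5000;
        # gB's body covers 4000..4800 -> a site at 4500 hits both
        gA = GeneModel("gA", GenomicInterval("Chr1", 5000, 5500, "+"))
        gB = GeneModel("gB", GenomicInterval("Chr1", 4000, 4800, "+"))
        catalog = GeneCatalog(genes={"gA": gA, "gB": gB})
        sites = pd.DataFrame(
            [{"chrom": "Chr1", "pos": 4501, "strand": "+", "meth_diff": 30.0,
              "p_value": 1e-5, "q_value": 1e-4, "direction": "up"}]
        )
        dmsgs = build_dmsgs(sites, catalog)
        assert len(dmsgs) == 2
        by_gene = dmsgs.set_index("gene_id")["location"]
        assert by_gene["gA"] == "promoter" and by_gene["gB"] == "gene_body"

    def test_output_genes_subset_of_interval_scan_oracle(self, small_bundle):
        catalog = load_annotation(small_bundle.gff3, small_bundle.chrom_lengths)
        rng = np.random.default_rng(3)
        sites = pd.DataFrame(
            {
                "chrom": rng.choice(["Chr1", "Chr2"], size=300),
                "pos": rng.integers(1, 300_000, size=300),
                "strand": "+",
                "meth_diff": 30.0,
                "p_value": 1e-5,
                "q_value": 1e-4,
                "direction": "up",
            }
        )
        dmsgs = build_dmsgs(sites, catalog)
        # oracle: brute-force linear scan over every gene for every site
        expected = set()
        for row in sites.itertuples():
            for gene in catalog:
                if gene.span.chrom != row.chrom:
                    continue
                p0 = row.pos - 1
                if gene.span.start <= p0 < gene.span.end:
                    expected.add((gene.gene_id, row.pos, "gene_body"))
                elif gene.strand == "+" and gene.span.start - 2000 <= p0 < gene.span.start:
                    expected.add((gene.gene_id, row.pos, "promoter"))
                elif gene.strand == "-" and gene.span.end <= p0 < gene.span.end + 2000:
                    expected.add((gene.gene_id, row.pos, "promoter"))
        got = {(r.gene_id, r.pos, r.location) for r in dmsgs.itertuples()}
        assert got == expected

    def test_top_site_mode_keeps_one_site_per_gene(self):
        gA = GeneModel("gA", GenomicInterval("Chr1", 1000, 2000, "+"))
        catalog = GeneCatalog(genes={"gA": gA})
        sites = pd.DataFrame(
            [
                {"chrom": "Chr1", "pos": 1101, "strand": "+", "meth_diff": 30.0,
                 "p_value": 1e-5, "q_value": 1e-4, "direction": "up"},
                {"chrom": "Chr1", "pos": 1201, "strand": "+", "meth_diff": -60.0,
                 "p_value": 1e-6, "q_value": 1e-5, "direction": "down"},
            ]
        )
        top = build_dmsgs(sites, catalog, top_site_only=True)
        assert len(top) == 1 and top.iloc[0]["pos"] == 1201


class TestDirectionAndLevels:
    def test_identical_profiles_positive(self):
        prof = [0.1, 0.2, 0.3, 0.25, 0.4, 0.5]
        assert methylation_expression_direction(prof, prof) == "positive"

    def test_mirrored_profiles_negative(self):
        prof = np.array([0.1, 0.2, 0.3, 0.25, 0.4, 0.5])
        assert methylation_expression_direction(prof, 1 - prof) == "negative"

    def test_planted_negative_coupling_recovered(self):
        """Planted negative methylation-expression coupling is recovered."""
        from mirmeth.synthetic import SimConfig, generate

        recovered, total = 0, 0
        for seed in range(200):
            bundle = generate(SimConfig(seed=seed, n_genes=60, dm_shift=40.0))
            truth = bundle.truth["true_dm_sites"]
            neg = truth[truth["coupling"] == "negative"]
            if not len(neg):
                continue
            sheet = bundle.sample_sheet
            times = sorted(sheet["time_h"].unique())
            cols = {t: sheet.loc[sheet["time_h"] == t, "sample_id"].tolist() for t in times}
            for row in neg.itertuples():
                meth_prof, expr_prof = [], []
                for t in times:
                    m = u = 0
                    for s in cols[t]:
                        df = bundle.cpg_calls[s]
                        hit = df[(df["chrom"] == row.chrom) & (df["pos"] == row.pos)]
                        m += int(hit["meth_count"].iloc[0])
                        u += int(hit["unmeth_count"].iloc[0])
                    meth_prof.append(m / (m + u))
                    expr_prof.append(bundle.gene_counts.loc[row.gene_id, cols[t]].mean())
                total += 1
                recovered += methylation_expression_direction(meth_prof, expr_prof) == "negative"
        assert total >= 50
        assert recovered / total >= 0.95

    def test_single_site_level(self):
        g = GeneModel("g", GenomicInterval("Chr1", 1000, 2000, "+"))
        table = site_table({("Chr1", 1500): {"s1": (50, 50)}}, ["s1"])
        assert gene_methylation_level(g, table, ["s1"]) == pytest.approx(0.5)

    def test_unweighted_mean_of_extreme_sites(self):
        g = GeneModel("g", GenomicInterval("Chr1", 1000, 2000, "+"))
        table = site_table(
            {("Chr1", 1100): {"s1": (20, 0)}, ("Chr1", 1200): {"s1": (0, 10)}}, ["s1"]
        )
        assert gene_methylation_level(g, table, ["s1"]) == pytest.approx(0.5)
        assert gene_methylation_level(g, table, ["s1"], coverage_weighted=True) == pytest.approx(20 / 30)

    def test_five_site_hand_mean(self, rng):
        g = GeneModel("g", GenomicInterval("Chr1", 1000, 3000, "+"))
        specs, rates = {}, []
        for i in range(5):
            m, u = int(rng.integers(1, 40)), int(rng.integers(1, 40))
            specs[("Chr1", 1100 + i * 100)] = {"s1": (m, u)}
            rates.append(m / (m + u))
        table = site_table(specs, ["s1"])
        assert gene_methylation_level(g, table, ["s1"]) == pytest.approx(np.mean(rates))

    def test_no_covered_sites_is_nan(self):
        g = GeneModel("g", GenomicInterval("Chr2", 1000, 2000, "+"))
        table = site_table({("Chr1", 1500): {"s1": (5, 5)}}, ["s1"])
        assert np.isnan(gene_methylation_level(g, table, ["s1"]))

    def test_site_counts_include_promoter(self):
        g = GeneModel("g", GenomicInterval("Chr1", 5000, 6000, "+"))
        catalog = GeneCatalog(genes={"g": g})
        table = site_table(
            {("Chr1", 4500): {"s1": (5, 5)},   # promoter
             ("Chr1", 5500): {"s1": (5, 5)},   # body
             ("Chr1", 9000): {"s1": (5, 5)}},  # outside
            ["s1"],
        )
        assert gene_site_counts(catalog, table).loc["g"] == 2
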