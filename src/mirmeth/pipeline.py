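"""End-to-end orchestration: annotation → differential → targeting →
methylome → integration, with a machine-readable run manifest.

Every report table starts with a ``#`` header comment declaring its column
schema, so all outputs re-parse through the package's own readers. Runs are
deterministic given the configuration (including the permutation seed);
wall-clock timestamps live only in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
import time
from dataclasses import asdict, dataclass
from importlib import resources
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotation import load_annotation, read_chrom_lengths
from .differential import (
    call_differential,
    read_counts,
    read_sample_sheet,
    simple_de_test,
)
from .integration import (
    classify_regulation,
    dual_regulation_permutation,
    lfc_group_comparison,
    mode_proportions,
    mutual_regulation_report,
    structural_complementarity,
)
from .methylome import (
    build_dmsgs,
    diff_methylation,
    gene_methylation_levels,
    gene_site_counts,
    load_methylation_calls,
)
from .targeting import (
    assign_regions,
    attach_correlation,
    intersect_predictions,
    pairs_active_at,
    pairs_to_frame,
    read_predictions,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "summarize_table1_fixture",
    "load_table1_fixture",
]

TABLE1_SHA256 = "81c56fb49277be062d6573fb9ae9130faf11811849a85f326afd7d5f1eba1a98"

REPORT_FILES = [
    "regulation_calls.tsv",
    "mode_proportions.tsv",
    "permutation.json",
    "complementarity.tsv",
    "lfc_groups.tsv",
    "mutual_regulation.tsv",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """All input paths and thresholds of one pipeline run."""

    annotation: str
    sample_sheet: str
    gene_counts: str
    mirna_counts: str
    predictions_a: str
    predictions_b: str
    cpg_dir: str
    functional_genes: str
    out_dir: str
    chrom_lengths: Optional[str] = None
    lfc_min: float = 1.0
    alpha: float = 0.05
    energy_max: float = -20.0
    diff_min: float = 25.0
    q_max: float = 0.01
    min_coverage: int = 10
    upstream_bp: int = 2000
    promoter_strand_aware: bool = True
    iterations: int = 1000
    permutation_seed: int = 0
    cohort: str = "de"  # 'de' | 'all'
    universe: str = "functional"  # 'functional' | 'all'

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "annotation": self.annotation,
            "sample_sheet": self.sample_sheet,
            "gene_counts": self.gene_counts,
            "mirna_counts": self.mirna_counts,
            "predictions_a": self.predictions_a,
            "predictions_b": self.predictions_b,
            "cpg_dir": self.cpg_dir,
            "functional_genes": self.functional_genes,
        }
        if self.chrom_lengths:
            paths["chrom_lengths"] = self.chrom_lengths
        return paths


def _log(stage: str, message: str) -> None:
    print(f"[mirmeth:{stage}] {message}", file=sys.stderr)


def _write_table(df: pd.DataFrame, path: str, schema: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# columns: {schema}\n")
        df.to_csv(fh, sep="\t", index=False)


def _file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report files under ``config.out_dir``.

    Returns a summary dict with per-stage record counts. A stage failure
    raises :class:`PipelineError` after writing an error manifest; outputs of
    completed stages are left in place.
    """
    missing = [p for p in config.input_paths().values() if not os.path.exists(p)]
    if missing:
        raise PipelineError("startup", f"missing inputs: {missing}")
    os.makedirs(config.out_dir, exist_ok=True)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "inputs_sha256": {
            name: (_file_sha256(p) if os.path.isfile(p) else "directory")
            for name, p in config.input_paths().items()
        },
        "started_unix": time.time(),
        "stages": {},
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")

    def checkpoint(stage: str, **counts):
        manifest["stages"][stage] = counts
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        _log(stage, ", ".join(f"{k}={v}" for k, v in counts.items()) or "done")

    stage = "annotation"
    try:
        chrom_lengths = None
        if config.chrom_lengths:
            with open(config.chrom_lengths) as fh:
                chrom_lengths = read_chrom_lengths(fh)
        with open(config.annotation) as fh:
            catalog = load_annotation(fh, chrom_lengths)
        checkpoint(stage, genes=len(catalog))

        stage = "differential"
        sheet = read_sample_sheet(config.sample_sheet)
        gene_counts = read_counts(config.gene_counts)
        mirna_counts = read_counts(config.mirna_counts)
        times = sorted(t for t in sheet["time_h"].unique() if t != 0)
        deg_sets, demirna_sets, gene_stats = {}, {}, {}
        for t in times:
            gstats = simple_de_test(gene_counts, sheet, (0, t))
            gene_stats[t] = gstats.set_index("entity_id")
            deg_sets[t] = call_differential(gstats, config.lfc_min, config.alpha)
            mstats = simple_de_test(mirna_counts, sheet, (0, t))
            demirna_sets[t] = call_differential(mstats, config.lfc_min, config.alpha)
        checkpoint(
            stage,
            degs=sum(len(s) for s in deg_sets.values()),
            demirnas=sum(len(s) for s in demirna_sets.values()),
        )

        stage = "targeting"
        preds_a = read_predictions(config.predictions_a)
        preds_b = read_predictions(config.predictions_b)
        pairs = intersect_predictions(preds_a, preds_b, config.energy_max)
        pairs = assign_regions(pairs, catalog)
        mean_by_time = {
            "gene": _profiles(gene_counts, sheet),
            "mirna": _profiles(mirna_counts, sheet),
        }
        pairs = attach_correlation(pairs, mean_by_time["mirna"], mean_by_time["gene"])
        _write_table(
            pairs_to_frame(pairs),
            os.path.join(config.out_dir, "target_pairs.tsv"),
            "mirna_id gene_id t_start t_end region energy_best n_sites r p sign",
        )
        checkpoint(stage, pairs=len(pairs))

        stage = "methylome"
        cpg_files = {
            os.path.splitext(f)[0]: os.path.join(config.cpg_dir, f)
            for f in sorted(os.listdir(config.cpg_dir))
            if f.endswith(".tsv")
        }
        table = load_methylation_calls(cpg_files, config.min_coverage)
        functional = pd.read_csv(config.functional_genes, sep="\t", comment="#")
        functional_map = dict(zip(functional["gene_id"], functional["pathway"]))
        samples_of = {
            t: sheet.loc[sheet["time_h"] == t, "sample_id"].tolist()
            for t in sorted(sheet["time_h"].unique())
        }
        dmsg_frames = []
        for t in times:
            diff = diff_methylation(
                table,
                samples_of[0],
                samples_of[t],
                config.diff_min,
                config.q_max,
                contrast=(0, t),
            )
            dmsg_frames.append(
                build_dmsgs(
                    diff, catalog, functional_map, config.upstream_bp,
                    config.promoter_strand_aware,
                )
            )
        non_empty = [f for f in dmsg_frames if len(f)]
        dmsgs = pd.concat(non_empty or dmsg_frames[:1], ignore_index=True)
        _write_table(
            dmsgs,
            os.path.join(config.out_dir, "dmsgs.tsv"),
            "gene_id symbol chrom pos location meth_diff direction ref_time test_time function_label",
        )
        checkpoint(stage, sites=len(table.sites), dmsg_records=len(dmsgs))

        stage = "integration"
        functional_genes = list(functional["gene_id"])
        calls_rows, props_rows, lfc_rows = [], [], []
        mirna_union, meth_union = set(), set()
        for t in times:
            active = pairs_active_at(pairs, t, demirna_sets[t], deg_sets[t])
            dmsg_t = dmsgs[dmsgs["test_time"] == t] if len(dmsgs) else dmsgs
            calls = classify_regulation(
                t, deg_sets[t].entity_ids, active, dmsg_t, functional_genes,
                config.cohort,
            )
            mirna_union |= {c.gene_id for c in calls if c.mirna_evidence}
            meth_union |= {c.gene_id for c in calls if c.meth_evidence}
            props = mode_proportions(calls)
            props_rows.append({"time_h": t, **props["proportions"],
                               "n_with_evidence": props["n_with_evidence"],
                               "n_none": props["n_none"]})
            for c in calls:
                calls_rows.append(
                    {
                        "gene_id": c.gene_id,
                        "time_h": c.time_h,
                        "mode": c.mode,
                        "n_mirna_evidence": len(c.mirna_evidence),
                        "n_meth_evidence": len(c.meth_evidence),
                    }
                )
            comp = lfc_group_comparison(calls, gene_stats[t]["log2fc"])
            for label, res in comp.items():
                lfc_rows.append(
                    {
                        "time_h": t,
                        "comparison": label,
                        "p_value": res.p_value if res else None,
                        "n1": res.n1 if res else 0,
                        "n2": res.n2 if res else 0,
                    }
                )
        _write_table(
            pd.DataFrame(calls_rows),
            os.path.join(config.out_dir, "regulation_calls.tsv"),
            "gene_id time_h mode n_mirna_evidence n_meth_evidence",
        )
        _write_table(
            pd.DataFrame(props_rows),
            os.path.join(config.out_dir, "mode_proportions.tsv"),
            "time_h mirna_only methylation_only dual n_with_evidence n_none",
        )
        _write_table(
            pd.DataFrame(lfc_rows),
            os.path.join(config.out_dir, "lfc_groups.tsv"),
            "time_h comparison p_value n1 n2",
        )

        universe = (
            functional_genes if config.universe == "functional"
            else [g.gene_id for g in catalog]
        )
        perm = dual_regulation_permutation(
            universe,
            mirna_union & set(universe),
            meth_union & set(universe),
            iterations=config.iterations,
            seed=config.permutation_seed,
        )
        with open(os.path.join(config.out_dir, "permutation.json"), "w") as fh:
            fh.write(perm.to_json(indent=1, sort_keys=True))

        targeted = sorted({p.gene_id for p in pairs} & set(functional_genes))
        others = sorted(set(functional_genes) - set(targeted))
        levels = gene_methylation_levels(
            catalog, table, samples_of, config.upstream_bp, genes=functional_genes
        )
        site_counts = gene_site_counts(
            catalog, table, config.upstream_bp, genes=functional_genes
        )
        comp_report = structural_complementarity(targeted, others, levels, site_counts)
        comp_df = comp_report.levels.copy()
        if comp_report.site_count_test is not None:
            comp_df.attrs["site_count_p"] = comp_report.site_count_test.p_value
        _write_table(
            comp_df,
            os.path.join(config.out_dir, "complementarity.tsv"),
            "time_h n_targeted n_other n_missing targeted_mean targeted_sd "
            "other_mean other_sd p_value stars",
        )
        symbols = {g.gene_id: g.symbol for g in catalog}
        _write_table(
            mutual_regulation_report(pairs, dmsgs, symbols),
            os.path.join(config.out_dir, "mutual_regulation.tsv"),
            "watch_gene gene_id symbol layer partner region sign site_count direction",
        )
        checkpoint(
            stage,
            calls=len(calls_rows),
            permutation_p=perm.p_empirical,
            observed_overlap=perm.observed_overlap,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - converted to a stage error
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise PipelineError(stage, str(exc)) from exc

    manifest["finished_unix"] = time.time()
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {"stages": manifest["stages"], "out_dir": config.out_dir}


def _profiles(counts: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-time replicate-mean expression profiles (entities × time points)."""
    out = {}
    for t in sorted(sheet["time_h"].unique()):
        cols = sheet.loc[sheet["time_h"] == t, "sample_id"].tolist()
        out[t] = counts[cols].mean(axis=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# packaged reference table

def load_table1_fixture(verify: bool = True) -> pd.DataFrame:
    """The packaged 22-row DMSG reference table (one site per gene, with
    location, methylation direction, expression-correlation sign, function
    and pathway class)."""
    ref = resources.files("mirmeth").joinpath("data/table1_dmsg.tsv")
    raw = ref.read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE1_SHA256:
            raise PipelineError(
                "table1", f"fixture checksum mismatch: {digest} != {TABLE1_SHA256}"
            )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


def summarize_table1_fixture() -> dict:
    """Counts and breakdowns of the packaged DMSG reference table.

    Returns per-pathway gene counts, per-pathway location fractions, and
    direction/correlation tallies.
    """
    df = load_table1_fixture()
    out: dict = {"n_rows": len(df), "pathways": {}}
    for pathway, sub in df.groupby("pathway"):
        n = len(sub)
        gene_body = int((sub["location"] == "Gene body").sum())
        out["pathways"][pathway] = {
            "n_genes": int(sub["gene_id"].nunique()),
            "n_sites": n,
            "gene_body_fraction": gene_body / n,
            "promoter_fraction": (n - gene_body) / n,
            "direction": sub["diff_methy"].value_counts().to_dict(),
            "correlation": sub["correlation"].value_counts().to_dict(),
        }
    return out
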