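"""Orchestration of the two analyses: timepoint comparison and multi-sample
landscape comparison.

A :class:`RunConfig` (usually loaded from YAML) names the per-sample track and
hotspot files, optional masks and annotation, thresholds, and one root seed.
Every stage writes plain-text intermediates (TSV/BED/Newick) so each step is
independently inspectable, and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate as ann_mod
from . import enrich as enrich_mod
from . import landscapes as land_mod
from .dynamic import ConeParams, call_dynamic
from .intervals import IntervalSet, merge, read_bed, read_gff_genes, subtract_mask, write_bed
from .quantify import DhsMatrix, SampleProfile, filter_low_signal, read_bedgraph

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_timepoint_analysis", "run_landscape_analysis"]

DEFAULT_THRESHOLDS = {
    "min_mean": 50,        # low-signal row filter on raw counts
    "fold": 2.0,           # expression fold-change cutoff
    "tss_window": 400,     # bp upstream of TSS
    "subsample": 10_000,   # DHS rows per bootstrap tree
    "n_trees": 100,
    "large_dhs_min_cleavage": 50,
}


@dataclass
class RunConfig:
    """Everything one run needs; file paths are resolved at load time."""

    samples: dict                 # name -> {"track": path, "hotspots": path}
    outdir: Path
    masks: dict = field(default_factory=dict)        # label -> BED path
    cone: ConeParams = field(default_factory=ConeParams)
    thresholds: dict = field(default_factory=dict)
    annotation: dict = field(default_factory=dict)   # {"gff": path, "te": path}
    expression: dict = field(default_factory=dict)   # {"table": path, "t1": col, "t2": col}
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.thresholds = {**DEFAULT_THRESHOLDS, **self.thresholds}
        for name, files in self.samples.items():
            for key in ("track", "hotspots"):
                p = Path(files[key])
                if not p.exists():
                    raise FileNotFoundError(f"sample {name}: missing {key} file {p}")
        for label, path in self.masks.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"mask {label}: missing file {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cone = ConeParams(**raw.get("cone", {}))
        base = Path(path).parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        samples = {
            name: {k: resolve(v) for k, v in files.items()}
            for name, files in raw["samples"].items()
        }
        masks = {k: resolve(v) for k, v in raw.get("masks", {}).items()}
        annotation = {k: resolve(v) for k, v in raw.get("annotation", {}).items()}
        expression = dict(raw.get("expression", {}))
        if "table" in expression:
            expression["table"] = resolve(expression["table"])
        return cls(samples=samples, outdir=resolve(raw.get("outdir", "out")),
                   masks=masks, cone=cone, thresholds=raw.get("thresholds", {}),
                   annotation=annotation, expression=expression,
                   seed=int(raw.get("seed", 0)))

    def load_profiles(self) -> list:
        return [
            SampleProfile(name, read_bedgraph(files["track"]),
                          read_bed(files["hotspots"]))
            for name, files in sorted(self.samples.items())
        ]

    def load_mask(self, label: str):
        return read_bed(self.masks[label]) if label in self.masks else None


def _write_log(config: RunConfig, stage: str, extra: dict) -> None:
    payload = {
        "stage": stage,
        "seed": config.seed,
        "cone": {"slope_margin": config.cone.slope_margin,
                 "intercept": config.cone.intercept,
                 "min_cleavage": config.cone.min_cleavage},
        "thresholds": config.thresholds,
        **extra,
    }
    path = config.outdir / f"{stage}_run.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    logger.info("%s: wrote %s", stage, path)


def run_timepoint_analysis(config: RunConfig) -> dict:
    """Two-sample comparison: union DHSs -> matrix -> dynamic calls ->
    contexts -> gene assignment -> expression enrichment."""
    profiles = config.load_profiles()
    if len(profiles) != 2:
        raise ValueError("timepoint analysis needs exactly 2 samples")
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    name_a, name_b = profiles[0].name, profiles[1].name

    union = merge(IntervalSet(
        [iv for p in profiles for iv in p.hotspots], label="union"))
    centromeres = config.load_mask("centromeres")
    if centromeres is not None:
        union = subtract_mask(union, centromeres)
    write_bed(union, out / "union_dhs.bed")

    matrix = DhsMatrix.from_samples(union, profiles)
    matrix = filter_low_signal(matrix, config.thresholds["min_mean"])
    matrix.to_tsv(out / "dhs_matrix.tsv")

    calls, summary = call_dynamic(matrix, name_a, name_b, config.cone)
    report: dict = {
        "samples": [name_a, name_b],
        "n_union_dhs": len(union),
        "n_matrix_dhs": len(matrix.dhss),
        "n_activated": summary["n_above"],
        "n_deactivated": summary["n_below"],
    }

    genes = []
    annotation = None
    if "gff" in config.annotation:
        genes = read_gff_genes(config.annotation["gff"])
        tes = (read_bed(config.annotation["te"])
               if "te" in config.annotation else IntervalSet())
        annotation = ann_mod.AnnotationSet(
            genes, tes, tss_window=config.thresholds["tss_window"])

    with open(out / "dynamic_calls.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tlog10_a\tlog10_b\tlabel\tcontexts\tgenes\n")
        for call in calls:
            ctx = (",".join(sorted(ann_mod.genomic_context(call.dhs, annotation)))
                   if annotation else "")
            gids = (",".join(ann_mod.assign_genes(call.dhs, genes))
                    if genes else "")
            fh.write(f"{call.dhs.chrom}\t{call.dhs.start}\t{call.dhs.end}\t"
                     f"{call.x:.4f}\t{call.y:.4f}\t{call.label}\t{ctx}\t{gids}\n")

    if genes:
        per_gene = ann_mod.dynamic_dhs_per_gene(calls, genes)
        report["n_genes_near_dynamic"] = len(per_gene)
        if "table" in config.expression:
            expr = enrich_mod.ExpressionTable.from_tsv(config.expression["table"])
            t1, t2 = config.expression["t1"], config.expression["t2"]
            up, down = enrich_mod.diff_expressed(
                expr, t1, t2, fold=config.thresholds["fold"])
            universe = {g.gene_id for g in genes}
            by_dir = ann_mod.genes_by_direction(calls, genes)
            grid = enrich_mod.direction_concordance(
                up & universe, down & universe,
                by_dir["activated"], by_dir["deactivated"], universe)
            with open(out / "concordance.tsv", "w") as fh:
                fh.write("expression\taccessibility\tuniverse_n\tset1_n\tset2_n\t"
                         "observed\texpected\tfold\tp\n")
                for (r, c), res in sorted(grid.items()):
                    if res is None:
                        fh.write(f"{r}\t{c}\tNA\tNA\tNA\tNA\tNA\tNA\tNA\n")
                    else:
                        d = res.as_dict()
                        fh.write(f"{r}\t{c}\t{d['universe_n']}\t{d['set1_n']}\t"
                                 f"{d['set2_n']}\t{d['observed']}\t"
                                 f"{d['expected']:.4f}\t{d['fold']:.4f}\t"
                                 f"{d['p']:.4g}\n")
            report["concordance"] = {
                f"{r}|{c}": (res.fold if res else None)
                for (r, c), res in grid.items()
            }
        else:
            logger.warning("no expression table configured; enrichment skipped")

    _write_log(config, "timepoint", report)
    return report


def run_landscape_analysis(config: RunConfig) -> dict:
    """Multi-sample comparison: high-confidence union, unique bases,
    saturation, bootstrap dendrogram, PCA, pairwise dynamic counts."""
    profiles = config.load_profiles()
    if len(profiles) < 3:
        raise ValueError("landscape analysis needs at least 3 samples")
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)

    landscape = land_mod.build_union(
        profiles, min_cleavage=config.thresholds["large_dhs_min_cleavage"])
    write_bed(landscape.union_dhss, out / "landscape_union.bed")
    report_ub = land_mod.unique_bases(landscape)
    report_ub.to_frame().to_csv(out / "unique_bases.tsv", sep="\t")
    order, cumulative = land_mod.saturation_curve(landscape)
    with open(out / "saturation.tsv", "w") as fh:
        fh.write("sample\tcumulative_bp\n")
        for name, bp in zip(order, cumulative):
            fh.write(f"{name}\t{bp}\n")

    matrix = DhsMatrix.from_samples(landscape.union_dhss, profiles, normalize=True)
    matrix.to_tsv(out / "landscape_matrix.tsv")

    subsample = min(config.thresholds["subsample"], matrix.counts.shape[0])
    dendro = land_mod.bootstrap_dendrogram(
        matrix, n_trees=config.thresholds["n_trees"],
        subsample=subsample, seed=config.seed)
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")

    scores, evr = land_mod.pca_landscape(matrix, exclude=config.load_mask("pca_exclude"))
    scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.6g")

    raw = DhsMatrix.from_samples(landscape.union_dhss, profiles)
    names = [p.name for p in profiles]
    with open(out / "pairwise_dynamic.tsv", "w") as fh:
        fh.write("sample_a\tsample_b\tn_above\tn_below\n")
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                _, summary = call_dynamic(raw, a, b, config.cone)
                fh.write(f"{a}\t{b}\t{summary['n_above']}\t{summary['n_below']}\n")

    report = {
        "n_samples": len(names),
        "union_bases": landscape.union_bases,
        "unique_bp": report_ub.unique_bp,
        "saturation_order": order,
        "min_support": min(dendro.support.values()) if dendro.support else None,
        "explained_variance": [float(v) for v in evr],
    }
    _write_log(config, "landscape", report)
    return report
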