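"""End-to-end workflow: integrate → discover → annotate → layout → evaluate.

:func:`run_pipeline` binds the stages together from a single
:class:`PipelineConfig` and writes every artifact plus a machine-readable
run manifest into the output directory.  One global seed governs the whole
run; stage-specific generators are derived from it with fixed offsets so
stages stay independent yet the run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .association import InvalidInputError, compute_correlations, integrate
from .bicluster import SearchConfig, discover_modules
from .cooperativity import analyze_groupings, build_genomic_clusters
from .enrichment import (
    AnnotationSet,
    label_modules,
    permuted_baseline,
    validated_pair_density,
)
from .modulemap import layout_modules, plot_layout
from .synthetic import SyntheticDataset

__all__ = ["PipelineConfig", "run_pipeline", "write_dataset"]

logger = logging.getLogger(__name__)

# fixed offsets fanning the global seed out to independent stages
_SEED_COOP = 1
_SEED_BASELINE = 2


@dataclass
class PipelineConfig:
    """Inputs, stage settings and output location of one full run."""

    mirna_expression: str = ""
    mrna_expression: str = ""
    targets: str = ""
    target_dialect: str = "pairs"
    gene_annotation: str | None = None
    families: str | None = None
    loci: str | None = None
    validated_pairs: str | None = None
    out_dir: str = "mirmodules_run"

    search: SearchConfig = field(default_factory=SearchConfig)
    correlation_method: str = "spearman"
    n_permutations: int = 100
    cluster_window: int = 10_000
    bh_correct: bool = False
    palette_size: int = 10
    r_min: float = 0.0
    r_max: float = 1.0
    rng_seed: int = 0
    run_cooperativity: bool = True
    run_baseline: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        search = SearchConfig(**raw.pop("search", {}))
        return cls(search=search, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _require(path: str | None, what: str) -> str:
    if not path:
        raise InvalidInputError(f"missing required input: {what}")
    if not Path(path).exists():
        raise InvalidInputError(f"{what} file not found: {path}")
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(config.search, rng_seed=config.rng_seed)

    def stage(name: str):
        logger.info("stage: %s", name)

    try:
        stage("load")
        mirna_expr = mio.read_expression(_require(config.mirna_expression, "miRNA expression"))
        mrna_expr = mio.read_expression(_require(config.mrna_expression, "mRNA expression"))
        targets = mio.read_targets(
            _require(config.targets, "target predictions"),
            dialect=config.target_dialect,
            mirna_ids=list(mirna_expr.index),
            mrna_ids=list(mrna_expr.index),
        )
    except InvalidInputError as err:
        raise InvalidInputError(f"[load] {err}") from err

    stage("integrate")
    corr = compute_correlations(mirna_expr, mrna_expr, method=config.correlation_method)
    assoc = integrate(corr, targets)
    mio.write_matrix(assoc, out / "association_matrix.tsv")
    mio.write_sparse_triplets(assoc, out / "association_triplets.tsv")

    stage("bicluster")
    modules = discover_modules(assoc, cfg)

    stage("annotate")
    gene_annot = None
    if config.gene_annotation:
        gene_annot = mio.read_annotation(
            _require(config.gene_annotation, "gene annotation"),
            universe=set(assoc.columns),
        )
    mirna_annot = None
    groupings = []
    if config.families:
        groupings += mio.read_families(_require(config.families, "miRNA families"))
    if config.loci:
        loci = mio.read_bed_loci(_require(config.loci, "miRNA loci"))
        groupings += build_genomic_clusters(loci, window=config.cluster_window)
    if groupings:
        mirna_annot = AnnotationSet(
            {g.name: g.members for g in groupings},
            frozenset(assoc.index),
            kind="mirna_grouping",
        )
    label_modules(modules, gene_annot, mirna_annot)
    mio.write_modules_json(modules, out / "modules.json")
    mio.write_modules_tsv(modules, out / "modules.tsv")
    _write_enrichment_tsv(modules, out / "enrichment.tsv")

    stage("layout")
    if len(modules) >= 2:
        layouts = layout_modules(
            modules, palette_size=config.palette_size,
            r_min=config.r_min, r_max=config.r_max,
        )
        mio.write_layout_tsv(layouts, out / "layout.tsv")
        plot_layout(layouts, str(out / "module_map.svg"))

    results: dict = {"n_modules": len(modules)}
    if config.run_cooperativity and groupings:
        stage("cooperativity")
        usable = [g for g in groupings if g.members <= set(corr.index) and g.n > 2]
        if usable:
            table = analyze_groupings(
                corr, targets, usable, n_perm=config.n_permutations,
                rng=np.random.default_rng(config.rng_seed + _SEED_COOP),
            )
            mio.write_cooperativity_tsv(table, out / "cooperativity.tsv")
            results["n_cooperativity_groups"] = len(usable)

    baseline_modules = None
    if config.run_baseline and gene_annot is not None and modules:
        stage("permuted-baseline")
        base = permuted_baseline(
            assoc, cfg, gene_annot,
            rng=np.random.default_rng(config.rng_seed + _SEED_BASELINE),
            real_modules=modules,
        )
        baseline_modules = base.permuted_modules
        results["baseline_mannwhitney_p"] = base.mannwhitney_p

    if config.validated_pairs and modules:
        stage("validated-pairs")
        pairs = mio.read_validated_pairs(_require(config.validated_pairs, "validated pairs"))
        report = validated_pair_density(modules, pairs, baseline=baseline_modules)
        (out / "density_report.tsv").write_text(_density_tsv(report))
        results["validated_pair_density"] = report.density
        results["validated_pair_fold"] = report.fold

    manifest = {
        "package": "mirmodules",
        "rng_seed": config.rng_seed,
        "config": config.to_dict(),
        "results": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _write_enrichment_tsv(modules, path: Path) -> None:
    lines = ["module_id\tterm\tn\tN\tS\tp_value"]
    for mod in modules:
        ann = mod.annotation
        if ann is None:
            continue
        for r in ann.gene_results:
            lines.append(f"{mod.module_id}\t{r.term}\t{r.n}\t{r.N}\t{r.S}\t{r.p_value:.4g}")
    path.write_text("\n".join(lines) + "\n")


def _density_tsv(report) -> str:
    rows = [
        ("total_validated_pairs_in_modules", report.n_pairs_inside),
        ("covered_cells", report.covered_cells),
        ("density", report.density),
        ("modules_with_pair", report.modules_with_pair),
        ("mean_mirnas_per_module", report.mean_mirnas),
        ("mean_mrnas_per_module", report.mean_mrnas),
        ("baseline_density", report.baseline_density),
        ("fold_vs_baseline", report.fold),
    ]
    return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write every file dialect of a synthetic dataset plus the truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_expression(dataset.mirna_expr, out / "mirna_expression.tsv")
    mio.write_expression(dataset.mrna_expr, out / "mrna_expression.tsv")
    mio.write_targets(dataset.targets, out / "targets.tsv", dialect="pairs")
    mio.write_annotation(dataset.gene_annotation, out / "gene_annotation.tsv")
    mio.write_families(
        [g for g in dataset.mirna_groupings if g.kind == "family"],
        out / "families.tsv",
    )
    mio.write_validated_pairs(dataset.validated_pairs, out / "validated_pairs.tsv")
    (out / "truth.json").write_text(dataset.truth.to_json() + "\n")
    return out
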