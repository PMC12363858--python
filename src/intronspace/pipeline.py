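"""Run the full analysis from one configuration with seeds and provenance.

Stages per cell line: intron catalog statistics -> 3D-feature overlap ->
resampling nulls -> expression / essentiality context -> splicing indices ->
cross-cell-line matched sets.  Stages whose inputs are missing are skipped
and recorded; all randomness derives from a single master seed captured in
the output manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

from . import catalog as cat
from . import features as feat
from . import gene_context as gc
from . import resampling as rs
from . import splicing as spl

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class CellLineInputs:
    name: str
    tracks: dict[str, str] = field(default_factory=dict)  # feature_type -> path
    tpm: str | None = None
    alignments: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    catalog_path: str
    chrom_sizes: str
    gene_models: str | None = None
    cell_lines: list[CellLineInputs] = field(default_factory=list)
    essentialome_total: str | None = None
    essentialome_core: str | None = None
    reference_cell_line: str | None = None
    min_overlap_frac: float = 0.5
    tpm_thresholds: tuple[float, float] = (1.0, 20.0)
    fdr: float = 0.05
    bin_size_bp: int = 250_000
    n_boot: int = 1000
    fractions: tuple[float, ...] = rs.DEFAULT_FRACTIONS
    subsample: dict[str, int] = field(default_factory=lambda: dict(spl.DEFAULT_SUBSAMPLE))
    family_size: int = 15
    seed: int = 0
    out_dir: str = "intronspace_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        cells = [CellLineInputs(**c) for c in raw.pop("cell_lines", [])]
        try:
            cfg = cls(cell_lines=cells, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        for p in [cfg.catalog_path, cfg.chrom_sizes]:
            if not Path(p).exists():
                raise ConfigError(f"missing input: {p}")
        return cfg


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict[str, Any]
    tables: dict[str, Path] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def partial(self) -> bool:
        return bool(self.errors)

    def add_table(self, name: str, df: pd.DataFrame) -> None:
        path = self.out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        self.tables[name] = path
        self.manifest.setdefault("tables", {})[name] = {
            "path": str(path),
            "rows": int(len(df)),
        }

    def write_manifest(self) -> None:
        self.manifest["skipped"] = self.skipped
        self.manifest["errors"] = self.errors
        (self.out_dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str) + "\n"
        )


def _param_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: v for k, v in config.__dict__.items() if k != "cell_lines"},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


RARE = ("major_like", "hybrid", "minor_like", "minor", "non_canonical")


def run_full_analysis(config: RunConfig) -> ReportBundle:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(
        out_dir=out_dir,
        manifest={"seed": config.seed, "parameter_hash": _param_hash(config),
                  "parameters": {k: str(v) for k, v in config.__dict__.items()
                                 if k != "cell_lines"}},
    )
    catalog = cat.load_intron_catalog(
        config.catalog_path, "bed_zero_half_open", config.chrom_sizes
    )
    bundle.manifest["class_counts"] = catalog.class_counts()

    def _stage(name: str, fn) -> Any:
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.error("stage %s failed: %s", name, exc)
            bundle.errors[name] = f"{exc}\n{traceback.format_exc(limit=3)}"
            return None

    def _linear() -> None:
        summaries = [
            cat.inter_intron_distances(catalog, c) for c in catalog.class_counts()
        ]
        bundle.add_table("inter_intron_distances", cat.distance_summaries_frame(summaries))
        usable = [(catalog.class_counts()[s.intron_class], s.median_bp)
                  for s in summaries if s.median_bp and s.median_bp > 0]
        if len(usable) >= 3:
            fit = cat.abundance_distance_fit(*zip(*usable))
            cat.write_fit_json(fit, out_dir / "abundance_distance_fit.json")
            bundle.manifest["abundance_distance_fit"] = fit
        bins = cat.bin_intron_density(catalog, config.bin_size_bp)
        cat.scan_density_clusters(bins, fdr=config.fdr)
        bundle.add_table("density_bins", cat.density_bins_frame(bins))

    _stage("linear_stats", _linear)

    gene_models = None
    if config.gene_models and Path(config.gene_models).exists():
        gene_models = spl.load_gene_models_bed12(config.gene_models)

    essential = None
    if config.essentialome_total and config.essentialome_core:
        essential = _stage(
            "essentialome",
            lambda: gc.load_essentialome(config.essentialome_total, config.essentialome_core),
        )

    matrices: dict[str, feat.OverlapMatrix] = {}
    si_tables: dict[str, pd.DataFrame] = {}
    for cell in config.cell_lines:
        cl = cell.name
        if not cell.tracks:
            bundle.skipped[f"overlap[{cl}]"] = "no feature tracks"
            continue

        def _overlap(cell=cell, cl=cl):
            tracks = [
                feat.load_feature_track(p, ft, cl) for ft, p in cell.tracks.items()
            ]
            matrix = feat.assign_membership(catalog, tracks, config.min_overlap_frac)
            matrices[cl] = matrix
            feat.write_membership_tsv(matrix, out_dir / f"membership.{cl}.tsv")
            for part in matrix.partitions:
                bundle.add_table(
                    f"proportions.{cl}.{part}",
                    feat.class_proportions(matrix, catalog, part).reset_index(),
                )
            results = []
            for part, cats_ in feat.PARTITIONS.items():
                for ft in cats_:
                    if ft not in matrix.memberships.columns:
                        continue
                    for cls in RARE:
                        if cls in catalog.class_counts():
                            results.append(
                                feat.enrichment_fisher(
                                    matrix, catalog, cls, ft,
                                    family_size=config.family_size,
                                )
                            )
            bundle.add_table(f"enrichment.{cl}", feat.enrichment_frame(results))

        _stage(f"overlap[{cl}]", _overlap)

        if cl in matrices and "minor" in catalog.class_counts():
            def _null(cl=cl):
                m = matrices[cl]
                n_minor = len(catalog.by_class("minor"))
                rows = []
                for ft in ("compartment_A", "SPAD", "LAD"):
                    if ft not in m.memberships.columns:
                        continue
                    boot = rs.bootstrap_null(
                        m, catalog, "major", ft, sample_size=n_minor,
                        n_boot=config.n_boot, seed=config.seed, focal_class="minor",
                    )
                    curve = rs.pollution_curve(
                        m, catalog, "major", "minor", ft,
                        fractions=config.fractions,
                        n_boot=max(50, config.n_boot // 10), seed=config.seed,
                    )
                    rows.append(
                        {"feature_type": ft, "bootstrap_median": boot.median,
                         "observed_minor": boot.observed_focal,
                         "percentile_of_observed": boot.percentile_of_observed,
                         "pollution_r": curve.r, "pollution_p": curve.p_r}
                    )
                bundle.add_table(f"resampling.{cl}", pd.DataFrame(rows))

            _stage(f"resampling[{cl}]", _null)

        expr = None
        if cell.tpm and Path(cell.tpm).exists():
            expr = _stage(
                f"expression[{cl}]",
                lambda cell=cell, cl=cl: gc.load_expression(cell.tpm, cell_line=cl),
            )
        elif cell.tpm:
            bundle.skipped[f"expression[{cl}]"] = f"missing {cell.tpm}"

        if expr is not None and cl in matrices:
            def _strat(cl=cl, expr=expr):
                rows = []
                for ft in ("compartment_A", "compartment_B", "SPAD", "LAD"):
                    if ft not in matrices[cl].memberships.columns:
                        continue
                    for cls in RARE:
                        rows.append(
                            gc.stratified_enrichment(
                                matrices[cl], catalog, expr, ft, cls,
                                threshold=config.tpm_thresholds[0],
                                family_size=config.family_size,
                            )
                        )
                bundle.add_table(f"expression_enrichment.{cl}", feat.enrichment_frame(rows))

            _stage(f"expression_enrichment[{cl}]", _strat)

        if essential is not None and cl in matrices:
            def _ess(cl=cl):
                rows = [
                    gc.essentiality_enrichment(
                        catalog, essential, cls, family_size=config.family_size
                    )
                    for cls in RARE
                ]
                rows += [
                    gc.within_class_essential_vs_all(
                        catalog, essential, matrices[cl], cls, "compartment_A",
                        family_size=config.family_size,
                    )
                    for cls in ("major", *RARE)
                    if "compartment_A" in matrices[cl].memberships.columns
                ]
                bundle.add_table(f"essentiality.{cl}", feat.enrichment_frame(rows))

            _stage(f"essentiality[{cl}]", _ess)

        if cell.alignments and gene_models is not None:
            missing = [a for a in cell.alignments if not Path(a).exists()]
            if missing:
                bundle.skipped[f"splicing[{cl}]"] = f"missing alignments: {missing}"
            else:
                def _splice(cell=cell, cl=cl, expr=expr):
                    per_rep = [
                        spl.extract_junction_evidence(
                            a, catalog, gene_models, cell_line=cl, replicate=str(i)
                        )
                        for i, a in enumerate(cell.alignments)
                    ]
                    pooled = spl.pool_evidence(per_rep)
                    table = spl.splicing_index_table(
                        pooled, catalog, expr=expr, matrix=matrices.get(cl), cell_line=cl
                    )
                    si_tables[cl] = table
                    bundle.add_table(f"splicing_index.{cl}", table)
                    filtered = spl.filter_for_analysis(
                        table, tpm_threshold=config.tpm_thresholds[0],
                        category_filter="both", subsample=config.subsample,
                        seed=config.seed,
                    )
                    comp = spl.compare_distributions(filtered, "intron_class", "si_ret")
                    if comp.pairwise is not None:
                        bundle.add_table(f"splicing_dunn.{cl}", comp.pairwise)

                _stage(f"splicing[{cl}]", _splice)
        elif cell.alignments:
            bundle.skipped[f"splicing[{cl}]"] = "no gene models"

    ref = config.reference_cell_line
    if ref and ref in si_tables and len(si_tables) > 1 and ref in matrices:
        def _crossline():
            sets = spl.matched_location_sets(
                {cl: matrices[cl] for cl in si_tables if cl in matrices},
                si_tables, ref, intron_class="minor",
            )
            rows = [
                {"cell_line": cl, "category": cat_, "n_shared": info["n_shared"],
                 "p": info["test"]["p"] if info["test"] else None}
                for (cl, cat_), info in sets["pairwise"].items()
            ]
            bundle.add_table("crossline_shared_sets", pd.DataFrame(rows))
            shared = {
                cl: sets["pairwise"][(cl, "neither")]["intron_ids"]
                for cl in si_tables if cl != ref and (cl, "neither") in sets["pairwise"]
            }
            improved = spl.improved_splicing_intersection(
                si_tables[ref], {cl: si_tables[cl] for cl in shared}, shared
            )
            export_gene_lists(bundle, improved)

        _stage("crossline", _crossline)

    bundle.write_manifest()
    return bundle


def export_gene_lists(bundle: ReportBundle, improved: Mapping[str, Any]) -> list[Path]:
    """Write deduplicated, sorted gene lists for external GO analysis."""
    out = bundle.out_dir / "gene_lists"
    out.mkdir(exist_ok=True)
    paths = []
    def _write(name: str, genes: Iterable[str]) -> None:
        p = out / f"{name}.txt"
        genes = sorted(set(genes))
        with open(p, "w") as fh:
            if not genes:
                fh.write("# empty set\n")
            for g in genes:
                fh.write(g + "\n")
        paths.append(p)
        bundle.manifest.setdefault("gene_lists", {})[name] = {
            "path": str(p), "n": len(genes)
        }
    for cl, genes in improved.get("genes_per_line", {}).items():
        _write(f"improved_in_{cl}", genes)
    _write("improved_intersection", improved.get("intersection_genes", set()))
    return paths
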