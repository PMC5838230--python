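"""End-to-end workflow: univariate screen, MMD screen, distance network,
optional PPI overlay, with a manifest of every parameter used.

The two oncogene conditions are independent runs over the same input table.
Each run is a pure function of (input data, config, seed): rerunning with
the same manifest reproduces every statistical output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .io import ScreenDataset, read_morphometry_table, validate_dataset, write_results_table
from .mmd import MMDScreen
from .network import (
    build_threshold_network,
    export_distance_matrix,
    export_network,
    pairwise_centered_distances,
    ward_cluster,
)
from .ppi import load_ppi_edges, map_constructs_to_genes, overlay_networks
from .preprocessing import scale_unit_variance
from .univariate import UnivariateScreen


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (one oncogene condition)."""

    input_path: str | None = None
    out_dir: str = "mmdscreen_out"
    condition: str = "none"
    clip_eps: float = 1e-6
    fdr_threshold: float = 0.05
    permutations: int = 10_000
    seed: int = 0
    mmd_edge_threshold: float = 0.1
    ppi_path: str | None = None
    ppi_min_confidence: float = 0.7
    gene_map_path: str | None = None

    def validate(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.mmd_edge_threshold <= 0:
            raise ValueError("mmd_edge_threshold must be positive")
        if not 0 <= self.ppi_min_confidence <= 1:
            raise ValueError("ppi_min_confidence must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for the permutation tests")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def concordance_report(univariate_hits: set, mmd_hits: set) -> dict:
    """Three-way concordance of the two hit-calling routes.

    A population is a univariate hit if significant in either trait; counts
    mirror a Venn diagram of the two hit lists.
    """
    both = univariate_hits & mmd_hits
    return {
        "both": sorted(map(list, both)),
        "univariate_only": sorted(map(list, univariate_hits - both)),
        "mmd_only": sorted(map(list, mmd_hits - both)),
        "counts": {
            "both": len(both),
            "univariate_only": len(univariate_hits - both),
            "mmd_only": len(mmd_hits - both),
        },
    }


def _read_gene_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"construct", "gene"} <= set(df.columns):
        raise ValueError("gene map needs columns 'construct' and 'gene'")
    return dict(zip(df["construct"].astype(str), df["gene"].astype(str)))


def run_pipeline(
    cfg: RunConfig,
    dataset: ScreenDataset | None = None,
    gene_map: Mapping[str, str] | None = None,
) -> dict:
    """Execute the full workflow for one condition; returns the manifest.

    Stages: validate -> preprocess -> univariate screen (normality, Wilcoxon,
    BH-FDR, hit categories) -> MMD permutation screen -> control-centered
    distances among MMD-significant populations -> Ward clustering ->
    threshold network -> exports -> optional gene mapping + PPI overlay.
    Any stage error aborts with the stage name; a partial manifest is still
    written.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "stages": {},
        "outputs": {},
    }
    stage = "load"

    def tick(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}

    try:
        t0 = time.perf_counter()
        if dataset is None:
            if cfg.input_path is None:
                raise ValueError("either a dataset or cfg.input_path is required")
            dataset = read_morphometry_table(cfg.input_path)
        tick("load", t0, records=len(dataset.records))

        stage = "validate"
        t0 = time.perf_counter()
        report = validate_dataset(dataset)
        report.to_json(out / "validation.json")
        if not report.ok:
            raise ValueError(f"dataset failed validation with {len(report.errors)} error(s)")
        tick("validate", t0, **report.counts)

        stage = "preprocess"
        t0 = time.perf_counter()
        fm = scale_unit_variance(dataset, cfg.condition, eps=cfg.clip_eps)
        tick("preprocess", t0, structures=len(fm.frame),
             feature_sd=fm.feature_sd)

        stage = "univariate"
        t0 = time.perf_counter()
        uni = UnivariateScreen(
            condition=cfg.condition, fdr_threshold=cfg.fdr_threshold
        ).fit(dataset)
        write_results_table(uni.normality_, out / "normality.tsv")
        write_results_table(uni.results_, out / "univariate_results.tsv")
        write_results_table(uni.hits_, out / "univariate_hits.tsv")
        tick("univariate", t0, tests=len(uni.results_),
             family_size=int(len(uni.results_) / 2) if len(uni.results_) else 0,
             hits=len(uni.hit_populations()))

        stage = "mmd_screen"
        t0 = time.perf_counter()
        screen = MMDScreen(
            permutations=cfg.permutations,
            seed=cfg.seed,
            fdr_threshold=cfg.fdr_threshold,
        ).fit(fm)
        write_results_table(screen.results_, out / "mmd_results.tsv")
        significant = screen.significant_populations()
        tick("mmd_screen", t0, tests=len(screen.tests_),
             bandwidth=screen.bandwidth_, significant=len(significant))
        manifest["bandwidth"] = screen.bandwidth_

        stage = "distance_network"
        t0 = time.perf_counter()
        if len(significant) >= 2:
            dm = pairwise_centered_distances(fm, significant, screen.bandwidth_)
            cluster = ward_cluster(dm)
            export_distance_matrix(dm, out / "distance_matrix.tsv", cluster)
            (out / "dendrogram.newick").write_text(cluster.to_newick() + "\n")
            net = build_threshold_network(dm, cfg.mmd_edge_threshold)
            export_network(net, out, stem="phenotype_network")
            tick("distance_network", t0, populations=len(dm.labels),
                 edges=net.graph.number_of_edges())
        else:
            net = None
            tick("distance_network", t0, populations=len(significant), skipped=True)

        stage = "concordance"
        t0 = time.perf_counter()
        concordance = concordance_report(uni.hit_populations(), screen.hit_populations())
        (out / "concordance.json").write_text(json.dumps(concordance, indent=2) + "\n")
        tick("concordance", t0, **concordance["counts"])

        if net is not None and (gene_map is not None or cfg.gene_map_path):
            stage = "gene_mapping"
            t0 = time.perf_counter()
            mapping = dict(gene_map) if gene_map is not None else _read_gene_map(cfg.gene_map_path)
            gene_net = map_constructs_to_genes(net, mapping)
            export_network(gene_net, out, stem="gene_network")
            tick("gene_mapping", t0, genes=gene_net.graph.number_of_nodes())

            if cfg.ppi_path:
                stage = "ppi_overlay"
                t0 = time.perf_counter()
                ppi = load_ppi_edges(cfg.ppi_path, cfg.ppi_min_confidence)
                overlay = overlay_networks(gene_net, ppi)
                frame = overlay.to_frame()
                if not frame.empty:
                    write_results_table(frame, out / "overlay.tsv")
                tick("ppi_overlay", t0, ppi_edges=ppi.n_edges,
                     both=len(overlay.both),
                     phenotype_only=len(overlay.phenotype_only),
                     ppi_only=len(overlay.ppi_only))
        manifest["ok"] = True
    except Exception as exc:
        manifest["ok"] = False
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise PipelineError(stage, exc) from exc

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
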