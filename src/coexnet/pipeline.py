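"""End-to-end orchestration: correlate → network → centrality → levels →
scale-free scan → layout, with every artifact written as TSV/GraphML and
a manifest tying them together.

All randomness flows from ``PipelineConfig.rng_seed`` and every table is
written with fixed formatting, so a rerun with the same config and seed
produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .centrality import MEASURES, centrality_report
from .correlation import (
    DEFAULT_MIN_OBS,
    correlate_frame,
    seed_network,
    top_correlates,
)
from .data_io import (
    align_strains,
    read_expression_matrix,
    read_phenotype_table,
    write_network,
)
from .errors import CoexnetError, ConfigError
from .graph import (
    bfs_levels,
    degrees_of_separation,
    level_table,
    mean_shortest_path,
)
from .layout import color_by_level, force_layout, grid_layout
from .scalefree import scan_frame, threshold_scan

log = logging.getLogger(__name__)

DEFAULT_SCAN_TAUS = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; defaults match the headline
    setting (signed correlations thresholded at r >= 0.6)."""

    expression_path: str
    phenotype_path: str
    seed_traits: list[str]
    out_dir: str
    tau: float = 0.6
    mode: str = "signed"
    min_obs: int = DEFAULT_MIN_OBS
    scan_taus: tuple[float, ...] = DEFAULT_SCAN_TAUS
    measures: tuple[str, ...] = MEASURES
    top_k: int = 20
    layout_iterations: int = 300
    layout_moves: int = 10000
    rng_seed: int = 0
    run_scan: bool = True
    run_layout: bool = True

    def validate(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ConfigError(f"tau must lie in (0, 1), got {self.tau}")
        if self.mode not in ("signed", "absolute"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not self.seed_traits:
            raise ConfigError("at least one seed trait is required")


def _write_frame(frame, path: Path) -> int:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="Inf")
    return len(frame)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk).

    Any stage failure is re-raised wrapped with the stage name so a long
    run fails loudly and diagnosably.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "version": __version__,
        "rng_seed": config.rng_seed,
        "artifacts": {},
    }
    counts = manifest["artifacts"]
    stage = "load"
    try:
        t0 = time.perf_counter()
        expr = read_expression_matrix(config.expression_path)
        pheno = read_phenotype_table(config.phenotype_path)
        data = align_strains(expr, pheno)
        for seed in config.seed_traits:
            if seed not in data.trait_ids:
                raise ConfigError(f"seed trait {seed!r} not in phenotype table")
        log.info("load: %d transcripts, %d traits, %d shared strains (%.2fs)",
                 len(data.transcript_ids), len(data.trait_ids),
                 len(data.shared_strain_ids), time.perf_counter() - t0)

        stage = "correlate"
        t0 = time.perf_counter()
        net, corr = seed_network(
            data, config.seed_traits, config.tau, config.mode, config.min_obs
        )
        for seed in config.seed_traits:
            table = top_correlates(corr, seed, k=None)
            table.rows = [
                (node, r) for node, r in table.rows
                if (abs(r) if config.mode == "absolute" else r) >= config.tau
            ]
            path = out / f"correlates_{seed}.tsv"
            counts[path.name] = _write_frame(correlate_frame(table), path)
        log.info("correlate: network %d nodes / %d edges (%.2fs)",
                 net.n_nodes, net.n_edges, time.perf_counter() - t0)

        stage = "network"
        write_network(net, out / "network_edges.tsv", "edge_list_tsv")
        write_network(net, out / "network.graphml", "graphml")
        counts["network_edges.tsv"] = net.n_edges
        counts["network.graphml"] = net.n_nodes

        stage = "centrality"
        t0 = time.perf_counter()
        reports = centrality_report(
            net, config.measures, top_k=config.top_k, node_filter="transcript"
        )
        for measure, report in reports.items():
            path = out / f"centrality_{measure}.tsv"
            with open(path, "w") as handle:
                handle.write("rank\tnode_id\tscore\n")
                for rank, (node, score) in enumerate(report.ranking, start=1):
                    handle.write(f"{rank}\t{node}\t{score:.6g}\n")
            counts[path.name] = len(report.ranking)
        log.info("centrality: %d measures (%.2fs)",
                 len(reports), time.perf_counter() - t0)

        stage = "levels"
        t0 = time.perf_counter()
        tables = {seed: level_table(net, seed) for seed in config.seed_traits}
        max_k = max((t.rows[-1][0] for t in tables.values() if t.rows), default=0)
        with open(out / "levels.tsv", "w") as handle:
            handle.write("Level\t" + "\t".join(config.seed_traits) + "\n")
            for k in range(1, max_k + 1):
                row = [str(k)]
                for seed in config.seed_traits:
                    rows = tables[seed].rows
                    row.append(str(rows[min(k, len(rows)) - 1][1]) if rows else "0")
                handle.write("\t".join(row) + "\n")
        counts["levels.tsv"] = max_k

        stage = "paths"
        mean_path = mean_shortest_path(net, scope="reachable_pairs")
        separation = degrees_of_separation(mean_path)
        with open(out / "path_summary.tsv", "w") as handle:
            handle.write(
                "n_nodes\tn_edges\tmean_shortest_path\tmean_degrees_of_separation\n"
            )
            handle.write(
                f"{net.n_nodes}\t{net.n_edges}\t{mean_path:.6g}\t{separation:.6g}\n"
            )
        counts["path_summary.tsv"] = 1
        log.info("paths: mean shortest path %.3f (= %.3f degrees of separation; %.2fs)",
                 mean_path, separation, time.perf_counter() - t0)

        if config.run_scan:
            stage = "scalefree"
            t0 = time.perf_counter()
            rows = threshold_scan(corr, config.scan_taus, config.mode)
            counts["threshold_scan.tsv"] = _write_frame(
                scan_frame(rows), out / "threshold_scan.tsv"
            )
            log.info("scalefree: scanned %d thresholds (%.2fs)",
                     len(rows), time.perf_counter() - t0)

        if config.run_layout:
            stage = "layout"
            t0 = time.perf_counter()
            levels = bfs_levels(net, config.seed_traits[0])
            flay = force_layout(
                net, iterations=config.layout_iterations, rng_seed=config.rng_seed
            )
            counts["layout_force.tsv"] = _write_frame(
                color_by_level(flay, levels), out / "layout_force.tsv"
            )
            glay = grid_layout(net, rng_seed=config.rng_seed,
                               moves=config.layout_moves)
            counts["layout_grid.tsv"] = _write_frame(
                color_by_level(glay, levels), out / "layout_grid.tsv"
            )
            log.info("layout: force + grid done (%.2fs)", time.perf_counter() - t0)

        stage = "manifest"
        with open(out / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")
    except CoexnetError as err:
        raise CoexnetError(f"pipeline stage {stage!r} failed: {err}") from err
    return manifest
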