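"""End-to-end orchestration: regions -> outlier cleaning -> stability scan
-> resolution scan -> label projection."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .config import RunConfig
from .graph_stability import StabilityResult, stability_scan
from .io_preprocess import ClusteringResult, EmbeddingMatrix
from .partition import RegionPartition, divide_regions, update_centroids
from .resolution_select import ResolutionScan, finalize_labels, resolution_scan_at_k

logger = logging.getLogger(__name__)


@dataclass
class RunArtifacts:
    """Everything a run produced, for diagnostics and evaluation."""

    result: ClusteringResult
    partition: RegionPartition
    stability: StabilityResult
    scan: ResolutionScan
    timings: dict[str, float] = field(default_factory=dict)


def run(M: EmbeddingMatrix, config: RunConfig | None = None) -> RunArtifacts:
    """Cluster an embedding with the full pipeline.

    Deterministic for a fixed config (the master seed drives region
    division, resampling and louvain).
    """
    config = config or RunConfig()
    if config.g > M.n_cells:
        raise ValueError(f"g={config.g} exceeds the number of cells {M.n_cells}")
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    partition = divide_regions(M, g=config.g, seed=config.seed)
    partition = update_centroids(M, partition, alpha=config.alpha)
    timings["partition"] = time.perf_counter() - t0
    logger.info("region division + cleaning: %.2fs", timings["partition"])

    t0 = time.perf_counter()
    stability = stability_scan(M, partition, config)
    timings["stability"] = time.perf_counter() - t0
    logger.info("stability scan: %.2fs, K*=%d", timings["stability"], stability.k_star)

    t0 = time.perf_counter()
    scan = resolution_scan_at_k(
        stability.samples,
        stability.k_star,
        list(config.resolution_grid),
        seed=config.seed,
    )
    result = finalize_labels(scan, partition, M.cell_ids, stability.k_star)
    timings["resolution"] = time.perf_counter() - t0
    logger.info(
        "resolution scan + projection: %.2fs, res*=%.3g, %d clusters",
        timings["resolution"], scan.res_star, result.n_clusters,
    )
    return RunArtifacts(
        result=result,
        partition=partition,
        stability=stability,
        scan=scan,
        timings=timings,
    )
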