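"""Run configuration shared by every stage of the pipeline.

The defaults are the framework's recommended operating point: ``g`` coarse
regions, a neighborhood-size search grid ``k_min..k_max``, ``L`` resampling
replicates clustered at resolution ``res_default``, and a resolution grid
swept at the final community-detection stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Resolution grid swept when selecting the final louvain resolution
#: (0.2 to 3.0 in steps of 0.4).
DEFAULT_RESOLUTION_GRID: tuple[float, ...] = tuple(
    round(0.2 + 0.4 * i, 10) for i in range(8)
)


@dataclass(frozen=True)
class RunConfig:
    """Parameters controlling a full clustering run.

    Parameters
    ----------
    g
        Number of coarse regions the cells are partitioned into (default 500).
    k_min, k_max
        Inclusive search range for the KNN neighborhood size K (default 3..50).
    res_default
        Louvain resolution used during the stability resampling stage
        (default 1.0).
    L
        Number of resampling replicates (default 50).
    alpha
        Significance level of the per-region chi-squared outlier test
        (default 0.01).
    resolution_grid
        Strictly increasing grid of louvain resolutions swept at the final
        stage (default 0.2:3.0:0.4).
    n_pcs
        Number of principal components kept when reducing an expression
        matrix (default 5).
    seed
        Master seed; every random stage derives its stream from it.
    """

    g: int = 500
    k_min: int = 3
    k_max: int = 50
    res_default: float = 1.0
    L: int = 50
    alpha: float = 0.01
    resolution_grid: tuple[float, ...] = field(default=DEFAULT_RESOLUTION_GRID)
    n_pcs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g < 2:
            raise ValueError(f"g must be >= 2, got {self.g}")
        if not (0 < self.k_min < self.k_max < self.g):
            raise ValueError(
                f"need 0 < k_min < k_max < g, got k_min={self.k_min}, "
                f"k_max={self.k_max}, g={self.g}"
            )
        if self.res_default <= 0:
            raise ValueError("res_default must be positive")
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        grid = tuple(float(r) for r in self.resolution_grid)
        if len(grid) == 0:
            raise ValueError("resolution_grid must be nonempty")
        if any(r <= 0 for r in grid):
            raise ValueError("resolutions must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("resolution_grid must be strictly increasing")
        object.__setattr__(self, "resolution_grid", grid)
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be positive")


def parse_resolution_spec(spec: str) -> tuple[float, ...]:
    """Parse a ``start:stop:step`` string (or comma list) into a grid."""
    spec = spec.strip()
    if ":" in spec:
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(f"expected start:stop:step, got {spec!r}")
        start, stop, step = (float(p) for p in parts)
        if step <= 0:
            raise ValueError("step must be positive")
        out = []
        r = start
        while r <= stop + 1e-9:
            out.append(round(r, 10))
            r += step
        return tuple(out)
    return tuple(float(p) for p in spec.split(","))
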