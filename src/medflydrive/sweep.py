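"""Parameter sweeps over drive-activity rates and extinction-surface smoothing.

A sweep runs the population simulator over a grid spanning any subset of the
three drive-activity axes (germline cleavage rate, R2 fraction of NHEJ
repairs, HDR rate) with a fixed number of replicates per grid point, and
records the extinction fraction and the mean time to extinction at each
point.  The noisy extinction response over a two-axis grid is then smoothed
with a LOESS-style local polynomial regression (tricube distance weights on
standardised axes, weighted least squares of configurable degree) to obtain a
continuous rate-of-extinction surface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from math import ceil, comb
from pathlib import Path
import numpy as np
import pandas as pd

from .population import SimConfig, run_simulation, summarize_replicates
from .genetics import DriveDesign

__all__ = [
    "SweepGrid",
    "run_sweep",
    "smooth_extinction_surface",
    "local_polynomial_smooth",
    "sweep_preset",
    "PRESETS",
    "write_sweep_tsv",
    "read_sweep_tsv",
]

SWEEPABLE = ("cleavage_rate", "r2_fraction", "hdr_rate")


@dataclass(frozen=True)
class SweepGrid:
    """Axis specification for a sweep.

    ``axes`` maps swept parameter names (a subset of ``cleavage_rate``,
    ``r2_fraction``, ``hdr_rate``) to their value lists; unswept rates come
    from ``base_config.params``.  Total simulations = product of axis lengths
    times ``replicates``.
    """

    axes: dict[str, tuple[float, ...]]
    replicates: int
    base_config: SimConfig

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("a sweep needs at least one axis")
        for name, values in self.axes.items():
            if name not in SWEEPABLE:
                raise ValueError(
                    f"cannot sweep {name!r}; sweepable axes are {SWEEPABLE}"
                )
            if len(values) == 0:
                raise ValueError(f"axis {name!r} has no values")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_points(self) -> int:
        out = 1
        for values in self.axes.values():
            out *= len(values)
        return out

    @property
    def n_simulations(self) -> int:
        return self.n_points * self.replicates


def run_sweep(
    grid: SweepGrid,
    design: DriveDesign | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Execute the full grid and summarise each point over its replicates.

    Every (grid point, replicate) pair runs on its own spawned substream of
    the master seed, so the result is bitwise reproducible and row order is
    deterministic (itertools.product over the axes in declaration order).
    ``design``/``seed`` override the base config when given.
    """
    base = grid.base_config
    if design is not None:
        base = replace(base, design=design)
    master = base.seed if seed is None else seed
    names = list(grid.axes)
    streams = iter(np.random.SeedSequence(master).spawn(grid.n_simulations))
    rows = []
    for values in itertools.product(*(grid.axes[n] for n in names)):
        point = dict(zip(names, values))
        try:
            params = replace(base.params, **point)
            cfg = replace(base, params=params)
        except ValueError as exc:
            raise ValueError(f"invalid parameters at grid point {point}: {exc}") from exc
        results = [
            run_simulation(cfg, rng=np.random.default_rng(next(streams)))
            for _ in range(grid.replicates)
        ]
        summary = summarize_replicates(results)
        row = {"design": cfg.design.name}
        row.update(
            {
                "cleavage_rate": cfg.params.cleavage_rate,
                "hdr_rate": cfg.params.hdr_rate,
                "r2_fraction": cfg.params.r2_fraction,
                "maternal_factor": cfg.params.maternal_factor,
            }
        )
        row["extinction_fraction"] = summary.extinction_fraction
        row["mean_time_to_extinction"] = (
            np.nan
            if summary.mean_time_to_extinction is None
            else summary.mean_time_to_extinction
        )
        row["n_replicates"] = summary.n_replicates
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["config"] = base.to_dict()
    df.attrs["axes"] = {k: list(v) for k, v in grid.axes.items()}
    df.attrs["seed"] = master
    return df


def _six(lo: float, hi: float) -> tuple[float, ...]:
    return tuple(np.round(np.linspace(lo, hi, 6), 6))


def sweep_preset(
    name: str, base_config: SimConfig, replicates: int = 10
) -> SweepGrid:
    """Named default sweeps (36 grid points x 10 replicates = 360 runs).

    ``extinction-surface``
        cleavage rate x R2 fraction at a fixed HDR rate of 0.95 over 20
        generations; the response of interest is the extinction fraction.
    ``duration-surface``
        cleavage rate x HDR rate at a fixed R2/R1 split of 0.99/0.01; the
        response of interest is the mean time to extinction.
    """
    if name == "extinction-surface":
        params = replace(base_config.params, hdr_rate=0.95)
        axes = {"cleavage_rate": _six(0.5, 1.0), "r2_fraction": _six(0.0, 1.0)}
    elif name == "duration-surface":
        params = replace(base_config.params, r2_fraction=0.99)
        axes = {"cleavage_rate": _six(0.5, 1.0), "hdr_rate": _six(0.5, 1.0)}
    else:
        raise ValueError(
            f"unknown preset {name!r}; expected 'extinction-surface' or 'duration-surface'"
        )
    return SweepGrid(
        axes=axes, replicates=replicates, base_config=replace(base_config, params=params)
    )


PRESETS = ("extinction-surface", "duration-surface")


# ---------------------------------------------------------------------------
# Local polynomial regression (2-D LOESS-style smoother)
# ---------------------------------------------------------------------------


def local_polynomial_smooth(
    points: np.ndarray,
    values: np.ndarray,
    eval_points: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Weighted local polynomial fit of scattered 2-D data.

    For each evaluation point the ``ceil(span * n)`` nearest data points (on
    axes standardised to unit scale) define the bandwidth; tricube weights
    ``(1 - (d/bw)^3)^3`` feed a weighted least-squares polynomial of total
    degree ``degree``, whose value at the evaluation point is returned.
    ``span > 1`` inflates the bandwidth by ``sqrt(span)`` beyond the maximum
    distance, so the fit tends to the global polynomial fit as the span
    grows.

    Raises ``ValueError`` when a window holds fewer positively weighted
    points than the polynomial has coefficients.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    eval_points = np.asarray(eval_points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if span <= 0:
        raise ValueError("span must be positive")
    if degree < 0:
        raise ValueError("degree must be non-negative")
    n = points.shape[0]
    n_terms = comb(degree + 2, 2)  # monomials x^i y^j with i + j <= degree
    if n < n_terms:
        raise ValueError(
            f"need at least {n_terms} data points for degree {degree}, got {n}"
        )

    scale = points.std(axis=0)
    scale[scale == 0] = 1.0
    pts = points / scale
    evals = eval_points / scale

    k = min(n, max(n_terms, ceil(min(span, 1.0) * n)))
    powers = [(i, j) for t in range(degree + 1) for i, j in zip(range(t, -1, -1), range(t + 1))]

    out = np.empty(eval_points.shape[0])
    for m, e in enumerate(evals):
        d = np.hypot(pts[:, 0] - e[0], pts[:, 1] - e[1])
        bw = np.partition(d, k - 1)[k - 1]
        if span > 1.0:
            bw = max(bw, d.max()) * np.sqrt(span)
        if bw <= 0:
            # evaluation point coincides with >= k data points
            out[m] = values[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / bw) ** 3, 0.0, None) ** 3
        active = w > 0
        if active.sum() < n_terms:
            raise ValueError(
                f"window at {tuple(eval_points[m])} holds {int(active.sum())} points; "
                f"degree {degree} needs {n_terms}"
            )
        dx = pts[active, 0] - e[0]
        dy = pts[active, 1] - e[1]
        X = np.column_stack([dx**i * dy**j for i, j in powers])
        sw = np.sqrt(w[active])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], values[active] * sw, rcond=None)
        out[m] = beta[0]  # intercept = fitted value at the evaluation point
    return out


def smooth_extinction_surface(
    result: pd.DataFrame,
    x: str,
    y: str,
    value: str = "extinction_fraction",
    span: float = 0.75,
    degree: int = 2,
    grid_size: int = 25,
    clamp: tuple[float, float] | None = (0.0, 1.0),
) -> pd.DataFrame:
    """Smooth a sweep response over its two swept axes onto a dense grid.

    Returns a tidy frame with columns ``x``, ``y`` and ``<value>_smooth``;
    fitted extinction rates are clamped to [0, 1] (disable with
    ``clamp=None``, e.g. for time-to-extinction surfaces).
    """
    for col in (x, y, value):
        if col not in result.columns:
            raise ValueError(f"sweep result has no column {col!r}")
    data = result.dropna(subset=[value])
    points = data[[x, y]].to_numpy(dtype=float)
    vals = data[value].to_numpy(dtype=float)
    gx = np.linspace(points[:, 0].min(), points[:, 0].max(), grid_size)
    gy = np.linspace(points[:, 1].min(), points[:, 1].max(), grid_size)
    mx, my = np.meshgrid(gx, gy, indexing="ij")
    evals = np.column_stack([mx.ravel(), my.ravel()])
    fitted = local_polynomial_smooth(points, vals, evals, span=span, degree=degree)
    if clamp is not None:
        fitted = np.clip(fitted, clamp[0], clamp[1])
    return pd.DataFrame({x: evals[:, 0], y: evals[:, 1], f"{value}_smooth": fitted})


# ---------------------------------------------------------------------------
# TSV round trip with provenance header
# ---------------------------------------------------------------------------


def write_sweep_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a sweep result as TSV, embedding its config in '#' header lines."""
    import json

    path = Path(path)
    lines = []
    for key in ("config", "axes", "seed"):
        if key in df.attrs:
            lines.append(f"# {key}: {json.dumps(df.attrs[key])}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
        df.to_csv(fh, sep="\t", index=False)


def read_sweep_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_sweep_tsv` (header comments restored)."""
    import json

    path = Path(path)
    attrs = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, payload = line[1:].strip().partition(":")
            attrs[key.strip()] = json.loads(payload)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    df.attrs.update(attrs)
    return df
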