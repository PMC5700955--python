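"""Synthetic data with the structure the hierarchy method assumes.

Two generators cover the two failure modes the method addresses:

* :func:`make_manifold3d` - two parallel curved sheets (half-cylinder arcs)
  in 3-D whose Euclidean gap is small compared to the within-sheet geodesic
  diameter.  Measurement noise pushes a few percent of points into the gap,
  so their Euclidean nearest neighbour lies on the *other* sheet while their
  geodesic neighbourhood never leaves their own sheet - exactly the
  "shortcut" conflict that AoI-overlap similarities must survive and plain
  Euclidean re-linking of landmarks must not.

* :func:`make_mixture` - labelled Gaussian mixtures in arcsinh marker space
  with one rare sub-population (default 0.5% of cells, mirroring the
  smallest disease-associated population highlighted in mass-cytometry
  practice).  Latent values are pushed through ``sinh(x) * 5`` so the raw
  output behaves like ion counts and the standard arcsinh cofactor-5
  transform recovers the latent scale exactly.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io import ExpressionMatrix, write_table

__all__ = ["SyntheticSpec", "ManifoldData", "MixtureData", "make_manifold3d", "make_mixture", "write_fixture"]


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic data set (used by the CLI)."""

    kind: str = "mixture"  # "manifold3d" or "mixture"
    n_cells: int = 100_000
    n_markers: int = 12
    n_components: int = 6
    rare_fraction: float = 0.005
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("manifold3d", "mixture"):
            raise ValueError(f"unknown synthetic kind {self.kind!r}")
        if self.n_cells < 100:
            raise ValueError("n_cells must be >= 100")
        if not 0 < self.rare_fraction < 0.5:
            raise ValueError("rare_fraction must be in (0, 0.5)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


class ManifoldData(NamedTuple):
    matrix: ExpressionMatrix
    labels: np.ndarray  # sheet id per cell (0 or 1)
    arc_coords: np.ndarray  # (n, 2) noise-free intrinsic coordinates (arc length, height)


class MixtureData(NamedTuple):
    matrix: ExpressionMatrix  # raw (untransformed) counts
    labels: np.ndarray  # component id per cell
    means: np.ndarray  # (n_components, n_markers) latent component means
    fractions: np.ndarray


def make_manifold3d(
    n_cells: int = 10_000,
    noise_sd: float = 0.015,
    gap: float = 0.2,
    radius: float = 1.0,
    height: float = 3.0,
    seed: int = 0,
) -> ManifoldData:
    """Sample two concentric half-cylinder sheets separated by ``gap``.

    Sheet 0 is the arc of radius ``radius``, sheet 1 the arc of radius
    ``radius + gap``; both span a half turn and ``height`` along the axis,
    and isotropic Gaussian noise of scale ``noise_sd`` is added in 3-D.  The
    gap stays far below the within-sheet geodesic diameter, so the two sheets
    are close in Euclidean space but far along the manifold.  ``arc_coords``
    are the intrinsic noise-free coordinates ``(r * theta, z)`` for geodesic
    oracles (the sheets are analytic, so within-sheet geodesics are flat
    distances in these coordinates).
    """
    if n_cells < 100:
        raise ValueError("n_cells must be >= 100")
    diam = float(np.hypot(np.pi * radius, height))
    if gap >= 0.2 * diam:
        raise ValueError(f"gap {gap} must stay below 20% of the geodesic diameter ({diam:.3g})")
    if noise_sd > 0.5 * gap:
        warnings.warn(
            f"noise_sd {noise_sd} exceeds half the sheet gap {gap}; the sheets will blur together",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    labels = (np.arange(n_cells) % 2).astype(np.int64)  # balanced sheets
    radii = np.where(labels == 0, radius, radius + gap)
    theta = rng.uniform(0.0, np.pi, size=n_cells)
    z = rng.uniform(0.0, height, size=n_cells)
    pts = np.stack([radii * np.cos(theta), radii * np.sin(theta), z], axis=1)
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    m = ExpressionMatrix(
        values=pts,
        cell_ids=[f"manifold:{i}" for i in range(n_cells)],
        marker_names=["dim1", "dim2", "dim3"],
        transformed=True,  # geometric coordinates, not ion counts
    )
    arc = np.stack([radii * theta, z], axis=1)
    return ManifoldData(matrix=m, labels=labels, arc_coords=arc)


def _component_means(n_components: int, n_markers: int, min_dist: float, rng: np.random.Generator) -> np.ndarray:
    """Distinct hi/lo marker patterns, pairwise at least ``min_dist`` apart."""
    lo, hi = 0.5, 2.5
    if (hi - lo) < min_dist and n_markers * (hi - lo) ** 2 < min_dist**2:
        raise ValueError(f"cannot separate {n_components} components by {min_dist} in {n_markers} markers")
    seen: set[tuple[int, ...]] = set()
    patterns = []
    attempts = 0
    while len(patterns) < n_components:
        attempts += 1
        if attempts > 1000 * n_components:
            raise ValueError(f"cannot place {n_components} components {min_dist} apart in {n_markers} markers")
        code = tuple(rng.integers(0, 2, size=n_markers).tolist())
        if code in seen:
            continue
        mean = lo + (hi - lo) * np.asarray(code, dtype=float)
        if patterns and np.sqrt(((np.asarray(patterns) - mean) ** 2).sum(axis=1)).min() < min_dist:
            continue
        seen.add(code)
        patterns.append(mean)
    return np.asarray(patterns)


def make_mixture(
    n_cells: int = 100_000,
    n_markers: int = 12,
    n_components: int = 6,
    rare_fraction: float = 0.005,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> MixtureData:
    """Sample a labelled Gaussian mixture with one rare component.

    Component means are distinct hi/lo marker patterns at pairwise latent
    distance >= 6 * ``noise_sd``; the last component carries
    ``rare_fraction`` of the cells and the remainder is split evenly.  The
    returned matrix holds raw counts ``sinh(latent) * 5`` (untransformed), so
    the arcsinh cofactor-5 transform recovers the latent mixture.
    """
    spec = SyntheticSpec(
        kind="mixture",
        n_cells=n_cells,
        n_markers=n_markers,
        n_components=n_components,
        rare_fraction=rare_fraction,
        noise_sd=noise_sd,
        seed=seed,
    )
    rng = np.random.default_rng(spec.seed)
    means = _component_means(n_components, n_markers, 6.0 * noise_sd, rng)
    fractions = np.full(n_components, (1.0 - rare_fraction) / (n_components - 1))
    fractions[-1] = rare_fraction
    labels = rng.choice(n_components, size=n_cells, p=fractions)
    latent = means[labels] + rng.normal(scale=noise_sd, size=(n_cells, n_markers))
    raw = np.sinh(latent) * 5.0
    m = ExpressionMatrix(
        values=raw,
        cell_ids=[f"mix:{i}" for i in range(n_cells)],
        marker_names=[f"M{j + 1:02d}" for j in range(n_markers)],
        transformed=False,
    )
    return MixtureData(matrix=m, labels=labels, means=means, fractions=fractions)


def write_fixture(m: ExpressionMatrix, path: str, format: str = "csv") -> None:
    """Write an expression matrix as a CSV/TSV fixture or a minimal FCS 3.1 file."""
    import pandas as pd

    format = format.lower()
    if format in ("csv", "tsv"):
        df = pd.DataFrame(m.values, columns=m.marker_names)
        write_table(df, path, sep="," if format == "csv" else "\t")
    elif format == "fcs":
        from .fcs import write_fcs

        write_fcs(path, m.values, m.marker_names)
    else:
        raise ValueError(f"unknown fixture format {format!r}")
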