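"""Residence-level traffic exposure metrics.

Three metrics are assigned to each residence from a link-based road network
(polylines carrying annual-average-daily-traffic, AADT, counts):

* ``vkt_250`` / ``vkt_500`` — vehicle-kilometres travelled per day within a
  Euclidean buffer of the residence: the length of each road segment falling
  inside the disc (in km) times the segment's AADT, summed over segments.
* ``density`` — a line-source Gaussian kernel density surface (daily traffic
  count per square metre) rasterised at 50 m resolution and sampled at the
  residence.  Each segment is discretised into point masses of weight
  AADT x sub-length; each mass spreads over nearby cells by an isotropic
  bivariate Gaussian truncated at a cutoff radius and renormalised to unit
  planar integral inside the truncation disc.

All coordinates are planar projected metres.  The disc-chord lengths are
computed analytically per linear piece via the circle-line quadratic, not by
polygonal approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("traffex")

__all__ = [
    "RoadSegment",
    "KernelSpec",
    "RasterSpec",
    "DensityRaster",
    "TrafficMetrics",
    "CoverageError",
    "OutOfExtentError",
    "segment_length_in_disc",
    "vkt_in_buffer",
    "raster_spec_covering",
    "kernel_density_raster",
    "density_at",
    "assign_exposures",
]


class CoverageError(ValueError):
    """Raster extent does not cover the network plus kernel cutoff."""


class OutOfExtentError(ValueError):
    """A sample point lies outside the raster extent."""


@dataclass(frozen=True)
class RoadSegment:
    """A road polyline with a daily traffic count.

    Parameters
    ----------
    id : str
        Segment identifier.
    vertices : (n, 2) array of float
        Ordered planar coordinates in metres; at least two vertices.
    aadt : float
        Annual-average daily traffic (vehicles/day), non-negative.
    """

    id: str
    vertices: np.ndarray
    aadt: float

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
            raise ValueError(f"segment {self.id}: vertices must be (n>=2, 2)")
        object.__setattr__(self, "vertices", v)
        if not np.isfinite(self.aadt) or self.aadt < 0:
            raise ValueError(f"segment {self.id}: aadt must be >= 0, got {self.aadt}")
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: polyline length must be > 0")

    @property
    def length(self) -> float:
        """Total polyline length in metres."""
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class KernelSpec:
    """Isotropic Gaussian line-source kernel, truncated and renormalised.

    sigma : bandwidth in metres (default 100).
    cutoff : truncation radius in metres (default 300 = 3 sigma; beyond it a
        road's influence is treated as insignificant).
    discretization_step : spacing of the point masses along each segment
        (default 10 m; the remainder of a piece is carried by the final mass).
    """

    sigma: float = 100.0
    cutoff: float = 300.0
    discretization_step: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.cutoff <= 0 or self.discretization_step <= 0:
            raise ValueError("kernel parameters must be positive")
        if self.cutoff < self.sigma:
            raise ValueError("cutoff must be >= sigma")

    @property
    def norm(self) -> float:
        """Kernel value scale: unit planar integral inside the cutoff disc."""
        trunc_mass = 1.0 - math.exp(-self.cutoff**2 / (2.0 * self.sigma**2))
        return 1.0 / (2.0 * math.pi * self.sigma**2 * trunc_mass)

    def weight(self, r: np.ndarray) -> np.ndarray:
        """Kernel weight (1/m^2) at radial distance ``r`` metres; 0 beyond cutoff."""
        r = np.asarray(r, dtype=float)
        w = self.norm * np.exp(-(r**2) / (2.0 * self.sigma**2))
        return np.where(r <= self.cutoff, w, 0.0)


@dataclass(frozen=True)
class RasterSpec:
    """Geometry of a north-up grid: lower-left corner, cell size, shape."""

    origin: tuple[float, float]
    cell_size: float = 50.0
    n_rows: int = 0
    n_cols: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("raster must have at least one cell")

    @property
    def x_max(self) -> float:
        return self.origin[0] + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.origin[1] + self.n_rows * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x of column centres, y of row centres); row 0 is the southernmost."""
        xs = self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys


@dataclass
class DensityRaster:
    """Traffic density surface (daily traffic count per m^2) on a grid.

    ``values[r, c]`` is the density of the cell in row r (counting north from
    the lower-left origin) and column c.
    """

    spec: RasterSpec
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values is None:
            self.values = np.zeros((self.spec.n_rows, self.spec.n_cols))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("values shape does not match raster spec")


@dataclass(frozen=True)
class TrafficMetrics:
    """The exposure triple assigned to one residence."""

    person_id: str
    vkt_250: float
    vkt_500: float
    density: float

    def __post_init__(self) -> None:
        if self.vkt_250 > self.vkt_500 + 1e-9:
            raise ValueError("vkt_250 cannot exceed vkt_500 (nested buffers)")
        if min(self.vkt_250, self.vkt_500, self.density) < 0:
            raise ValueError("traffic metrics must be non-negative")


# ---------------------------------------------------------------------------
# Disc-chord geometry
# ---------------------------------------------------------------------------

def _piece_lengths_in_disc(
    a: np.ndarray, b: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    """Length inside the closed disc for each straight piece a[i] -> b[i].

    Solves |a + t(b-a) - c|^2 = r^2 per piece and clips the inside interval
    to t in [0, 1]; exact up to floating point.
    """
    d = b - a
    L2 = np.einsum("ij,ij->i", d, d)
    lengths = np.zeros(len(a))
    ok = L2 > 0
    if not np.all(ok):
        logger.debug("skipping %d zero-length pieces", int((~ok).sum()))
    f = a - center
    # t^2 L2 + 2 t (f.d) + (|f|^2 - r^2) = 0
    bq = np.einsum("ij,ij->i", f, d)
    cq = np.einsum("ij,ij->i", f, f) - radius**2
    disc = bq**2 - L2 * cq
    hit = ok & (disc > 0)
    if np.any(hit):
        sq = np.sqrt(disc[hit])
        t1 = (-bq[hit] - sq) / L2[hit]
        t2 = (-bq[hit] + sq) / L2[hit]
        lo = np.clip(t1, 0.0, 1.0)
        hi = np.clip(t2, 0.0, 1.0)
        lengths[hit] = (hi - lo) * np.sqrt(L2[hit])
    return lengths


def segment_length_in_disc(
    segment: RoadSegment, center: tuple[float, float], radius: float
) -> float:
    """Exact length (m) of ``segment`` lying within the closed disc.

    Each linear piece is intersected analytically with the circle via the
    circle-line quadratic; zero-length pieces are skipped.  Returns 0.0 when
    the polyline and disc are disjoint.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    v = segment.vertices
    c = np.asarray(center, dtype=float)
    return float(_piece_lengths_in_disc(v[:-1], v[1:], c, radius).sum())


def vkt_in_buffer(
    network: list[RoadSegment], center: tuple[float, float], radius: float
) -> float:
    """Vehicle-kilometres travelled per day within ``radius`` m of ``center``.

    Sum over segments of (length inside the disc, km) x AADT.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not network:
        logger.warning("vkt_in_buffer called with empty network; returning 0")
        return 0.0
    total = 0.0
    c = np.asarray(center, dtype=float)
    for seg in network:
        v = seg.vertices
        inside = _piece_lengths_in_disc(v[:-1], v[1:], c, radius).sum()
        total += (inside / 1000.0) * seg.aadt
    return float(total)


# ---------------------------------------------------------------------------
# Kernel density raster
# ---------------------------------------------------------------------------

def _network_bounds(network: list[RoadSegment]) -> tuple[float, float, float, float]:
    allv = np.vstack([s.vertices for s in network])
    return (
        float(allv[:, 0].min()),
        float(allv[:, 1].min()),
        float(allv[:, 0].max()),
        float(allv[:, 1].max()),
    )


def raster_spec_covering(
    network: list[RoadSegment],
    kernel: KernelSpec,
    cell_size: float = 50.0,
    extra_points: np.ndarray | None = None,
) -> RasterSpec:
    """A raster spec covering the network (and any extra points) padded by the
    kernel cutoff, aligned to multiples of the cell size."""
    x0, y0, x1, y1 = _network_bounds(network)
    if extra_points is not None and len(extra_points):
        p = np.asarray(extra_points, dtype=float)
        x0, y0 = min(x0, p[:, 0].min()), min(y0, p[:, 1].min())
        x1, y1 = max(x1, p[:, 0].max()), max(y1, p[:, 1].max())
    pad = kernel.cutoff + cell_size
    ox = math.floor((x0 - pad) / cell_size) * cell_size
    oy = math.floor((y0 - pad) / cell_size) * cell_size
    n_cols = int(math.ceil((x1 + pad - ox) / cell_size))
    n_rows = int(math.ceil((y1 + pad - oy) / cell_size))
    return RasterSpec(origin=(ox, oy), cell_size=cell_size, n_rows=n_rows, n_cols=n_cols)


def _segment_point_masses(seg: RoadSegment, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Discretise a polyline into (positions, weights).

    Positions are the midpoints of sub-intervals of arc length <= step along
    each linear piece; the remainder of a piece is carried by its final
    (shorter) sub-interval.  Weights are AADT x sub-length, i.e.
    vehicle-metres/day.
    """
    pts: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    v = seg.vertices
    for a, b in zip(v[:-1], v[1:]):
        piece = b - a
        L = float(np.hypot(*piece))
        if L == 0:
            continue
        n_full = int(L // step)
        bounds = np.arange(n_full + 1) * step
        bounds = np.append(bounds, L) if L - n_full * step > 1e-12 else bounds
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        sub = np.diff(bounds)
        pts.append(a + np.outer(mids / L, piece))
        wts.append(seg.aadt * sub)
    if not pts:
        return np.empty((0, 2)), np.empty(0)
    return np.vstack(pts), np.concatenate(wts)


def kernel_density_raster(
    network: list[RoadSegment],
    raster_spec: RasterSpec,
    kernel: KernelSpec | None = None,
) -> DensityRaster:
    """Rasterise the network's traffic as a truncated-Gaussian kernel density.

    Every segment is broken into point masses of weight AADT x sub-length
    (vehicle-metres/day); each mass contributes weight x kernel(distance) to
    every cell centre within the cutoff.  Cell values are daily traffic counts
    per square metre (1 m reference length).

    Raises
    ------
    CoverageError
        If the raster does not cover the network bounding box padded by the
        cutoff; the message lists the clipped segments.
    """
    kernel = kernel or KernelSpec()
    if kernel.discretization_step > raster_spec.cell_size:
        raise ValueError("discretization_step must be <= cell_size")
    clipped = []
    for seg in network:
        v = seg.vertices
        if (
            v[:, 0].min() - kernel.cutoff < raster_spec.origin[0]
            or v[:, 1].min() - kernel.cutoff < raster_spec.origin[1]
            or v[:, 0].max() + kernel.cutoff > raster_spec.x_max
            or v[:, 1].max() + kernel.cutoff > raster_spec.y_max
        ):
            clipped.append(seg.id)
    if clipped:
        raise CoverageError(
            "raster does not cover network padded by cutoff; clipped segments: "
            + ", ".join(clipped)
        )

    values = np.zeros((raster_spec.n_rows, raster_spec.n_cols))
    xs, ys = raster_spec.cell_centers()
    cs = raster_spec.cell_size
    ox, oy = raster_spec.origin
    halo = int(math.ceil(kernel.cutoff / cs)) + 1
    for seg in network:
        if seg.aadt == 0:
            continue
        pos, w = _segment_point_masses(seg, kernel.discretization_step)
        # local cell window per mass keeps the accumulation O(masses * halo^2)
        ci = ((pos[:, 0] - ox) / cs).astype(int)
        ri = ((pos[:, 1] - oy) / cs).astype(int)
        for k in range(len(w)):
            r0, r1 = max(ri[k] - halo, 0), min(ri[k] + halo + 1, raster_spec.n_rows)
            c0, c1 = max(ci[k] - halo, 0), min(ci[k] + halo + 1, raster_spec.n_cols)
            dx = xs[c0:c1] - pos[k, 0]
            dy = ys[r0:r1] - pos[k, 1]
            rr = np.hypot(dx[None, :], dy[:, None])
            values[r0:r1, c0:c1] += w[k] * kernel.weight(rr)
    return DensityRaster(spec=raster_spec, values=values)


def density_at(raster: DensityRaster, point: tuple[float, float]) -> float:
    """Density of the cell containing ``point`` (nearest-cell, no interpolation).

    A point exactly on a shared cell edge belongs to the cell with the lower
    row/column index; points on the outer boundary count as inside.
    """
    spec = raster.spec
    x, y = float(point[0]), float(point[1])
    tx = (x - spec.origin[0]) / spec.cell_size
    ty = (y - spec.origin[1]) / spec.cell_size
    if tx < 0 or ty < 0 or tx > spec.n_cols or ty > spec.n_rows:
        raise OutOfExtentError(f"point ({x}, {y}) outside raster extent")
    # edge tie rule: boundary coordinates resolve to the lower-index cell
    col = max(math.ceil(tx) - 1, 0)
    row = max(math.ceil(ty) - 1, 0)
    return float(raster.values[row, col])


# ---------------------------------------------------------------------------
# Linking exposures to residences
# ---------------------------------------------------------------------------

def assign_exposures(
    persons: pd.DataFrame,
    network: list[RoadSegment],
    kernel: KernelSpec | None = None,
    radii: tuple[float, float] = (250.0, 500.0),
    cell_size: float = 50.0,
    raster: DensityRaster | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign the (vkt_250, vkt_500, density) triple to every residence.

    Parameters
    ----------
    persons : DataFrame with columns ``person_id``, ``x_m``, ``y_m``.
    network : road segments.
    kernel : kernel spec for the density surface (default KernelSpec()).
    radii : inner and outer buffer radii in metres, inner < outer.
    raster : optionally a precomputed density surface covering all residences.

    Returns
    -------
    (metrics, rejects) : metrics has one row per person with finite
    coordinates (columns person_id, vkt_250, vkt_500, density, with
    vkt_250 <= vkt_500 by construction); rejects lists excluded persons with a
    reason.
    """
    kernel = kernel or KernelSpec()
    r_in, r_out = sorted(float(r) for r in radii)
    coords_ok = np.isfinite(persons["x_m"].to_numpy(float)) & np.isfinite(
        persons["y_m"].to_numpy(float)
    )
    rejects = persons.loc[~coords_ok, ["person_id"]].copy()
    rejects["reason"] = "missing or non-finite coordinates"
    for pid in rejects["person_id"]:
        logger.warning("person %s excluded from exposure assignment", pid)
    kept = persons.loc[coords_ok]
    pts = kept[["x_m", "y_m"]].to_numpy(float)
    if raster is None:
        spec = raster_spec_covering(network, kernel, cell_size, extra_points=pts)
        raster = kernel_density_raster(network, spec, kernel)
    # flatten the network into straight pieces once; per person the buffer
    # lengths for all pieces come from one vectorized quadratic solve
    piece_a = np.vstack([s.vertices[:-1] for s in network]) if network else np.empty((0, 2))
    piece_b = np.vstack([s.vertices[1:] for s in network]) if network else np.empty((0, 2))
    piece_aadt = (
        np.concatenate([[s.aadt] * (len(s.vertices) - 1) for s in network])
        if network
        else np.empty(0)
    )
    rows = []
    for pid, p in zip(kept["person_id"], pts):
        lens_in = _piece_lengths_in_disc(piece_a, piece_b, p, r_in)
        lens_out = _piece_lengths_in_disc(piece_a, piece_b, p, r_out)
        v_in = float((lens_in / 1000.0) @ piece_aadt)
        v_out = float((lens_out / 1000.0) @ piece_aadt)
        dens = density_at(raster, (p[0], p[1]))
        rows.append((pid, v_in, v_out, dens))
    metrics = pd.DataFrame(rows, columns=["person_id", "vkt_250", "vkt_500", "density"])
    return metrics, rejects
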