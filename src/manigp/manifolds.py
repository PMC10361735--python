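"""Spectral geometry of the circle and the 2-sphere.

The covariogram machinery in this package is built on the spectral
decomposition of the Laplace–Beltrami operator.  For the two manifolds
implemented here everything is explicit:

* the **circle** of unit circumference, parameterised by an angle
  ``theta`` in ``[0, 1)``, has eigenvalues ``lambda_l = 4 pi^2 l^2`` with
  multiplicity 1 (``l = 0``) or 2 (``l >= 1``);
* the **unit 2-sphere** has eigenvalues ``lambda_l = l (l + 1)`` with
  multiplicity ``2 l + 1``.

Rather than enumerating individual eigenfunctions, each eigenspace is
represented through its *addition kernel* ``A_l(t)``: the sum of
``f(x) f(y)`` over an orthonormal basis of the level-``l`` eigenspace,
which by the addition theorem depends only on the geodesic separation
``t = d(x, y)``.  On the circle ``A_l(t) = 2 cos(2 pi l t)``; on the
sphere ``A_l(t) = (2l + 1) P_l(cos t) / (4 pi)`` with ``P_l`` the
Legendre polynomial.  In both cases ``A_l(0) = m_l / V`` where ``m_l``
is the multiplicity and ``V`` the volume of the manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "Circle",
    "Sphere",
    "Manifold",
    "ManifoldSpectrum",
    "DesignSet",
    "circle_spectrum",
    "sphere_spectrum",
    "geodesic_distance",
    "dyadic_circle_design",
    "fibonacci_sphere_design",
    "min_separation",
    "read_design",
    "write_design",
]

#: Hard cap on Legendre degree; the three-term recurrence is stable on
#: [-1, 1] well past this, but covariance assembly cost grows linearly in
#: the degree so we refuse absurd requests explicitly.
MAX_LEGENDRE_DEGREE = 512


def _legendre_table(max_degree: int, z: np.ndarray) -> np.ndarray:
    """All Legendre polynomials ``P_0..P_max_degree`` at points ``z``.

    Three-term recurrence ``(l+1) P_{l+1} = (2l+1) z P_l - l P_{l-1}``,
    vectorised over ``z``; returns shape ``(max_degree + 1,) + z.shape``.
    """
    if max_degree > MAX_LEGENDRE_DEGREE:
        raise ValueError(
            f"Legendre degree {max_degree} exceeds the cap "
            f"{MAX_LEGENDRE_DEGREE}; raise manigp.manifolds.MAX_LEGENDRE_DEGREE "
            "explicitly if you really need this."
        )
    z = np.asarray(z, dtype=float)
    out = np.empty((max_degree + 1,) + z.shape, dtype=float)
    out[0] = 1.0
    if max_degree >= 1:
        out[1] = z
    for l in range(1, max_degree):
        out[l + 1] = ((2 * l + 1) * z * out[l] - l * out[l - 1]) / (l + 1)
    return out


class Manifold:
    """Base class: dimension, volume, spectrum and geodesic distance."""

    dim: int
    volume: float
    name: str

    def eigenvalue(self, levels):
        raise NotImplementedError

    def multiplicity(self, levels):
        raise NotImplementedError

    def addition_kernels(self, max_level: int, t) -> np.ndarray:
        """``A_l(t)`` for ``l = 0..max_level``; shape ``(L+1,) + t.shape``."""
        raise NotImplementedError

    def distance(self, x, y) -> np.ndarray:
        raise NotImplementedError

    def distance_matrix(self, points) -> np.ndarray:
        raise NotImplementedError

    def __eq__(self, other):
        return type(self) is type(other)

    def __hash__(self):
        return hash(type(self))

    def __repr__(self):
        return self.name


class Circle(Manifold):
    """Circle of unit circumference; points are angles in ``[0, 1)``."""

    dim = 1
    volume = 1.0
    name = "circle"

    def eigenvalue(self, levels):
        l = np.asarray(levels, dtype=float)
        return 4.0 * np.pi**2 * l**2

    def multiplicity(self, levels):
        l = np.asarray(levels)
        return np.where(l == 0, 1, 2).astype(int)

    def addition_kernels(self, max_level, t):
        t = np.asarray(t, dtype=float)
        l = np.arange(max_level + 1).reshape((-1,) + (1,) * t.ndim)
        out = 2.0 * np.cos(2.0 * np.pi * l * t)
        out[0] = 1.0  # A_0 = m_0 / V = 1
        return out

    @staticmethod
    def _validate(x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x >= 1):
            raise ValueError("circle coordinates must lie in [0, 1)")
        return x

    def distance(self, x, y):
        x, y = self._validate(x), self._validate(y)
        d = np.abs(x - y) % 1.0
        return np.minimum(d, 1.0 - d)

    def distance_matrix(self, points):
        p = self._validate(np.atleast_1d(points))
        d = np.abs(p[:, None] - p[None, :]) % 1.0
        return np.minimum(d, 1.0 - d)


class Sphere(Manifold):
    """Unit 2-sphere; points are unit 3-vectors."""

    dim = 2
    volume = 4.0 * np.pi
    name = "sphere"

    def eigenvalue(self, levels):
        l = np.asarray(levels, dtype=float)
        return l * (l + 1.0)

    def multiplicity(self, levels):
        l = np.asarray(levels)
        return (2 * l + 1).astype(int)

    def addition_kernels(self, max_level, t):
        t = np.asarray(t, dtype=float)
        P = _legendre_table(max_level, np.cos(t))
        l = np.arange(max_level + 1).reshape((-1,) + (1,) * t.ndim)
        return (2 * l + 1) * P / (4.0 * np.pi)

    @staticmethod
    def _validate(x, tol: float = 1e-8) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[-1] != 3:
            raise ValueError("sphere points must be 3-vectors")
        norms = np.linalg.norm(x, axis=-1)
        if np.any(np.abs(norms - 1.0) > tol):
            raise ValueError("sphere points must be unit vectors")
        return x

    def distance(self, x, y):
        x, y = self._validate(x), self._validate(y)
        dots = np.clip(np.sum(x * y, axis=-1), -1.0, 1.0)
        out = np.arccos(dots)
        return out[0] if out.shape == (1,) else out

    def distance_matrix(self, points):
        p = self._validate(points)
        g = np.clip(p @ p.T, -1.0, 1.0)
        return np.arccos(g)


@dataclass(frozen=True)
class ManifoldSpectrum:
    """Levels 0..max_level of the Laplace–Beltrami spectrum of a manifold.

    ``eigenvalues`` and ``multiplicities`` index *distinct* eigenvalues;
    every spectral sum in this package weights by multiplicity.
    """

    manifold: Manifold
    max_level: int
    eigenvalues: np.ndarray
    multiplicities: np.ndarray

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.max_level + 1)

    def addition_kernels(self, t) -> np.ndarray:
        return self.manifold.addition_kernels(self.max_level, t)


def _spectrum(manifold: Manifold, max_level: int) -> ManifoldSpectrum:
    if max_level < 0:
        raise ValueError("max_level must be nonnegative")
    levels = np.arange(max_level + 1)
    return ManifoldSpectrum(
        manifold=manifold,
        max_level=int(max_level),
        eigenvalues=manifold.eigenvalue(levels),
        multiplicities=manifold.multiplicity(levels),
    )


def circle_spectrum(max_level: int) -> ManifoldSpectrum:
    """Spectrum of the unit-circumference circle: ``lambda_l = 4 pi^2 l^2``."""
    return _spectrum(Circle(), max_level)


def sphere_spectrum(max_level: int) -> ManifoldSpectrum:
    """Spectrum of the unit 2-sphere: ``lambda_l = l (l + 1)``."""
    return _spectrum(Sphere(), max_level)


def geodesic_distance(manifold: Union[Manifold, ManifoldSpectrum], x, y):
    """Geodesic distance between points ``x`` and ``y`` on the manifold."""
    if isinstance(manifold, ManifoldSpectrum):
        manifold = manifold.manifold
    return manifold.distance(x, y)


# ---------------------------------------------------------------------------
# Designs


@dataclass
class DesignSet:
    """Ordered observation sites on a manifold.

    The ordering matters: prefixes of the point list are themselves valid
    designs, which is how the increasing-sequence (infill) asymptotics are
    realised in the experiments.
    """

    manifold: Manifold
    points: np.ndarray
    _distances: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def distances(self) -> np.ndarray:
        if self._distances is None:
            self._distances = self.manifold.distance_matrix(self.points)
        return self._distances

    @property
    def q(self) -> float:
        """Minimal separation; ``inf`` for a single-point design."""
        if self.n < 2:
            return np.inf
        off = self.distances[~np.eye(self.n, dtype=bool)]
        return float(off.min())

    def prefix(self, n: int) -> "DesignSet":
        return DesignSet(self.manifold, self.points[:n])

    def distances_to(self, x0) -> np.ndarray:
        """Geodesic distances from every design point to ``x0``."""
        if self.manifold.dim == 1:
            return self.manifold.distance(self.points, np.asarray(x0, dtype=float))
        x0 = np.atleast_2d(np.asarray(x0, dtype=float))
        return self.manifold.distance(self.points, np.broadcast_to(x0, self.points.shape))


def dyadic_circle_design(level: int, include_zero: bool = True) -> DesignSet:
    """Nested dyadic grid ``{j / 2^level}`` on the circle.

    Points are ordered by refinement level, so the first ``2^k`` points
    reproduce the level-``k`` design exactly (an increasing sequence of
    designs).  ``include_zero=False`` drops the point at ``theta = 0``,
    leaving 0 as an accumulation point of the design — the configuration
    used for the prediction experiments, where the prediction site must
    not coincide with an observation.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    pts = [0.0, 0.5]
    for k in range(2, level + 1):
        step = 0.5**k
        pts.extend(j * step for j in range(1, 2**k, 2))
    if not include_zero:
        pts = pts[1:]
    return DesignSet(Circle(), np.array(pts))


def fibonacci_sphere_design(n: int) -> DesignSet:
    """Quasi-uniform Fibonacci lattice of ``n`` points on the unit sphere."""
    if n < 1:
        raise ValueError("n must be >= 1")
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return DesignSet(Sphere(), pts)


def min_separation(design: DesignSet) -> float:
    """Smallest off-diagonal geodesic distance of a design.

    Raises if any two points coincide: a zero separation breaks the
    positive-definiteness guarantees downstream.
    """
    if design.n < 2:
        raise ValueError("min_separation needs at least two points")
    q = design.q
    if q <= 0.0:
        raise ValueError("design contains duplicate points (q = 0)")
    return q


# ---------------------------------------------------------------------------
# Plain-text design I/O


def write_design(design: DesignSet, path) -> None:
    """Write a design as delimited text, one point per row, with header."""
    path = Path(path)
    if design.manifold.dim == 1:
        header, data = "theta", design.points.reshape(-1, 1)
    else:
        header, data = "x,y,z", design.points
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def read_design(path) -> DesignSet:
    """Read a design from delimited text.

    The header decides the format: ``theta`` (circle angle in [0,1)),
    ``x,y,z`` (sphere unit vectors) or ``lon,lat`` (sphere, degrees).
    Row order is the design order.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().lower()
    cols = [c.strip() for c in header.split(",")]
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if cols == ["theta"]:
        return DesignSet(Circle(), data[:, 0])
    if cols == ["x", "y", "z"]:
        pts = data / np.linalg.norm(data, axis=1, keepdims=True)
        return DesignSet(Sphere(), pts)
    if cols == ["lon", "lat"]:
        lon, lat = np.radians(data[:, 0]), np.radians(data[:, 1])
        pts = np.column_stack(
            [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
        )
        return DesignSet(Sphere(), pts)
    raise ValueError(f"unrecognised design header: {header!r}")
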