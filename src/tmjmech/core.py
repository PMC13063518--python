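"""Core containers shared across the package.

Units follow the mm-N-MPa-s convention for all file-level and user-facing
quantities; the rigid-body simulator converts to SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz; must be positive.
    values : ndarray
        Sample values; at least two, all finite.
    start_time : float
        Time of the first sample in seconds.
    """

    sample_rate: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")
        if vals.ndim != 1 or vals.size < 2:
            raise InvalidInputError("series needs at least 2 samples")
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("series values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Time span from first to last sample, in seconds."""
        return (self.n - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) * self.dt

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        return UniformSeries(self.sample_rate, np.asarray(values, float), self.start_time)

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Index slice covering ``[t0, t1]`` (inclusive), validated in-span."""
        t0, t1 = float(window[0]), float(window[1])
        if t1 <= t0:
            raise InvalidInputError(f"empty or inverted window {window}")
        eps = 0.5 * self.dt
        if t0 < self.start_time - eps or t1 > self.end_time + eps:
            raise InvalidInputError(f"window {window} outside series span "
                                    f"[{self.start_time}, {self.end_time}]")
        i0 = int(np.ceil((t0 - self.start_time) * self.sample_rate - 1e-9))
        i1 = int(np.floor((t1 - self.start_time) * self.sample_rate + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.n - 1)
        if i1 <= i0:
            raise InvalidInputError(f"window {window} contains fewer than 2 samples")
        return slice(i0, i1 + 1)


@dataclass
class TriangleMesh:
    """Triangulated surface with optional per-vertex outward normals.

    Vertices in mm. Degenerate (zero-area) faces are rejected at
    construction; the mean edge length is recorded and a warning flag set
    when it exceeds ``EDGE_WARN_MM`` (analysis meshes are expected near the
    0.3 mm working resolution).
    """

    EDGE_WARN_MM = 0.45

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None
    mean_edge: float = field(init=False)
    n_components: int = field(init=False)
    coarse_warning: bool = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
            raise InvalidInputError("vertices must be a non-empty (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] == 0:
            raise InvalidInputError("faces must be a non-empty (m, 3) array")
        if f.min() < 0 or f.max() >= len(v):
            raise InvalidInputError("face indices out of range")
        tri = v[f]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        if np.any(areas < 1e-14):
            raise InvalidInputError("mesh contains degenerate (zero-area) faces")
        self.vertices = v
        self.faces = f
        if self.vertex_normals is not None:
            nrm = np.asarray(self.vertex_normals, dtype=float)
            if nrm.shape != v.shape:
                raise InvalidInputError("vertex_normals shape mismatch")
            self.vertex_normals = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        self.mean_edge = float(
            np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1).mean())
        self.coarse_warning = self.mean_edge > self.EDGE_WARN_MM
        self.n_components = _count_components(len(v), edges)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def compute_vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (used when none were supplied)."""
        if self.vertex_normals is not None:
            return self.vertex_normals
        tri = self.triangles()
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        vn /= np.linalg.norm(vn, axis=1, keepdims=True)
        self.vertex_normals = vn
        return vn


def _count_components(n_vertices: int, edges: np.ndarray) -> int:
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    adj = sp.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
        shape=(n_vertices, n_vertices))
    ncomp, _ = connected_components(adj, directed=False)
    return int(ncomp)


@dataclass
class ScalarField:
    """One real value per mesh vertex (e.g. joint gap in mm, congruency in 1/mm).

    NaN marks vertices where the quantity is undefined (excluded from
    summaries).
    """

    mesh: TriangleMesh
    values: np.ndarray
    name: str = "field"
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.mesh.n_vertices,):
            raise InvalidInputError("field length must equal vertex count")
        self.values = vals

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def summary(self) -> dict:
        v = self.values[self.defined]
        return {"name": self.name, "units": self.units, "n_defined": int(v.size),
                "mean": float(v.mean()), "min": float(v.min()), "max": float(v.max())}


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures (1/mm), ``k_max >= k_min`` everywhere.

    ``dir_max`` optionally stores the unit principal direction of ``k_max``.
    NaN rows mark vertices where the fit was undefined.
    """

    mesh: TriangleMesh
    k_max: np.ndarray
    k_min: np.ndarray
    dir_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        kmax = np.asarray(self.k_max, float)
        kmin = np.asarray(self.k_min, float)
        if kmax.shape != (self.mesh.n_vertices,) or kmin.shape != kmax.shape:
            raise InvalidInputError("curvature arrays must match vertex count")
        ok = np.isfinite(kmax) & np.isfinite(kmin)
        if np.any(kmax[ok] < kmin[ok] - 1e-12):
            raise InvalidInputError("k_max < k_min at some vertex")
        self.k_max, self.k_min = kmax, kmin
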