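"""Lead fields, source spaces, and forward projection of cross-spectra.

The toy head model is a current dipole in an infinite homogeneous medium:
the potential of a dipole with moment ``q`` at ``r0`` observed at ``r`` is

    phi(r) = (1 / (4 pi sigma)) * q . (r - r0) / |r - r0|^3

sampled at the sensor positions and then average-referenced.  This keeps
the forward operator closed-form and testable while preserving the
qualitative smoothness and severe ill-conditioning that source imaging
must confront when the number of sensors is far below the number of
sources.  Geodesic distances over the cortical mesh are graph shortest
paths along triangle edges weighted by Euclidean edge length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "SourceSpace",
    "SensorMontage",
    "LeadField",
    "geodesic_distances",
    "make_toy_leadfield",
    "project_source_cross_spectrum",
]


@dataclass
class SourceSpace:
    """Triangulated source mesh with vertex coordinates in mm.

    ``geodesic`` caches the all-pairs graph geodesic distance matrix; it is
    computed on first access via :func:`geodesic_distances`.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    _geodesic: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (G, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (n, 3)")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(
            initial=-1
        ) >= len(self.vertices):
            raise ValueError("triangle indices out of range")

    @property
    def num_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def geodesic(self) -> np.ndarray:
        if self._geodesic is None:
            self._geodesic = geodesic_distances(self)
        return self._geodesic

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals, oriented away from the centroid."""
        v = self.vertices
        t = self.triangles
        face_n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        normals = np.zeros_like(v)
        for col in range(3):
            np.add.at(normals, t[:, col], face_n)
        # orient outward relative to the mesh centroid
        centroid = v.mean(axis=0)
        flip = np.einsum("ij,ij->i", normals, v - centroid) < 0
        normals[flip] *= -1
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return normals / norms


@dataclass
class SensorMontage:
    """Named sensor positions (mm) on the scalp."""

    names: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (E, 3)")
        if len(self.names) != self.positions.shape[0]:
            raise ValueError("names and positions disagree in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("sensor names must be unique")

    @property
    def num_sensors(self) -> int:
        return int(self.positions.shape[0])


@dataclass
class LeadField:
    """Forward operator L mapping source amplitudes to sensor readings."""

    matrix: np.ndarray
    channel_names: list[str]
    source_space_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("lead field must be a 2-D array")
        if not np.isfinite(self.matrix).all():
            raise ValueError("lead field has non-finite entries")
        col_norms = np.linalg.norm(self.matrix, axis=0)
        if np.any(col_norms == 0):
            raise ValueError("lead field has an all-zero column (invisible source)")
        if len(self.channel_names) != self.matrix.shape[0]:
            raise ValueError("channel_names length does not match rows")

    @property
    def num_sensors(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def num_sources(self) -> int:
        return int(self.matrix.shape[1])


def geodesic_distances(space: SourceSpace) -> np.ndarray:
    """All-pairs shortest-path distance along mesh edges (mm).

    Edges are the triangle edges weighted by Euclidean length.  Raises for a
    disconnected mesh, naming the component sizes.
    """
    g = space.num_vertices
    t = space.triangles
    i = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
    j = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
    edges = np.unique(np.sort(np.column_stack([i, j]), axis=1), axis=0)
    i, j = edges[:, 0], edges[:, 1]
    w = np.linalg.norm(space.vertices[i] - space.vertices[j], axis=1)
    adj = coo_matrix(
        (
            np.concatenate([w, w]),
            (np.concatenate([i, j]), np.concatenate([j, i])),
        ),
        shape=(g, g),
    ).tocsr()
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"mesh is disconnected: {n_comp} components with sizes {sizes.tolist()}"
        )
    dist = shortest_path(adj, method="D", directed=False)
    return 0.5 * (dist + dist.T)


def make_toy_leadfield(
    montage: SensorMontage,
    space: SourceSpace,
    conductivity: float = 0.33,
    normalize_columns: bool = False,
    source_space_id: str = "",
) -> LeadField:
    """Lead field of normal-oriented dipoles in an infinite homogeneous medium.

    Column ``g`` is the electric potential of a unit current dipole at
    vertex ``g`` oriented along the mesh normal, evaluated at the sensor
    positions and average-referenced (each column sums to zero across
    sensors).  ``conductivity`` is in S/m (mm-scale coordinates are
    consistent as long as all geometry uses the same unit).
    """
    if conductivity <= 0:
        raise ValueError("conductivity must be positive")
    sensors = montage.positions
    sources = space.vertices
    centroid = sources.mean(axis=0)
    sensor_radius = np.linalg.norm(sensors - centroid, axis=1).min()
    source_radius = np.linalg.norm(sources - centroid, axis=1).max()
    if source_radius >= sensor_radius:
        raise ValueError(
            "sources must lie strictly inside the sensor sphere "
            f"(max source radius {source_radius:.2f} >= min sensor radius "
            f"{sensor_radius:.2f})"
        )
    normals = space.vertex_normals()
    diff = sensors[:, None, :] - sources[None, :, :]  # (E, G, 3)
    r3 = np.linalg.norm(diff, axis=2) ** 3
    if np.any(r3 == 0):
        raise ValueError("a source coincides with a sensor")
    lf = np.einsum("egk,gk->eg", diff, normals) / (4.0 * np.pi * conductivity * r3)
    lf = lf - lf.mean(axis=0, keepdims=True)
    if normalize_columns:
        lf = lf / np.linalg.norm(lf, axis=0, keepdims=True)
    return LeadField(
        lf,
        list(montage.names),
        source_space_id=source_space_id,
        metadata={
            "average_referenced": True,
            "column_normalized": bool(normalize_columns),
            "conductivity": float(conductivity),
        },
    )


def project_source_cross_spectrum(src_cs, L: LeadField, noise_cs):
    """Forward-project a source cross-spectrum: L Sigma_ii L^T + Sigma_xi.

    ``src_cs`` and ``noise_cs`` are :class:`~cesi.spectral.CrossSpectrum`
    objects in source and sensor space; the result is a sensor-space
    cross-spectrum on the same grid.
    """
    from cesi.spectral import CrossSpectrum

    if src_cs.num_channels != L.num_sources:
        raise ValueError("source cross-spectrum does not match lead field columns")
    if noise_cs.num_channels != L.num_sensors:
        raise ValueError("noise cross-spectrum does not match lead field rows")
    if noise_cs.grid.num_frequencies != src_cs.grid.num_frequencies:
        raise ValueError("source and noise grids disagree")
    lf = L.matrix
    mats = np.einsum("eg,fgh,dh->fed", lf, src_cs.matrices, lf) + noise_cs.matrices
    mats = 0.5 * (mats + np.conj(np.transpose(mats, (0, 2, 1))))
    return CrossSpectrum(
        mats, src_cs.sample_size, src_cs.grid, space_tag="sensor",
        band_names=src_cs.band_names,
    )
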