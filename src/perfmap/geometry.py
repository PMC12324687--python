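"""Spherical geometry primitives.

Parcel-level spatial statistics on the cortex operate on a spherical
projection of the surface: each parcel is represented by the unit vector of
its centroid vertex, distances between parcels are great-circle arcs, and
rotation-based null models draw uniform random rotations of the sphere.
Everything downstream (spin tests, variogram surrogates, the synthetic
cohort generator) consumes the primitives defined here.

Distances are always expressed in radians on the unit sphere; callers scale
by a physical radius if they need millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SphereMesh",
    "Parcellation",
    "fibonacci_sphere",
    "great_circle_distance",
    "parcel_centroids",
    "random_rotation",
    "random_rotations",
    "mirror_rotation",
    "stream_rng",
    "read_parcel_table",
    "write_parcel_table",
]

#: tolerance for "is a unit vector" checks on stored meshes
_UNIT_TOL_STRICT = 1e-9
#: looser tolerance accepted on raw input coordinates
_UNIT_TOL_INPUT = 1e-6


def stream_rng(seed: int, stream: int = 0) -> np.random.Generator:
    """Independent, order-free random stream ``stream`` under a master seed.

    All heavy resampling loops in the package (spin ensembles, bootstraps,
    cross-validation splits) derive one stream per iteration from a single
    master seed, so serial and parallel evaluation orders produce identical
    ensembles.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass
class SphereMesh:
    """Vertices on the unit sphere, with optional faces and exclusion mask.

    The exclusion mask marks a "medial wall"-like region whose vertices carry
    no data; spin null models treat rotated positions landing there
    specially.
    """

    vertex_coords: np.ndarray
    faces: Optional[np.ndarray] = None
    exclusion_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        if self.vertex_coords.ndim != 2 or self.vertex_coords.shape[1] != 3:
            raise ValueError("vertex_coords must be (n_vertices, 3)")
        norms = np.linalg.norm(self.vertex_coords, axis=1)
        bad = np.where(np.abs(norms - 1.0) > _UNIT_TOL_STRICT)[0]
        if bad.size:
            raise ValueError(f"vertices not on the unit sphere: indices {bad[:5].tolist()}")
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=int)
            if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertex_coords):
                raise ValueError("face indices out of range")
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if self.exclusion_mask.shape != (len(self.vertex_coords),):
                raise ValueError("exclusion_mask must have one entry per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)


@dataclass
class Parcellation:
    """Per-vertex parcel labels plus a parcel table.

    Label 0 is reserved for excluded vertices. ``parcel_table`` has columns
    ``parcel_id``, ``name``, ``hemisphere``, ``centroid_vertex``.
    """

    labels: np.ndarray
    parcel_table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        ids = self.parcel_table["parcel_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("parcel ids must be unique")
        if (ids == 0).any():
            raise ValueError("parcel id 0 is reserved for excluded vertices")
        present = np.unique(self.labels[self.labels != 0])
        missing = np.setdiff1d(present, ids)
        if missing.size:
            raise ValueError(f"labels contain ids absent from parcel_table: {missing.tolist()}")
        if "centroid_vertex" in self.parcel_table:
            cv = self.parcel_table["centroid_vertex"].to_numpy()
            if not np.array_equal(self.labels[cv], ids):
                raise ValueError("centroid vertices must carry their parcel's label")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_table)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (Fibonacci lattice).

    Used as stand-in geometry wherever a real surface mesh or atlas is not
    supplied: the lattice gives approximately equal-area parcels, the
    property the spin test relies on.
    """
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    coords = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return coords / np.linalg.norm(coords, axis=1, keepdims=True)


def great_circle_distance(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (radians) between unit vectors.

    d(a, b) = arccos(clip(a.b, -1, 1)); the result is symmetric with a zero
    diagonal and values in [0, pi].
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        bad = np.where(~np.isfinite(coords).all(axis=1))[0]
        raise ValueError(f"non-finite coordinates at indices {bad[:5].tolist()}")
    norms = np.linalg.norm(coords, axis=1)
    bad = np.where(np.abs(norms - 1.0) > _UNIT_TOL_INPUT)[0]
    if bad.size:
        raise ValueError(f"coordinates not unit-norm at indices {bad[:5].tolist()}")
    dots = np.clip(coords @ coords.T, -1.0, 1.0)
    d = np.arccos(dots)
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def parcel_centroids(mesh: SphereMesh, labels: np.ndarray) -> pd.DataFrame:
    """Centroid vertex of every parcel.

    The centroid is the member vertex closest (great-circle) to the parcel's
    renormalised mean direction; ties resolve to the lowest vertex index.
    Returns a frame with columns ``parcel_id`` and ``centroid_vertex``.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (mesh.n_vertices,):
        raise ValueError("labels must have one entry per vertex")
    out_ids, out_verts = [], []
    for pid in np.unique(labels[labels != 0]):
        members = np.where(labels == pid)[0]
        mean_dir = mesh.vertex_coords[members].mean(axis=0)
        norm = np.linalg.norm(mean_dir)
        if norm < 1e-9:
            raise ValueError(f"parcel {pid}: members are antipodally balanced, centroid undefined")
        mean_dir /= norm
        dots = mesh.vertex_coords[members] @ mean_dir
        # argmax of the dot product = argmin of great-circle distance;
        # np.argmax returns the first (lowest-index) maximiser, which after
        # sorting members ascending realises the lowest-vertex-index tie rule
        best = members[np.argmax(np.round(dots, 12))]
        out_ids.append(int(pid))
        out_verts.append(int(best))
    return pd.DataFrame({"parcel_id": out_ids, "centroid_vertex": out_verts})


def random_rotation(seed: int | np.random.Generator) -> np.ndarray:
    """One Haar-uniform rotation of R^3 (QR of a Gaussian matrix, sign-fixed)."""
    return random_rotations(1, seed)[0]


def random_rotations(n: int, seed: int | np.random.Generator) -> np.ndarray:
    """``n`` independent Haar-uniform 3x3 rotation matrices."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((n, 3, 3))
    for k in range(n):
        g = rng.standard_normal((3, 3))
        q, r = np.linalg.qr(g)
        q = q * np.sign(np.diag(r))  # make the O(3) draw Haar-unique
        if np.linalg.det(q) < 0:
            q[:, 2] = -q[:, 2]  # reflect into SO(3)
        out[k] = q
    return out


def mirror_rotation(rotation: np.ndarray) -> np.ndarray:
    """Mirrored counterpart M R M (M = x-axis reflection) for the opposite hemisphere."""
    m = np.diag([-1.0, 1.0, 1.0])
    return m @ rotation @ m


def read_parcel_table(path) -> pd.DataFrame:
    """Read the canonical TSV parcel table.

    Columns: parcel_id, name, hemisphere, x, y, z (unit-sphere centroids).
    """
    tab = pd.read_csv(path, sep="\t")
    required = {"parcel_id", "name", "hemisphere", "x", "y", "z"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"parcel table missing columns: {sorted(missing)}")
    coords = tab[["x", "y", "z"]].to_numpy(dtype=float)
    norms = np.linalg.norm(coords, axis=1)
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL_INPUT):
        raise ValueError("parcel table centroids must be unit vectors")
    return tab


def write_parcel_table(path, parcel_ids: Sequence[int], coords: np.ndarray,
                       names: Optional[Sequence[str]] = None,
                       hemispheres: Optional[Sequence[str]] = None) -> None:
    coords = np.asarray(coords, dtype=float)
    n = len(parcel_ids)
    tab = pd.DataFrame({
        "parcel_id": list(parcel_ids),
        "name": list(names) if names is not None else [f"parcel{p}" for p in parcel_ids],
        "hemisphere": list(hemispheres) if hemispheres is not None else ["L"] * n,
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
    })
    tab.to_csv(path, sep="\t", index=False)
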