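"""Fixed-length representations of the absorber's local environment.

Two descriptors are implemented, both invariant to rotation, translation
and atom reindexing:

* the sorted Coulomb matrix (CM): pairwise matrix with diagonal
  ``0.5 * Z**2.4`` and off-diagonal ``Z_I * Z_J / r_IJ``, built from the
  N atoms nearest the absorber, rows/columns permuted into descending
  row-norm order, upper triangle flattened row-wise;
* the radial distribution curve (RDC): a charge-weighted Gaussian
  smearing of all interatomic distances within a cutoff sphere,
  ``f(R) = sum_{I<J} w_I w_J exp(-alpha (r_IJ - R)**2)`` sampled on a
  regular grid reaching twice the cutoff radius.

Distances are in Angstrom by default; the Coulomb matrix can optionally
be built with distances in Bohr, which only rescales the off-diagonal.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structures import AtomicCluster, local_environment, nearest_n

__all__ = [
    "CMConfig",
    "RDCConfig",
    "CoulombMatrix",
    "FeatureVector",
    "SingularGeometryError",
    "FeaturisationError",
    "coulomb_matrix",
    "sort_cm",
    "flatten_cm",
    "unflatten_cm",
    "cm_feature",
    "rdc",
    "featurise_batch",
    "max_encoded_radius",
    "required_cm_dimension",
    "write_feature_table",
    "read_feature_table",
]

ANGSTROM_PER_BOHR = 0.529177210903


class SingularGeometryError(ValueError):
    """Coincident atoms make the Coulomb matrix singular."""


@dataclass(frozen=True)
class CMConfig:
    """Coulomb-matrix settings.

    ``n_atoms`` is the matrix dimension N: the N atoms closest to the
    absorber (the absorber among them) enter the matrix, the rest are
    discarded; clusters with fewer than N atoms are zero-padded.
    """

    n_atoms: int = 20
    length_unit: str = "angstrom"  # or "bohr"

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.length_unit not in ("angstrom", "bohr"):
            raise ValueError("length_unit must be 'angstrom' or 'bohr'")

    @property
    def feature_length(self) -> int:
        return self.n_atoms * (self.n_atoms + 1) // 2


def _default_grid(cutoff: float, n_points: int) -> np.ndarray:
    return np.linspace(0.0, 2.0 * cutoff, n_points)


@dataclass(frozen=True)
class RDCConfig:
    """Radial-distribution-curve settings.

    ``alpha`` (1/A^2) sets the sharpness of the Gaussian smearing:
    larger alpha resolves finer distance structure but eventually yields
    a sparse curve.  The grid spans 0 to twice the cutoff radius — the
    longest pair distance two in-sphere atoms can realise.  Weights
    default to nuclear charge; any per-element scalar map can be
    substituted to build property-weighted curves.
    """

    alpha: float = 10.0
    cutoff: float = 4.0
    grid: np.ndarray | None = None
    n_points: int = 800
    weight_property: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        grid = self.grid
        if grid is None:
            grid = _default_grid(self.cutoff, self.n_points)
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be a strictly increasing vector")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "n_points", len(grid))

    def weights(self, charges: np.ndarray) -> np.ndarray:
        if self.weight_property is None:
            return np.asarray(charges, dtype=float)
        return np.array(
            [self.weight_property[int(z)] for z in charges], dtype=float
        )

    @property
    def feature_length(self) -> int:
        return len(self.grid)


@dataclass
class CoulombMatrix:
    """A symmetric N x N Coulomb matrix with its source label."""

    matrix: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Coulomb matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("Coulomb matrix must be symmetric")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FeatureVector:
    """A fixed-length numeric encoding of one cluster."""

    values: np.ndarray
    representation: str  # "cm" | "rdc"
    config: CMConfig | RDCConfig | None = None
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("feature values must be a vector")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)


def coulomb_matrix(cluster: AtomicCluster, config: CMConfig | None = None) -> CoulombMatrix:
    """Build the (unsorted) Coulomb matrix of the N nearest atoms.

    Diagonal entries are ``0.5 * Z**2.4`` (free-atom term); off-diagonal
    entries ``Z_I * Z_J / r_IJ`` with r in the configured length unit.
    Clusters with fewer than N sites leave trailing rows/columns zero.
    """
    config = config or CMConfig()
    sub = nearest_n(cluster, config.n_atoms)
    z = sub.charges
    pos = sub.positions
    if config.length_unit == "bohr":
        pos = pos / ANGSTROM_PER_BOHR
    k = len(z)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    off = np.zeros((k, k))
    iu = ~np.eye(k, dtype=bool)
    if np.any(d[iu] <= 0):
        raise SingularGeometryError("coincident atoms in Coulomb matrix")
    off[iu] = np.outer(z, z)[iu] / d[iu]
    m = np.zeros((config.n_atoms, config.n_atoms))
    m[:k, :k] = off
    m[np.arange(k), np.arange(k)] = 0.5 * z**2.4
    return CoulombMatrix(m, cluster.label)


def sort_cm(cm: CoulombMatrix) -> CoulombMatrix:
    """Permute rows and columns into descending row-L2-norm order.

    One permutation is applied simultaneously to rows and columns, so
    symmetry is preserved.  Equal norms keep their pre-sort relative
    order (stable sort), which makes features deterministic for
    symmetric geometries; all-zero padding rows end up trailing.
    """
    norms = np.linalg.norm(cm.matrix, axis=1)
    order = np.argsort(-norms, kind="stable")
    return CoulombMatrix(cm.matrix[np.ix_(order, order)], cm.label)


def flatten_cm(cm: CoulombMatrix) -> FeatureVector:
    """Row-wise upper triangle (diagonal included): length N(N+1)/2."""
    n = cm.n
    iu = np.triu_indices(n)
    return FeatureVector(cm.matrix[iu], "cm", label=cm.label)


def unflatten_cm(vec: FeatureVector | np.ndarray) -> CoulombMatrix:
    """Reconstruct the symmetric matrix from a flattened upper triangle."""
    v = vec.values if isinstance(vec, FeatureVector) else np.asarray(vec)
    n = int((np.sqrt(8 * len(v) + 1) - 1) / 2)
    if n * (n + 1) // 2 != len(v):
        raise ValueError(f"length {len(v)} is not a triangular number")
    m = np.zeros((n, n))
    m[np.triu_indices(n)] = v
    m = m + m.T - np.diag(np.diag(m))
    label = vec.label if isinstance(vec, FeatureVector) else ""
    return CoulombMatrix(m, label)


def cm_feature(cluster: AtomicCluster, config: CMConfig | None = None) -> FeatureVector:
    """Full CM pipeline: build, norm-sort, flatten."""
    config = config or CMConfig()
    fv = flatten_cm(sort_cm(coulomb_matrix(cluster, config)))
    fv.config = config
    return fv


def rdc(cluster: AtomicCluster, config: RDCConfig | None = None) -> FeatureVector:
    """Radial distribution curve of the in-cutoff environment.

    The cluster is first restricted to the cutoff sphere around the
    absorber (idempotent if already restricted); the pair sum then runs
    over *all* pairs of in-sphere atoms, absorber included.  A lone
    absorber yields the all-zero vector.
    """
    config = config or RDCConfig()
    sub = local_environment(cluster, config.cutoff)
    w = config.weights(sub.charges)
    pos = sub.positions
    k = len(sub)
    if k < 2:
        values = np.zeros(len(config.grid))
    else:
        iu, ju = np.triu_indices(k, 1)
        r = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        ww = w[iu] * w[ju]
        values = np.einsum(
            "p,pg->g", ww, np.exp(-config.alpha * (r[:, None] - config.grid[None, :]) ** 2)
        )
    fv = FeatureVector(values, "rdc", config, cluster.label)
    return fv


@dataclass
class FeaturisationFailure:
    """One cluster that could not be featurised, with the reason."""

    index: int
    label: str
    error: str


class FeaturisationError(RuntimeError):
    """Raised when every cluster in a batch fails."""


def featurise_batch(
    clusters: Sequence[AtomicCluster],
    representation: str,
    config: CMConfig | RDCConfig | None = None,
) -> tuple[pd.DataFrame, list[FeaturisationFailure]]:
    """Featurise many clusters into a row-per-cluster table.

    Row order follows input order and rows are indexed by cluster label.
    Per-cluster failures are collected into the returned list rather
    than aborting the batch; the batch raises only if *every* cluster
    fails.
    """
    if representation == "cm":
        config = config or CMConfig()
        fn: Callable[[AtomicCluster], FeatureVector] = lambda c: cm_feature(c, config)
    elif representation == "rdc":
        config = config or RDCConfig()
        fn = lambda c: rdc(c, config)
    else:
        raise ValueError(f"unknown representation {representation!r}")

    if len(clusters) == 0:
        warnings.warn("featurise_batch called with no clusters", stacklevel=2)
        return pd.DataFrame(), []

    rows, labels, failures = [], [], []
    for i, cluster in enumerate(clusters):
        try:
            fv = fn(cluster)
        except Exception as exc:  # noqa: BLE001 - collected, not fatal
            label = getattr(cluster, "label", "")
            failures.append(FeaturisationFailure(i, label, str(exc)))
            continue
        rows.append(fv.values)
        labels.append(cluster.label or str(i))
    if not rows:
        raise FeaturisationError(
            "all clusters failed featurisation: "
            + "; ".join(f"{f.label or f.index}: {f.error}" for f in failures)
        )
    df = pd.DataFrame(np.vstack(rows), index=labels)
    df.attrs["representation"] = representation
    df.attrs["config_hash"] = config_hash(config)
    return df, failures


def max_encoded_radius(cluster: AtomicCluster, n: int = 20) -> float:
    """Distance from the absorber to the N-th nearest atom (Angstrom).

    This is the largest radius a CM of dimension N can encode for this
    cluster; the absorber counts among the N.  Clusters with fewer than
    N sites report the distance to their farthest site.
    """
    d = np.sort(cluster.distances_to_absorber())
    return float(d[min(n, len(d)) - 1])


def required_cm_dimension(cluster: AtomicCluster, radius: float) -> int:
    """Number of sites within ``radius`` of the absorber, absorber included.

    The CM dimension needed to encode everything inside that sphere.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return int(np.sum(cluster.distances_to_absorber() <= radius))


def config_hash(config: CMConfig | RDCConfig | None) -> str:
    """Short stable hash of a featuriser configuration."""
    if config is None:
        return "none"
    d: dict = {"type": type(config).__name__}
    for key, val in vars(config).items():
        if isinstance(val, np.ndarray):
            val = [float(val[0]), float(val[-1]), len(val)]
        elif isinstance(val, Mapping):
            val = sorted((int(k), float(v)) for k, v in val.items())
        d[key] = val
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as delimited text with a metadata header."""
    path = Path(path)
    rep = df.attrs.get("representation", "unknown")
    chash = df.attrs.get("config_hash", "none")
    with open(path, "w") as fh:
        fh.write(f"# representation={rep} config_hash={chash}\n")
        df.to_csv(fh, index_label="label")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_feature_table`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh, index_col="label")
    df.columns = range(df.shape[1])
    meta = dict(
        kv.split("=", 1) for kv in header.lstrip("# ").split() if "=" in kv
    )
    df.attrs["representation"] = meta.get("representation", "unknown")
    df.attrs["config_hash"] = meta.get("config_hash", "none")
    return df
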