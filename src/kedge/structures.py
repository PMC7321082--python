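"""Atomic clusters centred on an X-ray absorption site.

The unit of work throughout this package is a finite, absorber-centred
cluster of atoms: the local environment whose geometry determines the
near-edge region of the K-edge absorption spectrum.  Clusters are read
and written as plain XYZ files; the absorbing atom is designated by an
``absorber=<index>`` key (0-based) on the comment line, falling back to
the first iron site when the key is absent.

All coordinates are in Angstrom, all charges in units of the elementary
charge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomSite",
    "AtomicCluster",
    "XYZParseError",
    "NoAbsorberError",
    "read_xyz",
    "write_xyz",
    "local_environment",
    "nearest_n",
    "cluster_from_cell",
    "read_manifest",
    "write_manifest",
    "symbol_to_z",
    "z_to_symbol",
]

# Element symbols indexed by atomic number (index 0 unused).
_SYMBOLS = (
    "X H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe "
    "Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn "
    "Sb Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W "
    "Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf "
    "Es Fm Md No Lr"
).split()
_Z_BY_SYMBOL = {s: z for z, s in enumerate(_SYMBOLS) if z > 0}

IRON = 26

#: Two sites closer than this (Angstrom) are treated as corrupt geometry.
MIN_SEPARATION = 0.1


class XYZParseError(ValueError):
    """Raised when an XYZ file cannot be parsed; message names the line."""


class NoAbsorberError(ValueError):
    """Raised when a cluster has no Fe site and no explicit absorber tag."""


def symbol_to_z(symbol: str) -> int:
    """Map an element symbol (case-insensitive) to its atomic number."""
    z = _Z_BY_SYMBOL.get(symbol.capitalize())
    if z is None:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return z


def z_to_symbol(z: int) -> str:
    if not 1 <= z < len(_SYMBOLS):
        raise ValueError(f"atomic number {z} out of range")
    return _SYMBOLS[z]


@dataclass(frozen=True)
class AtomSite:
    """One atom: nuclear charge ``z`` and Cartesian ``position`` (Angstrom)."""

    z: int
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position components must be finite")
        if self.z < 1:
            raise ValueError("atomic number must be >= 1")
        object.__setattr__(self, "position", pos)

    @property
    def symbol(self) -> str:
        return z_to_symbol(self.z)


@dataclass
class AtomicCluster:
    """An ordered set of atom sites with one designated absorbing atom.

    Invariants enforced at construction: the absorber index addresses an
    existing site and no two sites sit closer than :data:`MIN_SEPARATION`
    (a guard against corrupt or duplicated coordinates).
    """

    sites: list[AtomSite]
    absorber_index: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("cluster must contain at least one site")
        if not 0 <= self.absorber_index < len(self.sites):
            raise ValueError(
                f"absorber_index {self.absorber_index} out of range for "
                f"{len(self.sites)} sites"
            )
        pos = self.positions
        if len(self.sites) > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < MIN_SEPARATION:
                i, j = np.unravel_index(int(d.argmin()), d.shape)
                raise ValueError(
                    f"sites {i} and {j} are {d[i, j]:.4f} A apart "
                    f"(< {MIN_SEPARATION} A): degenerate geometry"
                )

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of Cartesian coordinates in Angstrom."""
        return np.array([s.position for s in self.sites], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        """(n,) array of nuclear charges."""
        return np.array([s.z for s in self.sites], dtype=float)

    @property
    def absorber(self) -> AtomSite:
        return self.sites[self.absorber_index]

    def distances_to_absorber(self) -> np.ndarray:
        return np.linalg.norm(
            self.positions - self.absorber.position, axis=1
        )


_ABSORBER_RE = re.compile(r"absorber=(\S+)")
_LABEL_RE = re.compile(r"label=(\S+)")


def read_xyz(path: str | Path) -> AtomicCluster:
    """Read an XYZ file into an :class:`AtomicCluster`.

    The comment line may carry ``absorber=<index>`` (0-based); otherwise
    the first Fe site is taken as the absorber.  Element fields may be
    symbols or atomic numbers.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: line 1: empty file")
    try:
        natoms = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(
            f"{path}: line 1: expected an atom count, got {lines[0]!r}"
        ) from None
    if len(lines) < 2 + natoms:
        raise XYZParseError(
            f"{path}: header declares {natoms} atoms but only "
            f"{max(len(lines) - 2, 0)} record lines are present"
        )
    comment = lines[1]
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) != natoms:
        raise XYZParseError(
            f"{path}: header declares {natoms} atoms but found "
            f"{len(records)} record lines"
        )

    sites: list[AtomSite] = []
    for i, line in enumerate(records):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(
                f"{path}: line {i + 3}: expected 'element x y z', got {line!r}"
            )
        try:
            z = int(parts[0])
        except ValueError:
            try:
                z = symbol_to_z(parts[0])
            except ValueError:
                raise XYZParseError(
                    f"{path}: line {i + 3}: unknown element {parts[0]!r}"
                ) from None
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(
                f"{path}: line {i + 3}: non-numeric coordinate in {line!r}"
            ) from None
        sites.append(AtomSite(z, np.array(xyz)))

    m = _ABSORBER_RE.search(comment)
    if m:
        try:
            absorber = int(m.group(1))
        except ValueError:
            raise XYZParseError(
                f"{path}: line 2: absorber index {m.group(1)!r} is not an integer"
            ) from None
        if not 0 <= absorber < natoms:
            raise XYZParseError(
                f"{path}: line 2: absorber index {absorber} out of range"
            )
    else:
        iron = [i for i, s in enumerate(sites) if s.z == IRON]
        if not iron:
            raise NoAbsorberError(
                f"{path}: no absorber= tag and no Fe site to default to"
            )
        absorber = iron[0]

    m = _LABEL_RE.search(comment)
    label = m.group(1) if m else path.stem
    return AtomicCluster(sites, absorber, label)


def write_xyz(cluster: AtomicCluster, path: str | Path) -> None:
    """Write a cluster as XYZ with the absorber tagged on the comment line."""
    path = Path(path)
    lines = [str(len(cluster))]
    label = f"label={cluster.label} " if cluster.label else ""
    lines.append(f"{label}absorber={cluster.absorber_index}")
    for s in cluster.sites:
        x, y, z = s.position
        lines.append(f"{s.symbol:<2s} {x: .8f} {y: .8f} {z: .8f}")
    path.write_text("\n".join(lines) + "\n")


def _ascending_distance_order(cluster: AtomicCluster) -> np.ndarray:
    """Site order by increasing distance to the absorber.

    Ties keep the original site order (stable sort), so selection is
    deterministic for symmetric geometries.
    """
    return np.argsort(cluster.distances_to_absorber(), kind="stable")


def _subcluster(cluster: AtomicCluster, order: Sequence[int]) -> AtomicCluster:
    sites = [cluster.sites[i] for i in order]
    absorber = list(order).index(cluster.absorber_index)
    return AtomicCluster(sites, absorber, cluster.label)


def local_environment(cluster: AtomicCluster, cutoff: float) -> AtomicCluster:
    """All sites within ``cutoff`` (Angstrom) of the absorber.

    The absorber is always retained; the result is ordered by ascending
    distance to the absorber with ties broken by original index.  A lone
    absorber is a valid single-site result.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = cluster.distances_to_absorber()
    order = [int(i) for i in _ascending_distance_order(cluster) if d[i] <= cutoff]
    return _subcluster(cluster, order)


def nearest_n(cluster: AtomicCluster, n: int) -> AtomicCluster:
    """The ``n`` sites nearest the absorber (absorber counted among them).

    Returned in ascending-distance order, ties broken by original index;
    if the cluster has fewer than ``n`` sites all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    order = _ascending_distance_order(cluster)[: min(n, len(cluster))]
    return _subcluster(cluster, [int(i) for i in order])


def cluster_from_cell(
    lattice: np.ndarray,
    fractional: np.ndarray,
    charges: Sequence[int],
    absorber_index: int,
    radius: float,
    label: str = "",
) -> AtomicCluster:
    """Expand a periodic cell into a finite cluster of at least ``radius``.

    Optional convenience for crystalline inputs: replicates the cell over
    enough lattice images that every atom within ``radius`` of the chosen
    absorber is present, then keeps that sphere.  ``lattice`` rows are the
    cell vectors (Angstrom); ``fractional`` holds fractional coordinates.
    """
    lattice = np.asarray(lattice, dtype=float)
    fractional = np.asarray(fractional, dtype=float) % 1.0
    if lattice.shape != (3, 3):
        raise ValueError("lattice must be 3x3 (rows = cell vectors)")
    cart = fractional @ lattice
    centre = cart[absorber_index]
    # enough images along each axis to cover the sphere
    heights = np.abs(np.linalg.det(lattice)) / np.array(
        [
            np.linalg.norm(np.cross(lattice[1], lattice[2])),
            np.linalg.norm(np.cross(lattice[2], lattice[0])),
            np.linalg.norm(np.cross(lattice[0], lattice[1])),
        ]
    )
    reps = np.ceil(radius / heights).astype(int) + 1
    sites = [AtomSite(charges[absorber_index], centre.copy())]
    for i, j, k in np.ndindex(*(2 * reps + 1)):
        shift = (np.array([i, j, k]) - reps) @ lattice
        for a, pos in enumerate(cart):
            p = pos + shift
            d = np.linalg.norm(p - centre)
            if d <= radius and d > 1e-9:
                sites.append(AtomSite(charges[a], p))
    return AtomicCluster(sites, 0, label)


def write_manifest(
    entries: Iterable[tuple[str, str]], path: str | Path
) -> None:
    """Write a cluster-collection manifest: one ``label<TAB>path`` per line."""
    path = Path(path)
    lines = ["# label\tpath"]
    lines += [f"{label}\t{p}" for label, p in entries]
    path.write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> list[tuple[str, str]]:
    """Read a manifest written by :func:`write_manifest`."""
    path = Path(path)
    entries = []
    for i, line in enumerate(path.read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {i + 1}: expected 'label<TAB>path'")
        entries.append((parts[0], parts[1]))
    return entries


def load_collection(manifest_path: str | Path) -> list[AtomicCluster]:
    """Load every cluster listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    clusters = []
    for label, rel in read_manifest(manifest_path):
        c = read_xyz(manifest_path.parent / rel)
        c.label = label
        clusters.append(c)
    return clusters
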