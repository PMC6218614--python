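"""Sensor montages and leadfields for a spherical conductor head model.

The electromagnetic forward problem maps a current dipole at a source
position to the potentials at the EEG electrodes; its solutions are the
columns of the leadfield matrix L (n channels × 3m, one column triple per
source node for the x/y/z unit dipoles).

The head is modelled as a homogeneous conducting sphere with an insulating
exterior.  For a current monopole of strength I at position b inside a
sphere of radius R and conductivity σ_c, the surface potential at electrode
r (|r| = R) has the closed form (Legendre expansion summed exactly)

    φ(r) = I/(4π σ_c R) · [ 2R/d + ln( 2R / (R − b·r/R + d) ) ] + const,

with d = |r − b|.  The dipole potential is the directional derivative with
respect to the source position,

    φ_dip(r) = 1/(4π σ_c) · q · [ 2(r − b)/d³ + (r/R + (r − b)/d) / (R·s) ],

where s = R − b·r/R + d and q is the dipole moment.  The additive constant
drops under the average reference applied to every generated leadfield.

Units: positions mm, dipole moments nA·m, potentials µV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .mesh import TriMesh

__all__ = [
    "SensorMontage",
    "SourceSpace",
    "Leadfield",
    "make_equidistant_montage",
    "spherical_leadfield",
    "dipole_potentials",
    "read_leadfield",
    "write_leadfield",
    "read_montage",
    "write_montage",
]

BRAIN_CONDUCTIVITY_S_PER_M = 0.33


@dataclass
class SensorMontage:
    labels: list[str]
    positions: np.ndarray  # (n, 3) mm
    head_radius: float     # mm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.positions):
            raise ValueError("label/position count mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("sensor labels must be unique")

    @property
    def n_sensors(self) -> int:
        return len(self.labels)


@dataclass
class SourceSpace:
    """Source positions (mesh vertices) with free dipole orientation."""

    positions: np.ndarray  # (m, 3) mm
    mesh: TriMesh | None = None
    free_orientation: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.mesh is not None and self.mesh.n_vertices != len(self.positions):
            raise ValueError("source count does not match mesh vertex count")

    @property
    def n_sources(self) -> int:
        return len(self.positions)


@dataclass
class Leadfield:
    """n×3m leadfield; columns grouped (x, y, z) per source, average reference."""

    matrix: np.ndarray
    labels: list[str]
    reference: str = "average"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] % 3:
            raise ValueError("leadfield must be n x 3m")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("label count does not match row count")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1] // 3


def make_equidistant_montage(
    n_sensors: int, head_radius: float = 85.0, polar_coverage: float = 130.0
) -> SensorMontage:
    """Quasi-equidistant electrode layout on a spherical cap.

    Sensors are placed along a Fibonacci (golden-angle) spiral over the cap
    spanning ``polar_coverage`` degrees from the vertex, which yields nearly
    uniform pairwise spacing for any sensor count.  Deterministic; no seed.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    if not 0 < polar_coverage <= 180:
        raise ValueError("polar_coverage must be in (0, 180] degrees")
    i = np.arange(n_sensors)
    z_min = np.cos(np.deg2rad(polar_coverage))
    z = 1.0 - (1.0 - z_min) * (i + 0.5) / n_sensors
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    pos = head_radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    labels = [f"E{k + 1}" for k in range(n_sensors)]
    return SensorMontage(labels, pos, head_radius)


def dipole_potentials(
    electrode_positions: np.ndarray,
    source_position: np.ndarray,
    head_radius: float,
    conductivity: float = BRAIN_CONDUCTIVITY_S_PER_M,
) -> np.ndarray:
    """(n, 3) matrix of channel potentials (µV) for unit x/y/z dipoles (nA·m).

    Implements the closed-form homogeneous-sphere dipole potential from the
    module docstring, without re-referencing.
    """
    re = np.asarray(electrode_positions, dtype=float) * 1e-3  # -> m
    b = np.asarray(source_position, dtype=float).ravel() * 1e-3
    R = head_radius * 1e-3
    if np.linalg.norm(b) >= R:
        raise ValueError("source lies on or outside the scalp sphere")
    diff = re - b                     # (n, 3)
    d = np.linalg.norm(diff, axis=1)  # (n,)
    s = R - (re @ b) / R + d          # (n,)
    grad = (
        2.0 * diff / d[:, None] ** 3
        + (re / R + diff / d[:, None]) / (R * s[:, None])
    )
    # q = 1 nA·m = 1e-9 A·m; potential in volts, reported in µV
    return grad / (4.0 * np.pi * conductivity) * 1e-9 * 1e6


def spherical_leadfield(
    montage: SensorMontage,
    source_space: SourceSpace,
    model: str = "homogeneous-sphere",
    conductivity: float = BRAIN_CONDUCTIVITY_S_PER_M,
) -> Leadfield:
    """Average-referenced leadfield of the homogeneous-sphere head model."""
    if model != "homogeneous-sphere":
        raise ValueError(f"unknown forward model {model!r}")
    radii = np.linalg.norm(source_space.positions, axis=1)
    if np.any(radii >= montage.head_radius):
        raise ValueError("all sources must lie strictly inside the scalp sphere")
    n, m = montage.n_sensors, source_space.n_sources
    L = np.empty((n, 3 * m))
    for j in range(m):
        L[:, 3 * j : 3 * j + 3] = dipole_potentials(
            montage.positions, source_space.positions[j], montage.head_radius, conductivity
        )
    L -= L.mean(axis=0, keepdims=True)  # average reference
    return Leadfield(L, list(montage.labels), reference="average")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_montage(montage: SensorMontage, path: str | Path) -> None:
    """Write 'label x y z' rows (mm); first line '# head_radius <mm>'."""
    lines = [f"# head_radius {float(montage.head_radius)!r}"]
    for lab, p in zip(montage.labels, montage.positions):
        lines.append(f"{lab} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_montage(path: str | Path) -> SensorMontage:
    labels, rows = [], []
    head_radius = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            t = line[1:].split()
            if len(t) == 2 and t[0] == "head_radius":
                head_radius = float(t[1])
            continue
        t = line.split()
        labels.append(t[0])
        rows.append([float(x) for x in t[1:4]])
    pos = np.array(rows)
    if head_radius is None:
        head_radius = float(np.linalg.norm(pos, axis=1).mean())
    return SensorMontage(labels, pos, head_radius)


def write_leadfield(L: Leadfield, path: str | Path) -> None:
    """Text ('n m' header + rows) for .txt, HDF5 datasets otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("leadfield", data=L.matrix)
            f.create_dataset("labels", data=np.array(L.labels, dtype="S"))
            f.attrs["reference"] = L.reference
        return
    n, m = L.n_channels, L.n_sources
    lines = [f"{n} {m}"]
    lines += [" ".join(repr(float(x)) for x in row) for row in L.matrix]
    lines += ["# labels " + " ".join(L.labels)]
    path.write_text("\n".join(lines) + "\n")


def read_leadfield(path: str | Path) -> Leadfield:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            mat = f["leadfield"][()]
            labels = [x.decode() for x in f["labels"][()]]
            ref = f.attrs.get("reference", "average")
        return Leadfield(mat, labels, reference=str(ref))
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError("no header: empty leadfield file")
    header = lines[0].split()
    try:
        n, m = int(header[0]), int(header[1])
    except (ValueError, IndexError) as exc:
        raise ValueError("no header: first line must be 'n m'") from exc
    data_lines = [ln for ln in lines[1:] if not ln.lstrip().startswith("#")]
    if len(data_lines) != n:
        raise ValueError(f"header claims {n} rows, file has {len(data_lines)}")
    mat = np.array([[float(x) for x in ln.split()] for ln in data_lines])
    if mat.shape[1] != 3 * m:
        raise ValueError(f"header claims {3 * m} columns, file has {mat.shape[1]}")
    labels = [f"E{k + 1}" for k in range(n)]
    for ln in lines[1:]:
        t = ln.split()
        if t[:2] == ["#", "labels"] and len(t) == n + 2:
            labels = t[2:]
    return Leadfield(mat, labels)
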