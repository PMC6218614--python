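"""Comparison measures for source reconstructions.

Residual variance RV = Σ(b_i − b̂_i)² / Σ b_i² and goodness of fit
GOF = 100·(1 − RV) quantify how well the reconstructed topography explains
the data.  Solution similarity applies the same quadratic form to two
max-normalized source-power vectors (0 % ⇔ identical; values above 100 %
occur).  Localization measures operate on the 50 %-masked power image:
activity strictly below half the maximum is zeroed, and the source location
is summarized either by the power-weighted center of mass (COM) or by the
node of maximal amplitude (MA).  Depth is the distance to the nearest
sensor; a positive depth shift means the simulated source was deeper than
the estimate.  The local-maxima count (nodes strictly above every 1-ring
neighbour) proxies false-positive blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .forward import SensorMontage
from .mesh import TriMesh

__all__ = [
    "MetricsResult",
    "residual_variance",
    "goodness_of_fit",
    "solution_similarity",
    "node_power",
    "threshold_mask",
    "center_of_mass",
    "max_amplitude_location",
    "localization_error",
    "source_depth",
    "depth_shift",
    "count_local_maxima",
    "evaluate_estimate",
]


def residual_variance(b: np.ndarray, b_hat: np.ndarray) -> float:
    """RV = Σ(b_i − b̂_i)² / Σ b_i²."""
    b = np.asarray(b, dtype=float).ravel()
    b_hat = np.asarray(b_hat, dtype=float).ravel()
    if b.shape != b_hat.shape:
        raise ValueError("length mismatch")
    denom = float(np.sum(b**2))
    if denom == 0:
        raise ZeroDivisionError("reference data is all zeros")
    return float(np.sum((b - b_hat) ** 2) / denom)


def goodness_of_fit(b: np.ndarray, b_hat: np.ndarray) -> float:
    """GOF = 100·(1 − RV) in percent; negative when RV > 1."""
    return 100.0 * (1.0 - residual_variance(b, b_hat))


def solution_similarity(power_ref: np.ndarray, power_test: np.ndarray) -> float:
    """Deviation (%) between two max-normalized power vectors; 0 ⇔ identical."""
    ref = np.asarray(power_ref, dtype=float).ravel()
    test = np.asarray(power_test, dtype=float).ravel()
    if ref.shape != test.shape:
        raise ValueError("length mismatch")
    denom = float(np.sum(ref**2))
    if denom == 0:
        raise ZeroDivisionError("reference power is all zeros")
    return float(100.0 * np.sum((ref - test) ** 2) / denom)


def node_power(estimate: np.ndarray, amplitude: bool = False) -> np.ndarray:
    """Max-normalized per-node power from a 3m moment vector.

    Power is the squared norm of each node's (x, y, z) moment; with
    ``amplitude=True`` the norm itself is used instead.  An all-zero
    estimate maps to all zeros.
    """
    j = np.asarray(estimate, dtype=float).ravel()
    if j.size % 3:
        raise ValueError("estimate length must be a multiple of 3")
    p = np.sum(j.reshape(-1, 3) ** 2, axis=1)
    if amplitude:
        p = np.sqrt(p)
    mx = p.max() if p.size else 0.0
    return p / mx if mx > 0 else p


def threshold_mask(power: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Zero entries strictly below ``fraction`` of the maximum (ties kept)."""
    p = np.asarray(power, dtype=float).copy()
    if p.size == 0:
        return p
    cut = fraction * p.max()
    p[p < cut] = 0.0
    return p


def center_of_mass(positions: np.ndarray, masked_power: np.ndarray) -> np.ndarray:
    """Power-weighted mean position over the masked support."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    w = np.asarray(masked_power, dtype=float).ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero mask: center of mass undefined")
    return (w[:, None] * pos).sum(axis=0) / total


def max_amplitude_location(positions: np.ndarray, power: np.ndarray) -> tuple[int, np.ndarray]:
    """Argmax node and its position; ties broken by the lowest index."""
    p = np.asarray(power, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty power vector")
    idx = int(np.argmax(p))
    return idx, np.asarray(positions, dtype=float).reshape(-1, 3)[idx]


def localization_error(est_point: np.ndarray, true_point: np.ndarray) -> float:
    """Euclidean distance (mm) between estimated and simulated location."""
    return float(np.linalg.norm(np.asarray(est_point, float) - np.asarray(true_point, float)))


def source_depth(point: np.ndarray, montage: SensorMontage) -> float:
    """Distance (mm) from a point to the nearest sensor."""
    if montage.n_sensors == 0:
        raise ValueError("empty montage")
    return float(np.min(np.linalg.norm(montage.positions - np.asarray(point, float), axis=1)))


def depth_shift(depth_sim: float, depth_est: float) -> float:
    """Signed depth_sim − depth_est; positive ⇔ simulated source was deeper."""
    return float(depth_sim) - float(depth_est)


def count_local_maxima(mesh: TriMesh, power: np.ndarray) -> int:
    """Nodes whose amplitude strictly exceeds every 1-ring neighbour."""
    p = np.asarray(power, dtype=float).ravel()
    if p.size != mesh.n_vertices:
        raise ValueError("power length does not match mesh vertex count")
    count = 0
    for i in range(mesh.n_vertices):
        nbrs = mesh.neighbors(i)
        if len(nbrs) and np.all(p[i] > p[nbrs]):
            count += 1
    return count


@dataclass
class MetricsResult:
    """One full row of comparison measures for a single reconstruction."""

    localization_error_com: float
    localization_error_ma: float
    depth_sim: float
    depth_est_com: float
    depth_est_ma: float
    depth_shift_com: float
    depth_shift_ma: float
    n_local_maxima: int
    rv: float
    gof: float
    similarity_to_reference: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_estimate(
    estimate_j: np.ndarray,
    mesh: TriMesh,
    montage: SensorMontage,
    true_position: np.ndarray,
    b: np.ndarray,
    b_hat: np.ndarray,
    reference_power: np.ndarray | None = None,
) -> MetricsResult:
    """Compute every comparison measure for one reconstructed dataset."""
    power = node_power(estimate_j)
    masked = threshold_mask(power)
    com = center_of_mass(mesh.vertices, masked)
    _, ma = max_amplitude_location(mesh.vertices, masked)
    d_sim = source_depth(true_position, montage)
    d_com = source_depth(com, montage)
    d_ma = source_depth(ma, montage)
    rv = residual_variance(b, b_hat)
    sim = None
    if reference_power is not None:
        sim = solution_similarity(reference_power, power)
    return MetricsResult(
        localization_error_com=localization_error(com, true_position),
        localization_error_ma=localization_error(ma, true_position),
        depth_sim=d_sim,
        depth_est_com=d_com,
        depth_est_ma=d_ma,
        depth_shift_com=depth_shift(d_sim, d_com),
        depth_shift_ma=depth_shift(d_sim, d_ma),
        n_local_maxima=count_local_maxima(mesh, power),
        rv=rv,
        gof=100.0 * (1.0 - rv),
        similarity_to_reference=sim,
    )
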