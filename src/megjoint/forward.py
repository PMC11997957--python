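"""Analytic spherical-conductor MEG forward model.

The magnetic field of a current dipole inside a spherically symmetric
conductor has a closed form (the Sarvas formula); it depends only on the
conductor center, is exactly zero for radially oriented dipoles, and
needs no conductivity profile.  One fixed tangential dipole orientation
per source vertex keeps the eLORETA and MWE solvers on the same scalar
unknowns.

Positions are in mm at the API surface and converted to meters
internally, so leadfields come out in T/(A·m).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import Mesh

__all__ = [
    "SensorArray",
    "Leadfield",
    "sarvas_field",
    "helmet_sensors",
    "tangential_orientations",
    "build_leadfield",
    "jitter_subject",
]

_MU0_4PI = 1e-7  # T·m/A


@dataclass
class SensorArray:
    """Magnetometer array: positions (mm) and unit pickup orientations."""

    positions: np.ndarray  # (N, 3) mm
    orientations: np.ndarray  # (N, 3) unit vectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensor orientations must be unit-norm")

    @property
    def n_sensors(self) -> int:
        return len(self.positions)

    def to_hdf5(self, group) -> None:
        group.create_dataset("positions", data=self.positions)
        group.create_dataset("orientations", data=self.orientations)

    @classmethod
    def from_hdf5(cls, group) -> "SensorArray":
        return cls(group["positions"][()], group["orientations"][()])


@dataclass
class Leadfield:
    """N×P gain matrix in T/(A·m) with its construction context.

    The sensor array, conductor center and per-vertex source positions /
    orientations are kept so that per-subject jitter can recompute
    columns from perturbed geometry.
    """

    matrix: np.ndarray  # (N, P)
    sensors: SensorArray
    sphere_center: np.ndarray
    source_positions: np.ndarray  # (P, 3) mm, possibly jittered
    source_orientations: np.ndarray  # (P, 3) unit tangential vectors

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.sphere_center = np.asarray(self.sphere_center, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("leadfield contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def sarvas_field(
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    sensor_position: np.ndarray,
    sphere_center: np.ndarray = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Magnetic field (T) of a current dipole in a spherical conductor.

    Parameters
    ----------
    dipole_position, sensor_position, sphere_center : (3,) arrays, mm.
    dipole_moment : (3,) array, A·m.

    The sensor must lie strictly outside the dipole's radius from the
    sphere center (the closed form is valid outside the conductor).
    """
    c = np.asarray(sphere_center, dtype=float)
    r0 = (np.asarray(dipole_position, dtype=float) - c) * 1e-3  # m
    r = (np.asarray(sensor_position, dtype=float) - c) * 1e-3
    q = np.asarray(dipole_moment, dtype=float)

    R = np.linalg.norm(r)
    if R <= np.linalg.norm(r0):
        raise ValueError("sensor must lie strictly outside the dipole radius")
    if np.linalg.norm(r0) == 0.0:
        raise ValueError("dipole must not sit at the sphere center")

    a_vec = r - r0
    a = np.linalg.norm(a_vec)
    ar = float(a_vec @ r)
    F = a * (R * a + R**2 - float(r0 @ r))
    gradF = (a**2 / R + ar / a + 2.0 * a + 2.0 * R) * r - (a + 2.0 * R + ar / a) * r0
    qxr0 = np.cross(q, r0)
    B = _MU0_4PI / F**2 * (F * qxr0 - float(qxr0 @ r) * gradF)
    return B


def helmet_sensors(
    n_sensors: int = 64,
    helmet_radius: float = 120.0,
    z_min_fraction: float = -0.25,
    center: np.ndarray = (0.0, 0.0, 0.0),
) -> SensorArray:
    """Radially oriented magnetometers on a spherical helmet cap.

    Sensors are placed by a Fibonacci lattice on the cap
    ``z >= z_min_fraction * helmet_radius`` so the array covers the top
    and the posterior surface of the head surrogate.
    """
    c = np.asarray(center, dtype=float)
    i = np.arange(n_sensors)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    # z uniform on the cap
    z = z_min_fraction + (1.0 - z_min_fraction) * (i + 0.5) / n_sensors
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = golden * i
    dirs = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return SensorArray(positions=c + helmet_radius * dirs, orientations=dirs)


def tangential_orientations(
    positions: np.ndarray, sphere_center: np.ndarray
) -> np.ndarray:
    """Deterministic unit tangential orientation at each source position.

    The orientation is ``normalize(z_hat × radial)``, falling back to
    ``normalize(x_hat × radial)`` near the poles where the first cross
    product degenerates.  Tangential with respect to the conductor
    center, so every column of the resulting leadfield is non-silent.
    """
    radial = np.asarray(positions, dtype=float) - np.asarray(sphere_center, dtype=float)
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    z_hat = np.array([0.0, 0.0, 1.0])
    x_hat = np.array([1.0, 0.0, 0.0])
    t = np.cross(np.broadcast_to(z_hat, radial.shape), radial)
    norms = np.linalg.norm(t, axis=1)
    degenerate = norms < 1e-6
    if np.any(degenerate):
        t[degenerate] = np.cross(x_hat, radial[degenerate])
        norms = np.linalg.norm(t, axis=1)
    return t / norms[:, None]


def _fields_batch(
    source_positions: np.ndarray,
    source_orientations: np.ndarray,
    sensors: SensorArray,
    sphere_center: np.ndarray,
) -> np.ndarray:
    """Vectorized Sarvas evaluation -> (N, P) sensor-projected gains."""
    c = np.asarray(sphere_center, dtype=float)
    r0 = (source_positions - c) * 1e-3  # (P, 3)
    r = (sensors.positions - c) * 1e-3  # (N, 3)
    q = source_orientations  # (P, 3), unit A·m

    R = np.linalg.norm(r, axis=1)  # (N,)
    a_vec = r[:, None, :] - r0[None, :, :]  # (N, P, 3)
    a = np.linalg.norm(a_vec, axis=2)  # (N, P)
    ar = np.einsum("npk,nk->np", a_vec, r)
    r0r = r @ r0.T  # (N, P)
    F = a * (R[:, None] * a + R[:, None] ** 2 - r0r)
    coef_r = a**2 / R[:, None] + ar / a + 2.0 * a + 2.0 * R[:, None]
    coef_r0 = a + 2.0 * R[:, None] + ar / a
    qxr0 = np.cross(q, r0)  # (P, 3)
    qxr0_r = r @ qxr0.T  # (N, P)
    # B·n for radial sensors: project each term on sensor orientation
    n_dot_r = np.einsum("nk,nk->n", sensors.orientations, r)  # (N,)
    n_dot_r0 = sensors.orientations @ r0.T  # (N, P)
    n_dot_qxr0 = sensors.orientations @ qxr0.T  # (N, P)
    gradF_dot_n = coef_r * n_dot_r[:, None] - coef_r0 * n_dot_r0
    return _MU0_4PI / F**2 * (F * n_dot_qxr0 - qxr0_r * gradF_dot_n)


def build_leadfield(
    mesh: Mesh,
    sensors: SensorArray,
    sphere_center: np.ndarray = (0.0, 0.0, 0.0),
) -> Leadfield:
    """Leadfield for one fixed tangential dipole per mesh vertex.

    Column ``i`` is the sensor-orientation projection of the Sarvas
    field of a unit (1 A·m) dipole at vertex ``i``.
    """
    center = np.asarray(sphere_center, dtype=float)
    dists = np.linalg.norm(sensors.positions - center, axis=1)
    src_r = np.linalg.norm(mesh.vertices - center, axis=1)
    if dists.min() <= src_r.max():
        raise ValueError("sensors must lie strictly outside the source sphere")
    ori = tangential_orientations(mesh.vertices, center)
    L = _fields_batch(mesh.vertices, ori, sensors, center)
    return Leadfield(L, sensors, center, mesh.vertices.copy(), ori)


def jitter_subject(
    leadfield: Leadfield,
    mesh: Mesh,
    seed: int,
    position_jitter_mm: float = 2.0,
    gain_jitter_fraction: float = 0.1,
) -> Leadfield:
    """Per-subject leadfield with tangential position and gain jitter.

    Vertex positions are perturbed tangentially (with respect to the
    conductor center) by at most ``position_jitter_mm`` and the columns
    recomputed; each column is then scaled by ``1 + g`` with
    ``g ~ U(-gain_jitter_fraction, +gain_jitter_fraction)``.  With both
    jitters zero the input is returned unchanged.  Deterministic given
    the seed.
    """
    if position_jitter_mm < 0 or gain_jitter_fraction < 0:
        raise ValueError("jitters must be non-negative")
    if position_jitter_mm == 0 and gain_jitter_fraction == 0:
        return leadfield

    rng = np.random.default_rng(seed)
    pos = leadfield.source_positions.copy()
    center = leadfield.sphere_center
    if position_jitter_mm > 0:
        radial = pos - center
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        raw = rng.standard_normal(pos.shape)
        tang = raw - np.einsum("pk,pk->p", raw, radial)[:, None] * radial
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        mags = rng.uniform(0.0, position_jitter_mm, size=len(pos))
        pos = pos + mags[:, None] * tang
    ori = tangential_orientations(pos, center)
    L = _fields_batch(pos, ori, leadfield.sensors, center)
    if gain_jitter_fraction > 0:
        g = rng.uniform(-gain_jitter_fraction, gain_jitter_fraction, size=L.shape[1])
        L = L * (1.0 + g)[None, :]
    return replace(
        leadfield, matrix=L, source_positions=pos, source_orientations=ori
    )
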