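"""Synthetic multi-subject retinotopy experiments with known ground truth.

Generates the kind of data a multifocal retinotopic-mapping study
produces after sensor-level preprocessing: per-subject leadfields with
anatomical jitter, noise covariances, and separated evoked responses
(one per stimulus region) peaking in the 60-100 ms window.  The
stimulus is a dartboard of ``rings x wedges`` regions; regions touching
the vertical meridian activate both hemispheres, all others only the
hemisphere contralateral to their visual hemifield.

Targets live in a posterior "V1 surrogate" patch on each hemisphere:
eccentricity maps to geodesic distance from an occipital-pole anchor,
polar angle to direction around it.  Evoked amplitudes are calibrated
so the realized amplitude SNR (whitened-RMS estimator, 0-300 ms window)
matches a requested target, emulating a study-grade SNR near 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.linalg
import scipy.optimize

from .eloreta import _whitener
from .forward import Leadfield, SensorArray, build_leadfield, helmet_sensors, jitter_subject
from .mesh import LEFT, RIGHT, Mesh, build_template_space, geodesic_distances

__all__ = [
    "ConfigurationError",
    "StimulusRegion",
    "StimulusLayout",
    "GroundTruth",
    "SubjectModel",
    "ExperimentConfig",
    "Experiment",
    "make_stimulus_layout",
    "make_noise_cov",
    "place_targets",
    "simulate_evoked",
    "simulate_experiment",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration cannot be realized."""


@dataclass(frozen=True)
class StimulusRegion:
    """One dartboard sector (1-based ring and wedge indices)."""

    index: int
    ring: int
    wedge: int
    inner_deg: float
    outer_deg: float
    angle_start_deg: float
    angle_end_deg: float
    bilateral: bool

    @property
    def center_angle_deg(self) -> float:
        return 0.5 * (self.angle_start_deg + self.angle_end_deg)


@dataclass
class StimulusLayout:
    regions: list[StimulusRegion]
    rings: int
    wedges: int

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def make_stimulus_layout(
    rings: int = 3,
    wedges: int = 8,
    radii_deg: tuple[float, ...] = (0.5, 2.3, 4.7, 8.4),
) -> StimulusLayout:
    """Dartboard stimulus layout of ``rings x wedges`` regions.

    ``radii_deg`` gives the inner radius followed by the outer radius of
    each ring (so its length is ``rings + 1``) and must be strictly
    increasing.  Polar angle is measured counterclockwise from the
    right horizontal meridian; wedges whose angular span touches the
    vertical meridian (90 or 270 degrees) are flagged bilateral.
    """
    radii = tuple(float(r) for r in radii_deg)
    if len(radii) != rings + 1:
        raise ValueError("radii_deg must have length rings + 1")
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii_deg must be strictly increasing")
    span = 360.0 / wedges
    regions = []
    idx = 0
    for ring in range(1, rings + 1):
        for wedge in range(1, wedges + 1):
            a0 = span * (wedge - 1)
            a1 = span * wedge
            bilateral = any(
                a0 <= meridian <= a1 for meridian in (90.0, 270.0)
            )
            regions.append(
                StimulusRegion(
                    index=idx,
                    ring=ring,
                    wedge=wedge,
                    inner_deg=radii[ring - 1],
                    outer_deg=radii[ring],
                    angle_start_deg=a0,
                    angle_end_deg=a1,
                    bilateral=bilateral,
                )
            )
            idx += 1
    return StimulusLayout(regions=regions, rings=rings, wedges=wedges)


def _hemifield_hemispheres(region: StimulusRegion) -> tuple[int, ...]:
    """Target hemisphere(s): contralateral to the stimulus hemifield."""
    if region.bilateral:
        return (LEFT, RIGHT)
    c = region.center_angle_deg % 360.0
    in_left_field = 90.0 < c < 270.0
    return (RIGHT,) if in_left_field else (LEFT,)


@dataclass
class GroundTruth:
    """Template-level target vertices and source parameters.

    ``targets`` maps ``(region_index, hemisphere)`` to a template vertex
    id.  ``amplitude`` is the nominal dipole amplitude in A·m used when
    no SNR calibration is requested; ``peak_time_ms`` the nominal
    response peak.
    """

    targets: dict[tuple[int, int], int]
    anchors: dict[int, int]  # hemisphere -> occipital pole anchor vertex
    amplitude: float = 2e-8
    peak_time_ms: float = 83.0

    def region_targets(self, region: StimulusRegion) -> list[tuple[int, int]]:
        return [
            (h, self.targets[(region.index, h)])
            for h in _hemifield_hemispheres(region)
        ]

    def neighbor_distances(self, mesh: Mesh, region_index: int, hemi: int
                           ) -> tuple[float, float]:
        """Mean and min geodesic distance from one target to the other
        same-hemisphere targets (the crowding characterization of the
        target constellation)."""
        v0 = self.targets[(region_index, hemi)]
        others = [
            v for (ri, h), v in self.targets.items()
            if h == hemi and ri != region_index and v != v0
        ]
        d = geodesic_distances(mesh, v0)[others]
        return float(np.mean(d)), float(np.min(d))


def _tangent_basis(radial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z_hat = np.array([0.0, 0.0, 1.0])
    t1 = np.cross(z_hat, radial)
    n = np.linalg.norm(t1)
    if n < 1e-6:
        t1 = np.cross(np.array([1.0, 0.0, 0.0]), radial)
        n = np.linalg.norm(t1)
    t1 /= n
    t2 = np.cross(radial, t1)
    return t1, t2


def place_targets(
    mesh: Mesh,
    layout: StimulusLayout,
    seed: int = 0,
    ring_distances_mm: tuple[float, ...] = (10.0, 20.0, 30.0),
    patch_radius_mm: float = 40.0,
    pole_direction: tuple[float, float, float] = (0.0, -1.0, -0.35),
    angle_jitter_deg: float = 0.0,
) -> GroundTruth:
    """Place retinotopic target vertices in a posterior patch per hemisphere.

    Eccentricity ring ``k`` maps to geodesic distance
    ``ring_distances_mm[k-1]`` from the hemisphere's occipital-pole
    anchor; the wedge's visual-field polar angle maps to the direction
    around the anchor.  Unilateral regions get one target on the
    contralateral hemisphere, bilateral regions one target per
    hemisphere.  Deterministic given the seed (used only for the
    optional angular jitter).
    """
    if len(ring_distances_mm) < layout.rings:
        raise ConfigurationError("need one ring distance per eccentricity ring")
    if max(ring_distances_mm[: layout.rings]) > patch_radius_mm:
        raise ConfigurationError(
            "outermost ring distance exceeds the patch radius: "
            "the target patch is too small for this layout"
        )
    rng = np.random.default_rng(seed)
    dirn = np.asarray(pole_direction, dtype=float)
    dirn /= np.linalg.norm(dirn)

    anchors: dict[int, int] = {}
    frames: dict[int, tuple[np.ndarray, float, np.ndarray, np.ndarray, np.ndarray]] = {}
    for hemi in (LEFT, RIGHT):
        vids = mesh.hemisphere_vertices(hemi)
        verts = mesh.vertices[vids]
        center = verts.mean(axis=0)
        radius = float(np.mean(np.linalg.norm(verts - center, axis=1)))
        pole_point = center + radius * dirn
        anchor_local = int(np.argmin(np.linalg.norm(verts - pole_point, axis=1)))
        anchor = int(vids[anchor_local])
        anchors[hemi] = anchor
        rho = (mesh.vertices[anchor] - center)
        rho /= np.linalg.norm(rho)
        t1, t2 = _tangent_basis(rho)
        frames[hemi] = (center, radius, rho, t1, t2)
        # on coarse meshes neighbouring targets may share a vertex; guard
        # only against patches too degenerate to express the rings at all
        n_patch = int(np.sum(geodesic_distances(mesh, anchor)[vids] <= patch_radius_mm))
        if n_patch < layout.rings + 1:
            raise ConfigurationError(
                f"patch has only {n_patch} vertices for {layout.rings} "
                f"eccentricity rings: the target patch is too small"
            )

    targets: dict[tuple[int, int], int] = {}
    for region in layout.regions:
        d = float(ring_distances_mm[region.ring - 1])
        for hemi in _hemifield_hemispheres(region):
            center, radius, rho, t1, t2 = frames[hemi]
            theta = np.deg2rad(region.center_angle_deg)
            if angle_jitter_deg > 0:
                theta += np.deg2rad(rng.normal(0.0, angle_jitter_deg))
            u = np.cos(theta) * t1 + np.sin(theta) * t2
            alpha = d / radius  # arc length -> central angle
            p = center + radius * (np.cos(alpha) * rho + np.sin(alpha) * u)
            vids = mesh.hemisphere_vertices(hemi)
            local = int(np.argmin(np.linalg.norm(mesh.vertices[vids] - p, axis=1)))
            targets[(region.index, hemi)] = int(vids[local])
    return GroundTruth(targets=targets, anchors=anchors)


def make_noise_cov(
    n_sensors: int,
    seed: int,
    noise_std: float = 1e-13,
    lowrank: int = 8,
) -> np.ndarray:
    """Diagonal-plus-low-rank SPD noise covariance (T^2).

    Stands in for a resting-state covariance: heterogeneous sensor
    variances plus a few shared spatial noise modes.
    """
    rng = np.random.default_rng(seed)
    diag = rng.uniform(0.5, 1.5, size=n_sensors)
    A = rng.standard_normal((n_sensors, lowrank))
    cov = np.diag(diag) + 0.5 * (A @ A.T) / lowrank
    return noise_std**2 * cov


def _source_vector(
    mesh: Mesh,
    target_vertices: list[int],
    neighbor_leakage: float,
) -> np.ndarray:
    x = np.zeros(mesh.n_vertices)
    adj = mesh.adjacency()
    for v in target_vertices:
        x[v] += 1.0
        if neighbor_leakage > 0:
            nbrs = adj.indices[adj.indptr[v]: adj.indptr[v + 1]]
            x[nbrs] += neighbor_leakage
    return x


def simulate_evoked(
    leadfield: Leadfield,
    noise_cov: np.ndarray,
    mesh: Mesh,
    truth: GroundTruth,
    region: StimulusRegion,
    snr_target: float | None = 2.0,
    peak_time_ms: float | None = None,
    peak_time_jitter_ms: float = 0.0,
    amplitude_jitter_fraction: float = 0.0,
    seed: int = 0,
    noise_scale: float = 1.0,
    pulse_sigma_ms: float = 10.0,
    neighbor_leakage: float = 0.3,
    times: np.ndarray | None = None,
    target_vertices: list[int] | None = None,
    snr_window: tuple[float, float] = (0.0, 300.0),
) -> tuple[np.ndarray, dict]:
    """Simulate one region's evoked response ``Y = L x(t) + noise``.

    The source time course is a Gaussian pulse (width
    ``pulse_sigma_ms``) at the region's target vertex (or vertices, for
    bilateral regions) with fractional leakage to 1-ring neighbours.
    When ``snr_target`` is given, the source amplitude is calibrated so
    the whitened-RMS amplitude SNR over ``snr_window`` equals
    ``snr_target`` (times an optional per-trial jitter factor); with
    ``snr_target=None`` the nominal ``truth.amplitude`` is used
    directly.  Deterministic given the seed.

    Returns the ``(N, T)`` evoked array and an info dict with the
    realized amplitude, peak time and target vertices.
    """
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.arange(-50.0, 451.0, 1.0)
    peak = float(peak_time_ms if peak_time_ms is not None else truth.peak_time_ms)
    if peak_time_jitter_ms > 0:
        peak += float(rng.uniform(-peak_time_jitter_ms, peak_time_jitter_ms))
    if target_vertices is None:
        target_vertices = [v for _, v in truth.region_targets(region)]

    x = _source_vector(mesh, target_vertices, neighbor_leakage)
    pulse = np.exp(-0.5 * ((times - peak) / pulse_sigma_ms) ** 2)
    signal = (leadfield.matrix @ x)[:, None] * pulse[None, :]

    n = leadfield.matrix.shape[0]
    if noise_scale > 0:
        chol = scipy.linalg.cholesky(noise_cov, lower=True)
        noise = noise_scale * (chol @ rng.standard_normal((n, len(times))))
    else:
        noise = np.zeros((n, len(times)))

    if snr_target is None:
        amplitude = truth.amplitude
        if amplitude_jitter_fraction > 0:
            amplitude *= 1.0 + rng.uniform(
                -amplitude_jitter_fraction, amplitude_jitter_fraction
            )
    else:
        goal = snr_target
        if amplitude_jitter_fraction > 0:
            goal *= 1.0 + rng.uniform(
                -amplitude_jitter_fraction, amplitude_jitter_fraction
            )
        W = _whitener(noise_cov, unit_diag=False)
        mask = (times >= snr_window[0]) & (times <= snr_window[1])
        zS = W @ signal[:, mask]
        zE = W @ noise[:, mask]

        def realized(c: float) -> float:
            return float(np.mean(np.sqrt(np.mean((c * zS + zE) ** 2, axis=0))))

        base = realized(0.0)
        if noise_scale == 0:
            amplitude = goal / realized(1.0)
        else:
            if goal <= base:
                raise ValueError(
                    f"snr_target {goal:.3g} is at or below the noise floor "
                    f"{base:.3g} of this realization"
                )
            hi = 1.0
            while realized(hi) < goal:
                hi *= 10.0
                if hi > 1e12:
                    raise RuntimeError("SNR calibration bracket failed")
            amplitude = float(
                scipy.optimize.brentq(lambda c: realized(c) - goal, 0.0, hi)
            )

    Y = amplitude * signal + noise
    info = {
        "amplitude": amplitude,
        "peak_time_ms": peak,
        "target_vertices": list(target_vertices),
        "region_index": region.index,
    }
    return Y, info


@dataclass
class SubjectModel:
    """One simulated subject: forward model, noise model and evoked data."""

    subject_id: int
    leadfield: Leadfield
    noise_cov: np.ndarray
    evoked: dict[int, np.ndarray]  # region index -> (N, T)
    times: np.ndarray
    info: dict = field(default_factory=dict)


@dataclass
class ExperimentConfig:
    """Generator defaults emulating the study conditions.

    The stimulus bookkeeping (258 flashes per run, 7 runs), the 3x8
    dartboard, the -50..450 ms epoch, the 60-100 ms peak window with a
    nominal 83 ms peak, and an amplitude SNR of 2 are the study
    conditions; jitters and attenuation model inter-subject anatomical
    and functional variability.
    """

    subdivisions: int = 3
    radius_mm: float = 70.0
    hemisphere_gap_mm: float = 60.0
    n_sensors: int = 64
    helmet_radius_mm: float = 120.0
    snr: float | None = 2.0
    noise_scale: float = 1.0
    noise_std: float = 1e-13
    pulse_sigma_ms: float = 10.0
    neighbor_leakage: float = 0.3
    peak_time_ms: float = 83.0
    subject_peak_jitter_ms: float = 5.0
    region_peak_jitter_ms: float = 3.0
    amplitude_jitter_fraction: float = 0.1
    position_jitter_mm: float = 6.0
    gain_jitter_fraction: float = 0.15
    target_jitter_mm: float = 8.0
    eccentricity_attenuation: tuple[float, ...] | None = (1.0, 0.8, 0.6)
    ring_distances_mm: tuple[float, ...] = (10.0, 20.0, 30.0)
    patch_radius_mm: float = 40.0
    tmin_ms: float = -50.0
    tmax_ms: float = 450.0
    sfreq: float = 1000.0
    flashes_per_run: int = 258
    n_runs: int = 7

    def time_axis(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        return np.arange(self.tmin_ms, self.tmax_ms + 0.5 * step, step)


@dataclass
class Experiment:
    """A complete simulated multi-subject experiment."""

    mesh: Mesh
    sensors: SensorArray
    layout: StimulusLayout
    truth: GroundTruth
    subjects: list[SubjectModel]
    config: ExperimentConfig
    metadata: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def simulate_experiment(
    n_subjects: int,
    layout: StimulusLayout | None = None,
    config: ExperimentConfig | None = None,
    master_seed: int = 0,
) -> Experiment:
    """Generate a full multi-subject experiment, reproducible from one seed.

    Every subject gets a jittered leadfield, an individual noise
    covariance, per-subject jittered target vertices (within
    ``target_jitter_mm`` geodesically of the shared template targets)
    and one evoked response per stimulus region.  Experiment metadata
    records the flash bookkeeping (flashes/run x runs = flashes per
    region) and every derived seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or ExperimentConfig()
    layout = layout or make_stimulus_layout()
    rng = np.random.default_rng(master_seed)

    mesh = build_template_space(
        config.subdivisions, config.radius_mm, config.hemisphere_gap_mm
    )
    sensors = helmet_sensors(config.n_sensors, config.helmet_radius_mm)
    L0 = build_leadfield(mesh, sensors)
    truth = place_targets(
        mesh,
        layout,
        seed=int(rng.integers(2**31)),
        ring_distances_mm=config.ring_distances_mm,
        patch_radius_mm=config.patch_radius_mm,
    )

    # per-subject target jitter candidates, shared across subjects
    template_vertices = sorted(set(truth.targets.values()))
    geo = geodesic_distances(mesh, np.asarray(template_vertices))
    jitter_candidates = {
        v: np.flatnonzero(geo[i] <= config.target_jitter_mm)
        for i, v in enumerate(template_vertices)
    }

    times = config.time_axis()
    atten = config.eccentricity_attenuation
    subjects: list[SubjectModel] = []
    subject_seeds = []
    for s in range(n_subjects):
        seed_s = int(rng.integers(2**31))
        subject_seeds.append(seed_s)
        rng_s = np.random.default_rng(seed_s)
        Ls = jitter_subject(
            L0, mesh, seed=int(rng_s.integers(2**31)),
            position_jitter_mm=config.position_jitter_mm,
            gain_jitter_fraction=config.gain_jitter_fraction,
        )
        cov = make_noise_cov(
            config.n_sensors, seed=int(rng_s.integers(2**31)),
            noise_std=config.noise_std,
        )
        base_peak = config.peak_time_ms
        if config.subject_peak_jitter_ms > 0:
            base_peak += float(
                rng_s.uniform(-config.subject_peak_jitter_ms,
                              config.subject_peak_jitter_ms)
            )
        evoked: dict[int, np.ndarray] = {}
        region_info: dict[int, dict] = {}
        for region in layout.regions:
            tv = []
            for _, v in truth.region_targets(region):
                cands = jitter_candidates[v]
                tv.append(int(cands[rng_s.integers(len(cands))])
                          if len(cands) > 1 and config.target_jitter_mm > 0
                          else int(v))
            snr_r = config.snr
            if snr_r is not None and atten is not None:
                snr_r = snr_r * atten[region.ring - 1]
            Y, info = simulate_evoked(
                Ls, cov, mesh, truth, region,
                snr_target=snr_r,
                peak_time_ms=base_peak,
                peak_time_jitter_ms=config.region_peak_jitter_ms,
                amplitude_jitter_fraction=config.amplitude_jitter_fraction,
                seed=int(rng_s.integers(2**31)),
                noise_scale=config.noise_scale,
                pulse_sigma_ms=config.pulse_sigma_ms,
                neighbor_leakage=config.neighbor_leakage,
                times=times,
                target_vertices=tv,
            )
            evoked[region.index] = Y
            region_info[region.index] = info
        true_median = float(np.median(
            [region_info[r.index]["peak_time_ms"] for r in layout.regions]
        ))
        subjects.append(
            SubjectModel(
                subject_id=s,
                leadfield=Ls,
                noise_cov=cov,
                evoked=evoked,
                times=times,
                info={
                    "seed": seed_s,
                    "base_peak_ms": base_peak,
                    "true_median_peak_ms": true_median,
                    "regions": region_info,
                },
            )
        )

    metadata = {
        "master_seed": int(master_seed),
        "subject_seeds": subject_seeds,
        "flashes_per_run": config.flashes_per_run,
        "n_runs": config.n_runs,
        "flashes_per_region": config.flashes_per_run * config.n_runs,
        "config": asdict(config),
    }
    return Experiment(mesh, sensors, layout, truth, subjects, config, metadata)
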