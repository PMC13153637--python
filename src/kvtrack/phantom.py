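"""Synthetic abdominal phantom, motion traces and projection rendering.

Real orthogonal-kV pancreas images are not publicly available, so this
module provides the study's stand-in: a parametric digital abdomen with

* an elliptical body of water-equivalent soft tissue,
* a static spine cylinder posterior to the target,
* a diaphragm dome with lung above it that moves with respiration,
* bowel-gas pockets and a low-contrast pancreatic target that move
  rigidly with the target (the "soft tissue block"),
* optional high-density fiducial markers inside the target, and
* stomach/duodenum/bowel surrogate ellipsoids used as dose structures.

DRRs are parallel-ray line integrals mu * int rho dl through the density
volume at the two oblique view angles, with densities above
1.869 g cm^-3 clipped to 1.0 before tracing (which hides the fiducials in
the reference DRRs but not in the simulated treatment images).  Ground
truth target positions are known exactly, which is what makes
parameter-recovery acceptance testing possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from kvtrack.geometry import ImagingGeometry, R_OBLIQUE

__all__ = [
    "PhantomConfig",
    "Phantom",
    "MotionTrace",
    "CohortSpec",
    "Cohort",
    "PatientData",
    "build_phantom",
    "sample_positions",
    "render_drr",
    "render_treatment_image",
    "generate_cohort",
    "synthetic_plan",
    "simulate_observation_cohort",
    "linear_map_cohort",
    "MU_120KV",
    "DENSITY_CLIP",
]

#: Effective linear attenuation coefficient used for ray tracing (mm^-1),
#: a water-equivalent value at 120 kV.
MU_120KV: float = 0.0171

#: Mass density above which voxels are reset to 1.0 before DRR tracing;
#: hides metal fiducials in the reference projections.
DENSITY_CLIP: float = 1.869


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and material parameters of the digital abdomen.

    Lengths in mm, densities in g/cm^3.  The patient frame has x toward
    patient left, y anterior, z superior, origin at the volume centre.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: float = 2.5
    body_semiaxes: tuple[float, float] = (140.0, 95.0)
    body_density: float = 1.0
    spine_center: tuple[float, float] = (0.0, -60.0)
    spine_radius: float = 14.0
    spine_density: float = 1.55
    lung_density: float = 0.28
    diaphragm_apex_z: float = 70.0
    diaphragm_depth: float = 55.0
    n_gas_pockets: int = 3
    gas_radius: float = 10.0
    gas_density: float = 0.05
    target_center: tuple[float, float, float] = (15.0, 15.0, -10.0)
    target_radius: float = 15.0
    target_density: float = 1.05
    n_fiducials: int = 4
    fiducial_radius: float = 2.5
    fiducial_density: float = 8.0
    #: zero-mean soft-tissue density texture carried by the moving block
    texture_amplitude: float = 0.07
    texture_scale_mm: float = 10.0
    ptv_margin: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fiducial_density <= DENSITY_CLIP:
            raise ValueError(
                "fiducial_density must exceed the DRR clipping density "
                f"{DENSITY_CLIP} so that clipping hides the markers"
            )
        for name in ("body_density", "spine_density", "lung_density",
                     "gas_density", "target_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        half = np.array(self.shape) * self.spacing / 2.0
        c = np.abs(np.asarray(self.target_center))
        if np.any(c + self.target_radius > half):
            raise ValueError("target must lie inside the volume")
        a, b = self.body_semiaxes
        if (self.target_center[0] / a) ** 2 + (self.target_center[1] / b) ** 2 >= 1.0:
            raise ValueError("target must lie inside the body ellipse")


def _axes_mm(shape, spacing):
    return [
        (np.arange(n, dtype=float) - (n - 1) / 2.0) * spacing for n in shape
    ]


class Phantom:
    """A realised phantom: fixed anatomy plus a movable soft-tissue block."""

    #: per-structure dose surrogate ellipsoids: centre (mm), semi-axes (mm)
    OARS = {
        "stomach": ((-50.0, 25.0, 10.0), (30.0, 22.0, 28.0)),
        "duodenum": ((42.0, 8.0, -12.0), (13.0, 13.0, 32.0)),
        "bowel": ((0.0, 48.0, -48.0), (52.0, 28.0, 24.0)),
    }

    def __init__(self, config: PhantomConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9A]))
        c = np.asarray(config.target_center)
        # gas pockets ring the target at seeded angles/distances
        centers = []
        for _ in range(config.n_gas_pockets):
            ang = rng.uniform(0, 2 * math.pi)
            dist = config.target_radius + config.gas_radius + rng.uniform(5.0, 25.0)
            dz = rng.uniform(-20.0, 20.0)
            centers.append(c + [dist * math.cos(ang), dist * math.sin(ang), dz])
        self.gas_centers = np.array(centers).reshape(-1, 3)
        # fiducials inside the target sphere
        pts = []
        for _ in range(config.n_fiducials):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pts.append(c + d * rng.uniform(0.0, 0.7 * config.target_radius))
        self.fiducial_coords = np.array(pts).reshape(-1, 3)
        # smooth zero-mean density texture that rides on the moving block;
        # it is what makes lateral soft-tissue motion visible in projection
        noise = rng.normal(size=config.shape)
        tex = ndimage.gaussian_filter(noise, config.texture_scale_mm / config.spacing)
        std = tex.std()
        self._texture = tex * (config.texture_amplitude / std if std > 0 else 0.0)
        self._grids = None

    # -- volume construction -------------------------------------------------

    def _coord_grids(self):
        if self._grids is None:
            ax = _axes_mm(self.config.shape, self.config.spacing)
            self._grids = np.meshgrid(*ax, indexing="ij", sparse=True)
        return self._grids

    def density(
        self,
        displacement=(0.0, 0.0, 0.0),
        include_fiducials: bool = True,
        spine_offset=(0.0, 0.0, 0.0),
    ) -> np.ndarray:
        """Density volume with the soft-tissue block displaced rigidly.

        The target, gas pockets and fiducials translate by the full
        3-vector ``displacement``; the diaphragm dome translates by its
        superior-inferior component only; the body outline and spine stay
        fixed (the spine can be given an independent small offset).
        """
        cfg = self.config
        X, Y, Z = self._coord_grids()
        dx, dy, dz = (float(v) for v in displacement)
        a, b = cfg.body_semiaxes

        shape = cfg.shape
        body = np.broadcast_to((X / a) ** 2 + (Y / b) ** 2 <= 1.0, shape)
        vol = np.where(body, cfg.body_density, 0.0)

        dome = cfg.diaphragm_apex_z + dz - cfg.diaphragm_depth * (
            (X / a) ** 2 + (Y / b) ** 2
        )
        vol[body & np.broadcast_to(Z > dome, shape)] = cfg.lung_density

        sx, sy, sz = (float(v) for v in spine_offset)
        spine = np.broadcast_to(
            (X - cfg.spine_center[0] - sx) ** 2
            + (Y - cfg.spine_center[1] - sy) ** 2
            <= cfg.spine_radius**2,
            shape,
        )
        vol[spine & body] = cfg.spine_density

        shift = np.array([dx, dy, dz])
        if cfg.texture_amplitude > 0:
            # the sub-diaphragm soft-tissue block translates rigidly with
            # the target; its internal texture is resampled accordingly
            tex = ndimage.shift(
                self._texture, shift / cfg.spacing, order=1, mode="nearest"
            )
            block = body & ~spine & np.broadcast_to(Z <= dome, shape)
            vol[block] += tex[block]
        for gc in self.gas_centers:
            p = gc + shift
            m = (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2 <= cfg.gas_radius**2
            vol[m & body] = cfg.gas_density

        tc = np.asarray(cfg.target_center) + shift
        target = (X - tc[0]) ** 2 + (Y - tc[1]) ** 2 + (Z - tc[2]) ** 2 <= cfg.target_radius**2
        vol[target] = cfg.target_density

        if include_fiducials:
            for fc in self.fiducial_coords:
                p = fc + shift
                m = (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2 <= cfg.fiducial_radius**2
                vol[m] = cfg.fiducial_density
        return vol

    # -- structures ----------------------------------------------------------

    @property
    def ptv_radius(self) -> float:
        return self.config.target_radius + self.config.ptv_margin

    def masks(self) -> dict[str, np.ndarray]:
        """Binary structure masks on the phantom voxel grid (planning pose).

        The PTV is the CTV dilated isotropically by the configured margin
        (computed with a Euclidean distance transform).
        """
        cfg = self.config
        X, Y, Z = self._coord_grids()
        tc = np.asarray(cfg.target_center)
        ctv = (
            (X - tc[0]) ** 2 + (Y - tc[1]) ** 2 + (Z - tc[2]) ** 2
            <= cfg.target_radius**2
        )
        dist = ndimage.distance_transform_edt(~ctv, sampling=cfg.spacing)
        ptv = dist <= cfg.ptv_margin
        spine = (X - cfg.spine_center[0]) ** 2 + (Y - cfg.spine_center[1]) ** 2 <= cfg.spine_radius**2
        spine = np.broadcast_to(spine, ctv.shape).copy()
        out = {"ctv": ctv, "ptv": ptv, "spine": spine}
        for name, (center, semi) in self.OARS.items():
            cx, cy, cz = center
            ax, ay, az = semi
            out[name] = (
                ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2
                <= 1.0
            )
        return out

    def dose_grid_masks(self, spacing: float = 2.0, half_extent: float = 60.0):
        """Analytic structure masks on a dose grid centred on the target.

        Returns (masks dict, origin mm, spacing).  The grid is a cube of
        the given half extent around the planning-pose target centre; OAR
        surrogates are clipped to the grid where they extend beyond it.
        """
        n = int(round(2 * half_extent / spacing)) + 1
        tc = np.asarray(self.config.target_center)
        ax = [tc[k] + (np.arange(n) - (n - 1) / 2.0) * spacing for k in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij", sparse=True)
        r2 = (X - tc[0]) ** 2 + (Y - tc[1]) ** 2 + (Z - tc[2]) ** 2
        masks = {
            "ctv": r2 <= self.config.target_radius**2,
            "ptv": r2 <= self.ptv_radius**2,
        }
        for name, (center, semi) in self.OARS.items():
            cx, cy, cz = center
            sx, sy, sz = semi
            masks[name] = (
                ((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2 + ((Z - cz) / sz) ** 2
                <= 1.0
            )
        origin = np.array([a[0] for a in ax])
        return masks, origin, spacing


def build_phantom(config: PhantomConfig) -> Phantom:
    """Construct a phantom; deterministic for a fixed config seed."""
    return Phantom(config)


# -- motion ------------------------------------------------------------------


@dataclass(frozen=True)
class MotionTrace:
    """Per-fraction motion: baseline offset plus a periodic respiratory term.

    ``amplitude`` holds per-axis half peak-to-peak amplitudes (mm); the
    waveform is either a pure cosine or the end-exhale-dwelling cos^4
    shape, both normalised to the range [-1, 1].
    """

    baseline: tuple[float, float, float] = (0.0, 0.0, 0.0)
    amplitude: tuple[float, float, float] = (0.0, 0.0, 0.0)
    period_s: float = 4.0
    phase: float = 0.0
    waveform: str = "cos4"
    sample_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.waveform not in ("cos", "cos4"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")


def _waveform(theta: np.ndarray, kind: str) -> np.ndarray:
    if kind == "cos":
        return np.cos(theta)
    # cos^4 with period 2*pi and range [-1, 1]: dwells near -1 (exhale)
    return 2.0 * np.cos(theta / 2.0) ** 4 - 1.0


def sample_positions(trace: MotionTrace, n_images: int):
    """Ground-truth target positions at the trace's sample times.

    position(t) = baseline + amplitude * w(2 pi t / T + phase).
    Returns (positions (n, 3) mm, per-fraction mean position (3,)).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if len(trace.sample_times) < n_images:
        raise ValueError(
            f"trace provides {len(trace.sample_times)} sample times, "
            f"need {n_images}"
        )
    t = np.asarray(trace.sample_times[:n_images], dtype=float)
    theta = 2.0 * math.pi * t / trace.period_s + trace.phase
    w = _waveform(theta, trace.waveform)
    pos = np.asarray(trace.baseline, float)[None, :] + np.outer(
        w, np.asarray(trace.amplitude, float)
    )
    return pos, pos.mean(axis=0)


# -- rendering ---------------------------------------------------------------

_VIEW_VECTORS = {
    # lateral detector axis u, ray direction d (unit vectors, patient frame)
    "A": (np.array([R_OBLIQUE, -R_OBLIQUE, 0.0]), np.array([R_OBLIQUE, R_OBLIQUE, 0.0])),
    "B": (np.array([R_OBLIQUE, R_OBLIQUE, 0.0]), np.array([-R_OBLIQUE, R_OBLIQUE, 0.0])),
}

_COORD_CACHE: dict = {}


def _ray_coordinates(shape, spacing, geometry: ImagingGeometry, view: str):
    """Voxel-index sample coordinates for all detector pixels and ray depths."""
    key = (shape, spacing, geometry.image_size, geometry.pixel_spacing, view)
    cached = _COORD_CACHE.get(key)
    if cached is not None:
        return cached
    u, d = _VIEW_VECTORS[view]
    n = geometry.image_size
    c0 = (n - 1) / 2.0
    half_diag = 0.5 * math.hypot(shape[0] * spacing, shape[1] * spacing)
    s = np.arange(-half_diag, half_diag + spacing, spacing)
    cols = (np.arange(n) - c0) * geometry.pixel_spacing
    rows_z = (c0 - np.arange(n)) * geometry.pixel_spacing  # row down = inferior
    # point = u * lateral + d * depth + z_hat * row_z
    lat = cols[None, :, None]
    dep = s[None, None, :]
    zz = rows_z[:, None, None]
    coords = np.empty((3, n, n, s.size), dtype=np.float32)
    for k in range(3):
        p_mm = u[k] * lat + d[k] * dep + (1.0 if k == 2 else 0.0) * zz
        coords[k] = p_mm / spacing + (shape[k] - 1) / 2.0
    _COORD_CACHE[key] = (coords, spacing)
    return coords, spacing


def render_drr(
    volume: np.ndarray,
    spacing: float,
    geometry: ImagingGeometry,
    view: str,
    mu: float = MU_120KV,
    clip_density: float | None = DENSITY_CLIP,
) -> np.ndarray:
    """Parallel-ray line-integral projection of a density volume.

    Each pixel holds mu * sum rho * dl along the oblique ray through that
    pixel (attenuation-style: dense anatomy is bright).  With the default
    ``clip_density``, voxels denser than 1.869 are traced as density 1.0,
    hiding metal fiducials; pass ``clip_density=None`` to trace the true
    densities (treatment-image simulation).
    """
    if view not in _VIEW_VECTORS:
        raise ValueError(f"view must be 'A' or 'B', got {view!r}")
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D")
    if clip_density is not None:
        volume = np.where(volume > clip_density, np.float32(1.0), volume)
    coords, step = _ray_coordinates(volume.shape, spacing, geometry, view)
    samples = ndimage.map_coordinates(
        volume, coords.reshape(3, -1), order=1, mode="constant", cval=0.0
    ).reshape(coords.shape[1:])
    return mu * step * samples.sum(axis=2).astype(float)


def _intensity_field(n: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative perturbation 1 + amplitude * q(u, v).

    q is a random quadratic polynomial over the frame, normalised to
    max |q| = 1, emulating slowly varying gain differences between the
    simulated detector and the DRR chain.
    """
    if amplitude == 0.0:
        rng.normal(size=5)  # keep the stream aligned regardless of amplitude
        return np.ones((n, n))
    u = np.linspace(-1.0, 1.0, n)
    U, V = np.meshgrid(u, u, indexing="ij")
    c = rng.normal(size=5)
    q = c[0] * U + c[1] * V + c[2] * U * U + c[3] * U * V + c[4] * V * V
    peak = np.max(np.abs(q))
    if peak > 0:
        q /= peak
    return 1.0 + amplitude * q


def render_treatment_image(
    phantom: Phantom,
    geometry: ImagingGeometry,
    true_position=(0.0, 0.0, 0.0),
    noise_level: float = 0.0,
    intensity_perturbation: float = 0.0,
    seed: int | np.random.Generator = 0,
    include_fiducials: bool = True,
) -> dict[str, np.ndarray]:
    """Simulate the processed treatment-image pair at a known target position.

    The soft-tissue block is displaced by ``true_position``; fiducials are
    *not* density-clipped here, so they appear in the images (to exercise
    the removal operator); additive Gaussian noise and a smooth
    multiplicative intensity field are applied per view.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    vol = phantom.density(
        displacement=true_position, include_fiducials=include_fiducials
    )
    out = {}
    for view in ("A", "B"):
        img = render_drr(
            vol, phantom.config.spacing, geometry, view, clip_density=None
        )
        img = img * _intensity_field(geometry.image_size, intensity_perturbation, rng)
        if noise_level > 0:
            img = img + rng.normal(0.0, noise_level, size=img.shape)
        else:
            rng.normal(0.0, 1.0, size=img.shape)  # keep the stream aligned
        out[view] = img
    return out


# -- cohorts -----------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Size and noise conditions of a synthetic patient cohort."""

    n_patients: int = 4
    n_fractions: int = 3
    n_images: int = 6
    noise_level: float = 0.05
    intensity_perturbation: float = 0.10
    baseline_sigma: float = 5.0
    #: per-axis (low, high) half peak-to-peak respiratory amplitudes, mm
    amplitude_ranges: tuple = ((3.0, 8.0), (3.0, 8.0), (6.0, 12.0))
    period_s: float = 4.0
    fraction_duration_s: float = 300.0
    include_fiducials: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_fractions, self.n_images) < 1:
            raise ValueError("cohort counts must all be >= 1")


@dataclass
class PatientData:
    """One synthetic patient: anatomy, reference DRRs, images and truth."""

    patient: int
    phantom: Phantom
    geometry: ImagingGeometry
    drr: dict[str, np.ndarray]
    images: dict[tuple[int, int], dict[str, np.ndarray]]
    truth: pd.DataFrame


@dataclass
class Cohort:
    spec: CohortSpec
    geometry: ImagingGeometry
    patients: list[PatientData]

    @property
    def truth(self) -> pd.DataFrame:
        return pd.concat([p.truth for p in self.patients], ignore_index=True)


def _patient_phantom_config(base: PhantomConfig, rng: np.random.Generator) -> PhantomConfig:
    """Mild per-patient anatomical variation around the base configuration."""
    jitter = rng.uniform(-5.0, 5.0, size=3)
    scale = rng.uniform(0.95, 1.05, size=2)
    return replace(
        base,
        target_center=tuple(
            float(v) for v in np.asarray(base.target_center) + jitter
        ),
        body_semiaxes=tuple(float(v) for v in np.asarray(base.body_semiaxes) * scale),
        seed=int(rng.integers(2**31 - 1)),
    )


def generate_cohort(
    spec: CohortSpec,
    phantom_config: PhantomConfig | None = None,
    geometry: ImagingGeometry | None = None,
) -> Cohort:
    """Generate a full synthetic cohort with known ground truth.

    Each patient gets an independent seed derived from the master seed, a
    mildly varied anatomy, per-fraction Gaussian baseline shifts and a
    per-patient respiratory amplitude drawn from the configured ranges.
    Deterministic for a fixed spec.
    """
    if phantom_config is None:
        phantom_config = PhantomConfig()
    if geometry is None:
        geometry = ImagingGeometry(
            image_size=phantom_config.shape[0], pixel_spacing=phantom_config.spacing
        )
    patients = []
    for p in range(spec.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed, p]))
        cfg = _patient_phantom_config(phantom_config, rng)
        phantom = build_phantom(cfg)
        drr = {
            v: render_drr(phantom.density(include_fiducials=True), cfg.spacing, geometry, v)
            for v in ("A", "B")
        }
        amplitude = tuple(rng.uniform(lo, hi) for lo, hi in spec.amplitude_ranges)
        images = {}
        rows = []
        for m in range(spec.n_fractions):
            baseline = rng.normal(0.0, spec.baseline_sigma, size=3)
            trace = MotionTrace(
                baseline=tuple(baseline),
                amplitude=amplitude,
                period_s=spec.period_s,
                phase=rng.uniform(0, 2 * math.pi),
                sample_times=tuple(
                    np.sort(rng.uniform(0, spec.fraction_duration_s, spec.n_images))
                ),
            )
            positions, _ = sample_positions(trace, spec.n_images)
            for n, pos in enumerate(positions):
                images[(m, n)] = render_treatment_image(
                    phantom,
                    geometry,
                    true_position=pos,
                    noise_level=spec.noise_level,
                    intensity_perturbation=spec.intensity_perturbation,
                    seed=np.random.default_rng(
                        np.random.SeedSequence([spec.master_seed, p, m, n])
                    ),
                    include_fiducials=spec.include_fiducials,
                )
                rows.append(
                    {"patient": p, "fraction": m, "image": n,
                     "x_mm": pos[0], "y_mm": pos[1], "z_mm": pos[2]}
                )
        patients.append(
            PatientData(
                patient=p,
                phantom=phantom,
                geometry=geometry,
                drr=drr,
                images=images,
                truth=pd.DataFrame(rows),
            )
        )
    return Cohort(spec=spec, geometry=geometry, patients=patients)


# -- synthetic treatment plan -------------------------------------------------


def synthetic_plan(
    ptv_mask: np.ndarray,
    spacing: float,
    n_beams: int = 60,
    prescription: float = 35.0,
):
    """Multi-beam conformal dose surrogate around a PTV mask.

    Each beam contributes an anisotropic Gaussian-falloff dose field
    conformal to the PTV from a distinct direction (azimuthal sweep with
    alternating elevation); the summed plan is normalised so that
    D95%(PTV) equals the prescription.  Returns (per-beam components,
    total dose), all on the PTV mask's grid.
    """
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    if not ptv_mask.any():
        raise ValueError("PTV mask is empty")
    idx = np.argwhere(ptv_mask)
    com = idx.mean(axis=0)
    ax = [(np.arange(n) - com[k]) * spacing for k, n in enumerate(ptv_mask.shape)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij", sparse=True)
    pts_ptv = (idx - com) * spacing

    sigma_lat, sigma_par = 4.0, 30.0
    beams = []
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for k in range(n_beams):
        az = k * golden
        el = math.radians(((k % 3) - 1) * 15.0)
        u = np.array(
            [math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)]
        )
        t = X * u[0] + Y * u[1] + Z * u[2]
        rho2 = (X * X + Y * Y + Z * Z) - t * t
        rho = np.sqrt(np.maximum(rho2, 0.0))
        t_ptv = pts_ptv @ u
        rho_ptv = np.sqrt(
            np.maximum((pts_ptv * pts_ptv).sum(axis=1) - t_ptv**2, 0.0)
        )
        r_lat = rho_ptv.max()
        t_par = np.abs(t_ptv).max()
        lat = np.exp(-0.5 * (np.clip(rho - r_lat, 0.0, None) / sigma_lat) ** 2)
        par = np.exp(-0.5 * (np.clip(np.abs(t) - t_par, 0.0, None) / sigma_par) ** 2)
        beams.append(lat * par)
    total = np.sum(beams, axis=0)
    d95 = np.percentile(total[ptv_mask], 5)
    if d95 <= 0:
        raise ValueError("degenerate plan: zero dose at the PTV cold quantile")
    scale = prescription / d95
    beams = [b * scale for b in beams]
    return beams, total * scale


# -- observation-level simulators ---------------------------------------------


def linear_map_cohort(
    n_obs: int,
    noise_sigma: float = 1.0,
    seed: int = 0,
    n_components: int = 104,
):
    """Observations from a known affine map registration-space -> position.

    Draws v ~ N(0, 1)^104 and sets r = [v; 1] @ C + eps with a fixed,
    seeded coefficient matrix C (105 x 3) and eps ~ N(0, noise_sigma^2).
    Returns (V (n, 104), Rpos (n, 3), C).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11]))
    C = rng.normal(0.0, 0.3, size=(n_components + 1, 3))
    V = rng.normal(size=(n_obs, n_components))
    Rpos = np.hstack([V, np.ones((n_obs, 1))]) @ C
    Rpos = Rpos + rng.normal(0.0, noise_sigma, size=Rpos.shape)
    return V, Rpos, C


def _forward_map(seed: int = 7, n_components: int = 104) -> np.ndarray:
    """Fixed position -> registration-space response matrix G (3 -> 104).

    Emulates how a rigid target displacement shows up in the registration
    vector: PTV slots respond with the exact oblique-projection weights,
    grid-region slots respond with seeded partial gains (regions far from
    the moving anatomy see less of the motion).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x47]))
    G = np.zeros((n_components, 3))
    R = R_OBLIQUE
    # per-view slot layout: 25 grid (I, J) pairs then the PTV (I, J) pair
    for view in range(2):
        base = view * 52
        i_row = np.array([R, -R, 0.0]) if view == 0 else np.array([R, R, 0.0])
        j_row = np.array([0.0, 0.0, -1.0])
        for k in range(25):
            gain = rng.uniform(0.0, 1.0)
            G[base + 2 * k] = gain * i_row
            G[base + 2 * k + 1] = gain * j_row
        G[base + 50] = i_row
        G[base + 51] = j_row
    return G


def simulate_observation_cohort(
    n_patients: int = 4,
    n_fractions: int = 3,
    n_images: int = 20,
    baseline_sigma: float = 5.0,
    amplitude_ranges=((3.0, 8.0), (3.0, 8.0), (6.0, 12.0)),
    observation_noise: float = 1.0,
    seed: int = 0,
):
    """Registration-space observations without image rendering.

    Target positions follow per-fraction baselines plus respiration (as in
    :func:`generate_cohort`); registration vectors are v = G r + eta with
    the fixed forward map of :func:`_forward_map` and i.i.d. Gaussian
    observation noise.  Orders of magnitude faster than rendering, used
    for motion-model studies.  Returns an
    :class:`~kvtrack.motion_model.ObservationSet`.
    """
    from kvtrack.motion_model import ObservationSet

    G = _forward_map()
    V, Rpos, pat, frac, img = [], [], [], [], []
    for p in range(n_patients):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0B5, p]))
        amplitude = tuple(rng.uniform(lo, hi) for lo, hi in amplitude_ranges)
        for m in range(n_fractions):
            trace = MotionTrace(
                baseline=tuple(rng.normal(0.0, baseline_sigma, size=3)),
                amplitude=amplitude,
                phase=rng.uniform(0, 2 * math.pi),
                sample_times=tuple(np.sort(rng.uniform(0, 300.0, n_images))),
            )
            pos, _ = sample_positions(trace, n_images)
            v = pos @ G.T + rng.normal(0.0, observation_noise, size=(n_images, G.shape[0]))
            V.append(v)
            Rpos.append(pos)
            pat.extend([p] * n_images)
            frac.extend([m] * n_images)
            img.extend(range(n_images))
    return ObservationSet(
        v=np.vstack(V),
        r=np.vstack(Rpos),
        patient=np.array(pat),
        fraction=np.array(frac),
        image=np.array(img),
    )
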