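"""Synthetic thorax phantoms and breathing-driven EIT recordings.

The generator stands in for animal data: it produces pig-like thorax
cross-sections (a fixed smooth averaged shape, seeded individual variations
of it, and the information-free circle), simulates a breathing recording by
modulating lung conductivity on a fine simulation mesh, and emits the
co-registered high-resolution ground-truth tidal aeration image that plays
the role of the CT tidal image.

Physiology model: inflation lowers lung conductivity.  Lung elements follow

    sigma(t) = sigma_lung0 * (1 - a(y) * dsigma * (1 - cos(2 pi f t)) / 2)

where ``a(y)`` is a linear anteroposterior weight with mean 1 over the lung
(``ap_gradient`` > 0 ventilates posterior regions more, as in a supine
subject) and ``dsigma`` is the peak relative conductivity swing.  Voltages
depend on time only through the scalar breath amplitude, so frames are
computed exactly from a small number of forward solves interpolated along
the amplitude axis.  The recording is simulated on a mesh refined relative
to the reconstruction meshes so that no inverse crime occurs, and white
Gaussian channel noise is added at a configurable SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import PchipInterpolator

from .forward import CEMSystem, LUNG_WEIGHT, skip4_scheme
from .geometry import (
    Contour,
    InvalidGeometryError,
    ThoraxGeometry,
    build_mesh,
    place_electrodes,
    rasterize,
    symmetric_difference,
    REGION_CODES,
)
from .pipeline import VoltageSeries
from .profiles import VentilationProfile, ap_profile

__all__ = [
    "PhantomConfig",
    "BreathingConfig",
    "GroundTruth",
    "Subject",
    "Cohort",
    "make_phantom",
    "simulate_recording",
    "cohort",
    "DEFAULT_RECON_ELEMENTS",
]

DEFAULT_RECON_ELEMENTS = 20000


# ---------------------------------------------------------------------------
# phantom geometry


def _ellipse(center, a, b, angle_deg, n=64, label=""):
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ang = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    xy = np.column_stack([x, y]) @ rot.T + np.asarray(center)
    return Contour(xy, label=label)


def _averaged_thorax(n: int = 160) -> Contour:
    """Fixed smooth pig-like thorax shape (low-order Fourier descriptor).

    A synthetic stand-in for a population-averaged contour, not a published
    shape library entry: dorsoventrally deeper than wide, broader dorsally,
    tapering ventrally, as in porcine mid-thorax cross-sections.
    """
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = (
        1.0
        - 0.08 * np.cos(2 * phi)
        + 0.05 * np.sin(phi)
        - 0.03 * np.sin(3 * phi)
    )
    return Contour(np.column_stack([r * np.cos(phi), r * np.sin(phi)]), "thorax")


def _lung_contour(side: int, n: int = 72) -> Contour:
    """Bean-shaped lung lobe, broadest dorsally, hugging the lateral wall.

    ``side`` -1 is the animal's right lung (-x half), +1 the left.
    Together the two lobes cover about a third of the thoracic
    cross-section, as in mid-thorax pig CT.
    """
    cx, cy, b, w0, bulge = 0.38, 0.20, 0.52, 0.30, 0.40
    t = np.linspace(-1.0, 1.0, n // 2)
    width = w0 * np.sqrt(np.clip(1.0 - t**2, 0.0, 1.0)) * (1.0 + bulge * t)
    y = cy + b * t
    inner = side * cx - side * width * 0.72
    outer = side * cx + side * width * 1.28
    pts = np.concatenate(
        [np.column_stack([outer, y]), np.column_stack([inner[::-1], y[::-1]])]
    )
    d = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    pts = pts[d > 1e-9]
    return Contour(pts, "lung_right" if side < 0 else "lung_left")


def _averaged_geometry() -> ThoraxGeometry:
    g = ThoraxGeometry(
        thorax=_averaged_thorax(),
        lungs=(_lung_contour(-1), _lung_contour(+1)),
        heart=_ellipse((0.05, -0.38), 0.20, 0.15, 0.0, label="heart"),
        kind="averaged",
    )
    return g.normalized()


def _circle_geometry(n: int = 128) -> ThoraxGeometry:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    c = Contour(np.column_stack([np.cos(t), np.sin(t)]), "thorax")
    return ThoraxGeometry(thorax=c, kind="circular").normalized()


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry settings.

    ``perturbation_amplitude`` controls the seeded smooth radial deformation
    of individual phantoms; the default targets a contour mismatch (relative
    symmetric difference vs. the averaged shape) inside ``delta_s_band``.
    """

    kind: Literal["circular", "averaged", "individual"] = "individual"
    seed: int = 0
    perturbation_amplitude: float = 0.035
    harmonics: tuple[int, ...] = (2, 3, 4, 5)
    delta_s_band: tuple[float, float] = (3.0, 8.0)
    max_attempts: int = 10


def _radial_perturbation(rng: np.random.Generator, cfg: PhantomConfig):
    g = rng.standard_normal(len(cfg.harmonics))
    phases = rng.uniform(0.0, 2 * np.pi, len(cfg.harmonics))
    a = cfg.perturbation_amplitude * np.sqrt(2.0) * g / np.linalg.norm(g)

    def rho(theta: np.ndarray) -> np.ndarray:
        out = np.ones_like(theta)
        for ak, k, ph in zip(a, cfg.harmonics, phases):
            out += ak * np.cos(k * theta + ph)
        return out

    return rho


def make_phantom(cfg: PhantomConfig) -> ThoraxGeometry:
    """Generate a normalized phantom geometry of the requested kind."""
    if cfg.kind == "circular":
        return _circle_geometry()
    base = _averaged_geometry()
    if cfg.kind == "averaged":
        return base
    if cfg.kind != "individual":
        raise ValueError(f"unknown phantom kind {cfg.kind!r}")
    rng = np.random.default_rng(cfg.seed)
    last_err: Exception | None = None
    for _ in range(cfg.max_attempts):
        rho = _radial_perturbation(rng, cfg)

        def deform(c: Contour, label: str) -> Contour:
            v = c.vertices
            theta = np.arctan2(v[:, 1], v[:, 0])
            return Contour(v * rho(theta)[:, None], label=label)

        try:
            g = ThoraxGeometry(
                thorax=deform(base.thorax, "thorax"),
                lungs=tuple(deform(l, l.label) for l in base.lungs),
                heart=deform(base.heart, "heart"),
                kind="individual",
            ).normalized()
        except InvalidGeometryError as exc:
            last_err = exc
            continue
        ds = symmetric_difference(g.thorax, base.thorax)
        if cfg.delta_s_band[0] <= ds <= cfg.delta_s_band[1]:
            return g
        last_err = InvalidGeometryError(
            f"contour mismatch {ds:.2f}% outside band {cfg.delta_s_band}"
        )
    raise InvalidGeometryError(
        f"could not generate an individual phantom after "
        f"{cfg.max_attempts} attempts: {last_err}"
    )


# ---------------------------------------------------------------------------
# breathing simulation


@dataclass(frozen=True)
class BreathingConfig:
    """Recording conditions of the simulated ventilation protocol."""

    f_resp: float = 6.0  # breaths per minute
    fs: float = 48.0  # frames per second
    duration: float = 30.0  # seconds
    dsigma_lung: float = 0.2  # peak relative lung conductivity decrease
    ap_gradient: float = 0.3  # anteroposterior ventilation asymmetry
    noise_snr: float | None = 50.0  # dB; None disables noise
    sim_mesh_refinement: float = 2.0
    sim_target_elements: int | None = None  # default: refinement * 20k
    amplitude_levels: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2.0 * self.f_resp / 60.0:
            raise ValueError("sampling rate must exceed twice the breath rate")
        if self.duration < 1.5 * 60.0 / self.f_resp:
            raise ValueError("duration must cover at least 1.5 breaths")
        if not 0.0 <= self.dsigma_lung < 1.0:
            raise ValueError("dsigma_lung must be in [0, 1)")
        if self.sim_mesh_refinement < 2.0:
            raise ValueError("simulation mesh refinement must be >= 2")

    @property
    def breath_period(self) -> float:
        return 60.0 / self.f_resp

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class GroundTruth:
    """High-resolution tidal aeration image and its ventilation profile."""

    tidal_aeration: np.ndarray  # (128, 128), arbitrary units, lung support
    lung_mask: np.ndarray  # (128, 128) bool
    vd_truth: VentilationProfile
    ap_weight_mean_y: float
    dsigma_lung: float


def _ap_weight(y: np.ndarray, y_lo: float, y_hi: float, gradient: float) -> np.ndarray:
    """Linear anteroposterior weight, +gradient at the posterior lung edge."""
    mid = 0.5 * (y_lo + y_hi)
    half = max(0.5 * (y_hi - y_lo), 1e-12)
    return np.clip(1.0 + gradient * (y - mid) / half, 0.0, None)


def simulate_recording(
    g: ThoraxGeometry,
    b: BreathingConfig,
    truth_shape: tuple[int, int] = (128, 128),
) -> tuple[VoltageSeries, GroundTruth]:
    """Simulate one breathing EIT recording plus its aeration ground truth."""
    if not g.lungs:
        raise ValueError("simulation needs a geometry with lungs")
    layout = place_electrodes(g.thorax, 32)
    target = b.sim_target_elements or int(b.sim_mesh_refinement * DEFAULT_RECON_ELEMENTS)
    mesh = build_mesh(g, layout, target_elements=target)
    scheme = skip4_scheme()
    system = CEMSystem(mesh, scheme)

    lung_sel = mesh.element_region == REGION_CODES["lung"]
    sigma0 = np.ones(mesh.n_elements)
    sigma0[lung_sel] = LUNG_WEIGHT
    if g.heart is not None:
        sigma0[mesh.element_region == REGION_CODES["heart"]] = 1.5

    ey = mesh.element_centroids[:, 1]
    lung_y = ey[lung_sel]
    y_lo, y_hi = float(lung_y.min()), float(lung_y.max())
    a_elem = _ap_weight(ey, y_lo, y_hi, b.ap_gradient)
    vols = mesh.element_volumes
    a_elem = a_elem / np.average(a_elem[lung_sel], weights=vols[lung_sel])

    # voltages depend on t only through the breath amplitude alpha(t)
    levels = np.linspace(0.0, 1.0, b.amplitude_levels)
    frames_at = np.empty((len(levels), scheme.n_channels))
    for i, alpha in enumerate(levels):
        sigma = sigma0.copy()
        sigma[lung_sel] = LUNG_WEIGHT * (
            1.0 - a_elem[lung_sel] * b.dsigma_lung * alpha
        )
        frames_at[i] = system.solve(sigma).channels
    t = np.arange(b.n_frames) / b.fs
    alpha_t = 0.5 * (1.0 - np.cos(2 * np.pi * (b.f_resp / 60.0) * t))
    valid = scheme.valid_flat
    values = np.full((b.n_frames, scheme.n_channels), np.nan)
    interp = PchipInterpolator(levels, frames_at[:, valid], axis=0)
    values[:, valid] = interp(alpha_t)

    if b.noise_snr is not None:
        rng = np.random.default_rng(b.seed)
        dev = values[:, valid] - values[:, valid].mean(axis=0)
        rms = float(np.sqrt(np.mean(dev**2)))
        std = rms / 10.0 ** (b.noise_snr / 20.0)
        if std > 0.0:
            values[:, valid] += rng.normal(0.0, std, size=values[:, valid].shape)

    series = VoltageSeries(
        values=values, timestamps=t, scheme=scheme, sampling_rate=b.fs
    )

    # ground truth: conductivity swing between end-expiration and
    # end-inspiration, rasterized on the thorax bounding box
    grid_hi = rasterize(g, shape=truth_shape)
    X, Y = grid_hi.pixel_centers()
    a_pix = _ap_weight(Y, y_lo, y_hi, b.ap_gradient)
    lung_hi = grid_hi.lung_mask
    if lung_hi.sum() == 0:
        raise ValueError("lung contours rasterize to an empty mask")
    a_pix = a_pix / a_pix[lung_hi].mean()
    tidal = np.where(lung_hi, LUNG_WEIGHT * b.dsigma_lung * a_pix, 0.0)
    if b.dsigma_lung > 0:
        vd = ap_profile(tidal, lung_hi)
    else:
        counts = lung_hi.reshape(32, truth_shape[0] // 32, -1).sum(axis=(1, 2))
        vd = VentilationProfile(100.0 * counts / counts.sum())
    truth = GroundTruth(
        tidal_aeration=tidal,
        lung_mask=lung_hi,
        vd_truth=vd,
        ap_weight_mean_y=0.5 * (y_lo + y_hi),
        dsigma_lung=b.dsigma_lung,
    )
    return series, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Subject:
    """One synthetic animal: its true geometry, recording and ground truth."""

    index: int
    seed: int
    geometry: ThoraxGeometry  # individual (truth and M3-analog prior)
    recording: VoltageSeries
    truth: GroundTruth


@dataclass
class Cohort:
    """A set of subjects sharing the circular and averaged priors."""

    subjects: list[Subject]
    circular: ThoraxGeometry
    averaged: ThoraxGeometry


def cohort(
    n: int = 8,
    seeds: list[int] | None = None,
    breathing: BreathingConfig | None = None,
    phantom: PhantomConfig | None = None,
) -> Cohort:
    """Generate ``n`` subjects: individual geometries, one recording each.

    ``seeds`` (one per subject) makes the cohort bit-reproducible; by
    default subject ``i`` uses seed ``i``.  The recording-noise seed is
    derived from the subject seed.
    """
    if n < 1:
        raise ValueError("cohort needs at least one subject")
    if seeds is None:
        seeds = list(range(n))
    if len(seeds) != n:
        raise ValueError("need exactly one seed per subject")
    base_breathing = breathing or BreathingConfig()
    base_phantom = phantom or PhantomConfig()
    subjects = []
    for i, s in enumerate(seeds):
        pcfg = PhantomConfig(
            kind="individual",
            seed=int(s),
            perturbation_amplitude=base_phantom.perturbation_amplitude,
            harmonics=base_phantom.harmonics,
            delta_s_band=base_phantom.delta_s_band,
            max_attempts=base_phantom.max_attempts,
        )
        geom = make_phantom(pcfg)
        bcfg = _with_seed(base_breathing, int(s) + 1_000_003)
        rec, truth = simulate_recording(geom, bcfg)
        subjects.append(
            Subject(index=i, seed=int(s), geometry=geom, recording=rec, truth=truth)
        )
    return Cohort(
        subjects=subjects,
        circular=_circle_geometry(),
        averaged=_averaged_geometry(),
    )


def _with_seed(b: BreathingConfig, seed: int) -> BreathingConfig:
    from dataclasses import replace

    return replace(b, seed=seed % (2**31 - 1))
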