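"""Synthetic slide, image, and spectrum generators plus a simulated instrument.

The targeting and classification stages are exercised end-to-end against a
*slide phantom* with known ground truth:

* defocused bright-field image tiles in which each cell nucleus focuses the
  partially coherent illumination into a bright spot in a plane displaced
  from focus (the "microlens" effect) — rendered phenomenologically as
  Gaussian spots with a Gaussian axial envelope, not by wave optics;
* Raman spectra modelled as a weighted superposition of a class signature,
  a glass-substrate background and a smooth polynomial baseline, with dark
  current, Poisson shot noise, Gaussian read noise and occasional
  cosmic-ray spikes.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectral_core import Spectrum, SpectrumSet, WavenumberAxis

__all__ = [
    "CameraModel",
    "Nucleus",
    "SlidePhantom",
    "SlideParams",
    "SpectralPhantomParams",
    "ImageTile",
    "PlacementError",
    "StageLimitError",
    "default_axis",
    "generate_slide",
    "render_image",
    "class_signature",
    "glass_profile",
    "generate_spectrum",
    "generate_spectrum_set",
    "SimulatedInstrument",
]


def default_axis(n: int = 1024, lo: float = -34.0, hi: float = 2517.0) -> WavenumberAxis:
    """The instrument's nominal linear axis: 1024 samples over -34..2517 cm^-1."""
    return WavenumberAxis(np.linspace(lo, hi, n))


@dataclass(frozen=True)
class CameraModel:
    """CCD noise model.

    Defaults follow a cooled, full-vertical-bin spectroscopy CCD: read noise
    4 electrons per spectral sample and a mean dark current of 0.0512
    electrons/second/sample, with unit gain (counts per electron).
    """

    read_noise_sd: float = 4.0
    dark_current: float = 0.0512
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.dark_current < 0 or self.gain < 0:
            raise ValueError("camera parameters must be non-negative")


@dataclass(frozen=True)
class Nucleus:
    x: float  # stage µm
    y: float  # stage µm
    label: str
    amplitude: float  # bright-spot peak counts above background
    spot_radius: float  # Gaussian sigma, µm


@dataclass
class SlideParams:
    """Free parameters of the slide phantom (none are fixed by real optics)."""

    field_extent: float = 400.0  # µm, square field
    z_spot: float = 14.0  # µm displacement of the bright-spot plane (ThinPrep preset)
    background: float = 100.0  # lamp background, counts
    amplitude: float = 150.0  # mean bright-spot amplitude, counts
    amplitude_jitter: float = 0.1  # relative sd
    spot_radius: float = 2.5  # µm (Gaussian sigma of the spot)
    isolation_um: float = 30.0  # minimum spacing of non-clustered nuclei
    pair_distance: tuple[float, float] = (4.0, 8.0)  # µm, clustered-pair offsets
    z_envelope: float = 5.0  # ζ, µm: axial width of the bright-spot contrast
    class_labels: tuple[str, str] = ("high_grade", "low_grade")

    @classmethod
    def thinprep(cls, **kw) -> "SlideParams":
        return cls(z_spot=14.0, **kw)

    @classmethod
    def adherent(cls, **kw) -> "SlideParams":
        return cls(z_spot=50.0, **kw)


@dataclass
class SlidePhantom:
    """Ground-truth synthetic slide."""

    nuclei: list[Nucleus]
    z_spot: float
    field_extent: float
    background: float
    z_envelope: float
    seed: int

    def __post_init__(self) -> None:
        if self.z_spot == 0:
            raise ValueError("z_spot must be non-zero (the bright-spot plane is displaced)")
        for n in self.nuclei:
            if n.amplitude <= 0:
                raise ValueError("bright-spot amplitudes must be > 0")
            if not (0 <= n.x <= self.field_extent and 0 <= n.y <= self.field_extent):
                raise ValueError(f"nucleus at ({n.x}, {n.y}) outside field extent")

    @property
    def positions(self) -> np.ndarray:
        return np.array([[n.x, n.y] for n in self.nuclei]).reshape(-1, 2)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SlidePhantom":
        d = json.loads(Path(path).read_text())
        d["nuclei"] = [Nucleus(**n) for n in d["nuclei"]]
        return cls(**d)


@dataclass
class ImageTile:
    """One camera frame with the stage state that produced it."""

    pixels: np.ndarray  # (rows, cols), counts
    stage_xy: tuple[float, float]  # commanded stage position, µm
    z: float  # focus offset, µm
    pixel_size: float  # µm/px

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")

    def save(self, path: str | Path) -> Path:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.pixels.astype(np.float32))
        return path


class PlacementError(RuntimeError):
    """The field is too small to place the requested nuclei at the required spacing."""


class StageLimitError(RuntimeError):
    """Commanded stage motion outside the configured travel range."""


# ---------------------------------------------------------------------------
# Slide generation


def generate_slide(
    n_nuclei: int,
    clustering: float = 0.0,
    params: SlideParams | None = None,
    seed: int = 0,
) -> SlidePhantom:
    """Place ``n_nuclei`` nuclei, a ``clustering`` fraction of them in close pairs.

    Non-clustered nuclei keep a minimum pairwise spacing of
    ``params.isolation_um``; clustered pairs sit closer than that (mimicking
    touching cells that risk double targeting).
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    if not 0.0 <= clustering <= 1.0:
        raise ValueError("clustering must be in [0, 1]")
    p = params or SlideParams()
    rng = np.random.default_rng(seed)

    n_paired = 2 * int(round(clustering * n_nuclei / 2.0))
    n_anchors = n_paired // 2
    n_singles = n_nuclei - n_paired
    pair_max = p.pair_distance[1]
    margin = pair_max + 2.0 * p.spot_radius
    lo, hi = margin, p.field_extent - margin
    if hi <= lo:
        raise PlacementError("field extent too small for the placement margins")
    # anchors and singles must clear isolation even after a pair partner is
    # attached, hence the inflated spacing
    spacing = p.isolation_um + 2.0 * pair_max

    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_singles + n_anchors:
        attempts += 1
        if attempts > 20000 * (n_singles + n_anchors + 1):
            raise PlacementError(
                f"could not place {n_nuclei} nuclei at spacing {spacing} µm "
                f"in a {p.field_extent} µm field"
            )
        cand = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(cand - q)) >= spacing for q in placed):
            placed.append(cand)

    coords = list(placed[:n_singles])
    for anchor in placed[n_singles:]:
        while True:
            d = rng.uniform(*p.pair_distance)
            ang = rng.uniform(0, 2 * np.pi)
            partner = anchor + d * np.array([np.cos(ang), np.sin(ang)])
            if lo <= partner[0] <= hi and lo <= partner[1] <= hi:
                break
        coords.append(anchor)
        coords.append(partner)

    nuclei = []
    for xy in coords:
        amp = p.amplitude * float(np.exp(rng.normal(0.0, p.amplitude_jitter)))
        label = p.class_labels[int(rng.integers(0, len(p.class_labels)))]
        nuclei.append(Nucleus(float(xy[0]), float(xy[1]), label, amp, p.spot_radius))
    return SlidePhantom(
        nuclei=nuclei,
        z_spot=p.z_spot,
        field_extent=p.field_extent,
        background=p.background,
        z_envelope=p.z_envelope,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Image rendering

#: axial width (µm) over which focal-plane edge contrast turns on / decays
_HALO_TURN_ON = 2.0
_HALO_DECAY = 10.0
_HALO_REL_AMP = 0.3


def _spot_envelope(z: float, z_spot: float, zeta: float) -> float:
    return float(np.exp(-((z - z_spot) ** 2) / (2.0 * zeta**2)))


def _halo_envelope(z: float) -> float:
    # zero exactly at focus, rises over ~2 µm, decays over ~10 µm: bright-field
    # contrast of a phase object is minimal in focus and grows with defocus
    return float((1.0 - np.exp(-(z**2) / (2.0 * _HALO_TURN_ON**2)))
                 * np.exp(-(z**2) / (2.0 * _HALO_DECAY**2)))


def render_image(
    ph: SlidePhantom,
    cam: CameraModel | None,
    stage_xy: tuple[float, float],
    z: float,
    fov: tuple[int, int] = (256, 256),
    pixel_size: float = 0.5,
    noise: bool = True,
    seed: int | None = None,
) -> ImageTile:
    """Render the camera view at a stage position and focus offset.

    Each in-view nucleus contributes an isotropic Gaussian bright spot whose
    amplitude is scaled by ``exp(-(z - z_spot)^2 / 2ζ^2)``; near focus only a
    faint edge ring remains.  Shot noise (Poisson) and read noise (Gaussian)
    are applied when ``noise`` is true and a camera model is given.

    Pixel rows run along decreasing stage *y*, columns along increasing *x*;
    the tile centre images the commanded stage position.
    """
    rows, cols = int(fov[0]), int(fov[1])
    if rows <= 0 or cols <= 0:
        raise ValueError("fov must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    sx, sy = float(stage_xy[0]), float(stage_xy[1])
    img = np.full((rows, cols), ph.background, dtype=float)

    env_spot = _spot_envelope(z, ph.z_spot, ph.z_envelope)
    env_halo = _halo_envelope(z)
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    half_r, half_c = (rows - 1) / 2.0, (cols - 1) / 2.0
    view = max(rows, cols) * pixel_size

    for n in ph.nuclei:
        col_n = (n.x - sx) / pixel_size + half_c
        row_n = (sy - n.y) / pixel_size + half_r
        if not (-view <= col_n <= cols + view and -view <= row_n <= rows + view):
            continue
        sig_px = n.spot_radius / pixel_size
        d2 = (rr - row_n) ** 2 + (cc - col_n) ** 2
        if env_spot > 1e-12:
            img += n.amplitude * env_spot * np.exp(-d2 / (2.0 * sig_px**2))
        if env_halo > 1e-12:
            ring_r = 2.5 * sig_px
            ring_w = 0.8 * sig_px
            d = np.sqrt(d2)
            img += (_HALO_REL_AMP * n.amplitude * env_halo
                    * np.exp(-((d - ring_r) ** 2) / (2.0 * ring_w**2)))

    if noise and cam is not None:
        if seed is None:
            ent = (int(ph.seed), int(round(sx * 1000)) & 0x7FFFFFFF,
                   int(round(sy * 1000)) & 0x7FFFFFFF, int(round(z * 1000)) & 0x7FFFFFFF)
            rng = np.random.default_rng(np.random.SeedSequence(ent))
        else:
            rng = np.random.default_rng(seed)
        img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        img = img + rng.normal(0.0, cam.read_noise_sd, size=img.shape)
        img = img * cam.gain
        img = np.clip(img, 0.0, None)
    return ImageTile(pixels=img, stage_xy=(sx, sy), z=float(z), pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Spectral phantom

# shared cell bands: (centre cm^-1, Gaussian sigma cm^-1, amplitude e/s).
# Amplitudes give strong bands of a few thousand electrons at a 10 s
# acquisition, typical of nucleus spectra on a 532 nm system.
_BASE_PEAKS: tuple[tuple[float, float, float], ...] = (
    (622, 5, 60), (645, 5, 50), (680, 6, 55), (720, 6, 80), (760, 5, 70),
    (789, 5, 120), (830, 6, 50), (855, 6, 60), (936, 6, 50), (1003, 4, 200),
    (1032, 5, 90), (1093, 7, 100), (1126, 5, 70), (1208, 6, 50), (1250, 10, 110),
    (1303, 7, 120), (1340, 7, 100), (1370, 6, 60), (1424, 6, 50), (1449, 8, 160),
    (1490, 6, 80), (1578, 7, 90), (1607, 5, 50), (1660, 9, 180),
)

DISCRIMINATING_BANDS: tuple[float, ...] = (789.0, 1003.0, 1490.0)


def _default_peak_table() -> dict[str, list[tuple[float, float, float]]]:
    low = [tuple(p) for p in _BASE_PEAKS]
    high = [
        (c, w, a * 1.15) if c in DISCRIMINATING_BANDS else (c, w, a)
        for (c, w, a) in _BASE_PEAKS
    ]
    return {"high_grade": high, "low_grade": low}


@dataclass
class SpectralPhantomParams:
    """Generative model for synthetic cell spectra.

    A raw spectrum is ``cr * R_class + cb * Glass + baseline + dark`` in
    electrons, then shot noise, read noise and cosmic-ray spikes.  The two
    default classes share every band except the discriminating ones
    (789/1003/1490 cm^-1, +15% amplitude in the high-grade class).
    """

    peaks: dict[str, list[tuple[float, float, float]]] = field(default_factory=_default_peak_table)
    glass_humps: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(1090.0, 80.0, 50.0), (1350.0, 140.0, 25.0), (800.0, 160.0, 15.0)]
    )
    baseline_order: int = 3
    baseline_offset_range: tuple[float, float] = (30.0, 80.0)  # e/s, constant term
    baseline_coeff_range: float = 15.0  # e/s, higher Legendre terms, uniform ±
    cr_sigma: float = 0.15  # lognormal sd of the cell weight (focus variation)
    cb_sigma: float = 0.20  # lognormal sd of the substrate weight
    cosmic_ray_rate: float = 0.02  # spikes per second of acquisition
    cosmic_ray_amp: tuple[float, float] = (20.0, 200.0)  # × local noise sd
    cosmic_ray_width: tuple[int, int] = (1, 3)  # channels

    def noise_free(self) -> "SpectralPhantomParams":
        """Copy with baseline randomness, substrate and cosmic rays disabled."""
        return dataclasses.replace(
            self,
            glass_humps=[],
            baseline_offset_range=(0.0, 0.0),
            baseline_coeff_range=0.0,
            cr_sigma=0.0,
            cb_sigma=0.0,
            cosmic_ray_rate=0.0,
        )


def class_signature(label: str, p: SpectralPhantomParams, axis: WavenumberAxis) -> np.ndarray:
    """Noise-free class signature R (electrons/second) on the axis."""
    if label not in p.peaks:
        raise KeyError(f"unknown class {label!r}; have {sorted(p.peaks)}")
    wn = axis.values
    sig = np.zeros_like(wn)
    for c, w, a in p.peaks[label]:
        sig += a * np.exp(-((wn - c) ** 2) / (2.0 * w**2))
    return sig


def glass_profile(p: SpectralPhantomParams, axis: WavenumberAxis) -> np.ndarray:
    """Smooth glass-substrate background (electrons/second) on the axis."""
    wn = axis.values
    g = np.zeros_like(wn)
    for c, w, a in p.glass_humps:
        g += a * np.exp(-((wn - c) ** 2) / (2.0 * w**2))
    return g


def _baseline(p: SpectralPhantomParams, axis: WavenumberAxis, rng: np.random.Generator) -> np.ndarray:
    t = np.interp(axis.values, (axis.values[0], axis.values[-1]), (-1.0, 1.0))
    coeffs = np.zeros(p.baseline_order + 1)
    coeffs[0] = rng.uniform(*p.baseline_offset_range)
    if p.baseline_order >= 1 and p.baseline_coeff_range > 0:
        coeffs[1:] = rng.uniform(-p.baseline_coeff_range, p.baseline_coeff_range,
                                 size=p.baseline_order)
    return np.polynomial.legendre.legval(t, coeffs)


def generate_spectrum(
    label: str,
    p: SpectralPhantomParams,
    cam: CameraModel,
    t_acq: float,
    axis: WavenumberAxis,
    seed: int = 0,
    cr: float | None = None,
    cb: float | None = None,
    noise: bool = True,
    id: str = "phantom",
) -> Spectrum:
    """Generate one synthetic cell spectrum (see :func:`generate_spectrum_set`
    for the dataset form that also returns cosmic-ray ground truth)."""
    s, _ = _generate_spectrum_with_truth(label, p, cam, t_acq, axis, seed, cr, cb, noise, id)
    return s


def _generate_spectrum_with_truth(
    label: str,
    p: SpectralPhantomParams,
    cam: CameraModel,
    t_acq: float,
    axis: WavenumberAxis,
    seed: int,
    cr: float | None,
    cb: float | None,
    noise: bool,
    id: str,
) -> tuple[Spectrum, list[int]]:
    if t_acq <= 0:
        raise ValueError("t_acq must be > 0")
    rng = np.random.default_rng(seed)
    R = class_signature(label, p, axis) if label is not None else np.zeros(len(axis))
    G = glass_profile(p, axis)
    w_r = float(np.exp(rng.normal(0.0, p.cr_sigma))) if cr is None else float(cr)
    w_b = float(np.exp(rng.normal(0.0, p.cb_sigma))) if cb is None else float(cb)
    base = _baseline(p, axis, rng)
    electrons = t_acq * (w_r * R + w_b * G + base + cam.dark_current)
    electrons = np.clip(electrons, 0.0, None)

    if noise:
        counts = rng.poisson(electrons).astype(float)
        counts += rng.normal(0.0, cam.read_noise_sd, size=counts.shape)
    else:
        counts = electrons.copy()
    counts *= cam.gain

    spike_channels: list[int] = []
    if p.cosmic_ray_rate > 0:
        n_spikes = int(rng.poisson(p.cosmic_ray_rate * t_acq))
        local_sd = cam.gain * np.sqrt(cam.read_noise_sd**2 + electrons)
        for _ in range(n_spikes):
            width = int(rng.integers(p.cosmic_ray_width[0], p.cosmic_ray_width[1] + 1))
            c0 = int(rng.integers(0, len(axis) - width + 1))
            for j in range(width):
                amp = rng.uniform(*p.cosmic_ray_amp) * float(local_sd[c0 + j])
                counts[c0 + j] += amp
                spike_channels.append(c0 + j)
    return Spectrum(axis, counts, id), sorted(set(spike_channels))


def generate_spectrum_set(
    labels: Sequence[str],
    p: SpectralPhantomParams,
    cam: CameraModel,
    t_acq: float,
    axis: WavenumberAxis,
    seed: int = 0,
    noise: bool = True,
) -> SpectrumSet:
    """Generate one spectrum per label; cosmic-ray ground truth is stored in
    each spectrum's ``meta["cosmic_channels"]``."""
    ss_seed = np.random.SeedSequence(seed)
    child_seeds = ss_seed.generate_state(len(labels))
    spectra, truths = [], []
    for i, (lab, s) in enumerate(zip(labels, child_seeds)):
        sp, truth = _generate_spectrum_with_truth(
            lab, p, cam, t_acq, axis, int(s) & 0x7FFFFFFF, None, None, noise, f"s{i:04d}"
        )
        spectra.append(sp)
        truths.append(truth)
    out = SpectrumSet.from_spectra(spectra, labels=list(labels))
    for m, truth in zip(out.meta, truths):
        m["cosmic_channels"] = truth
        m["t_acq_s"] = t_acq
    return out


def inject_cosmic_rays(
    ss: SpectrumSet,
    cam: CameraModel,
    p: SpectralPhantomParams,
    n_per_spectrum: int = 1,
    seed: int = 0,
) -> tuple[SpectrumSet, list[list[int]]]:
    """Inject a known number of cosmic-ray spikes into every spectrum.

    Amplitudes are drawn from ``p.cosmic_ray_amp`` times the local noise sd
    (estimated from the camera model and the observed counts), widths from
    ``p.cosmic_ray_width``; spikes never overlap within a spectrum.  Returns
    the spiked set and the ground-truth flagged channels per spectrum.
    """
    rng = np.random.default_rng(seed)
    X = ss.matrix.copy()
    truth: list[list[int]] = []
    n_ch = X.shape[1]
    for i in range(X.shape[0]):
        local_sd = cam.gain * np.sqrt(
            cam.read_noise_sd**2 + np.clip(X[i] / cam.gain, 0.0, None)
        )
        channels: list[int] = []
        occupied: set[int] = set()
        for _ in range(n_per_spectrum):
            width = int(rng.integers(p.cosmic_ray_width[0], p.cosmic_ray_width[1] + 1))
            for _try in range(1000):
                c0 = int(rng.integers(0, n_ch - width + 1))
                # keep one clean guard channel between spikes
                span = set(range(c0 - 1, c0 + width + 1))
                if not span & occupied:
                    break
            occupied |= span
            for j in range(c0, c0 + width):
                X[i, j] += rng.uniform(*p.cosmic_ray_amp) * float(local_sd[j])
                channels.append(j)
        truth.append(sorted(channels))
    return ss.with_matrix(X), truth


# ---------------------------------------------------------------------------
# Simulated instrument


class SimulatedInstrument:
    """Stage + lamp + laser + camera stack backed by a slide phantom.

    Exposes the acquisition contract the orchestrator drives:
    ``move_stage(x, y)``, ``set_z(z)``, ``snap_image()`` and
    ``acquire_spectrum(t_acq)``.  Stage motion is quantised to the encoder
    resolution (0.1 µm) and perturbed by repeatability jitter; the laser
    excites the nucleus nearest the (true) stage position when within its
    spot radius, otherwise only glass and baseline are recorded.
    """

    def __init__(
        self,
        phantom: SlidePhantom,
        cam: CameraModel | None = None,
        spectral_params: SpectralPhantomParams | None = None,
        axis: WavenumberAxis | None = None,
        fov: tuple[int, int] = (256, 256),
        pixel_size: float = 0.5,
        stage_resolution: float = 0.1,
        stage_repeatability: float = 0.25,
        travel_margin: float = 100.0,
        seed: int | None = None,
    ) -> None:
        self.phantom = phantom
        self.cam = cam or CameraModel()
        self.spectral_params = spectral_params or SpectralPhantomParams()
        self.axis = axis or default_axis()
        self.fov = fov
        self.pixel_size = pixel_size
        self.stage_resolution = stage_resolution
        self.stage_repeatability = stage_repeatability
        self.travel = (-travel_margin, phantom.field_extent + travel_margin)
        self._rng = np.random.default_rng(phantom.seed if seed is None else seed)
        self._xy_cmd = (0.0, 0.0)
        self._xy_true = (0.0, 0.0)
        self._z = 0.0
        self.visited: list[tuple[float, float]] = []

    # -- stage -------------------------------------------------------------
    def move_stage(self, x: float, y: float) -> tuple[float, float]:
        lo, hi = self.travel
        if not (lo <= x <= hi and lo <= y <= hi):
            raise StageLimitError(f"commanded ({x:.1f}, {y:.1f}) outside travel [{lo}, {hi}] µm")
        q = self.stage_resolution
        qx, qy = round(x / q) * q, round(y / q) * q
        jx, jy = self._rng.normal(0.0, self.stage_repeatability / 2.0, size=2)
        self._xy_cmd = (qx, qy)
        self._xy_true = (qx + jx, qy + jy)
        self.visited.append(self._xy_cmd)
        return self._xy_cmd

    def set_z(self, z: float) -> None:
        self._z = float(z)

    @property
    def position(self) -> tuple[float, float]:
        return self._xy_cmd

    # -- camera ------------------------------------------------------------
    def snap_image(self) -> ImageTile:
        tile = render_image(
            self.phantom,
            self.cam,
            self._xy_true,
            self._z,
            fov=self.fov,
            pixel_size=self.pixel_size,
            noise=True,
            seed=int(self._rng.integers(0, 2**31 - 1)),
        )
        # report the commanded position: that is all a real stage tells us
        tile.stage_xy = self._xy_cmd
        return tile

    # -- spectrometer ------------------------------------------------------
    def acquire_spectrum(self, t_acq: float) -> Spectrum:
        x, y = self._xy_true
        seed = int(self._rng.integers(0, 2**31 - 1))
        target: Nucleus | None = None
        if self.phantom.nuclei:
            pos = self.phantom.positions
            d = np.hypot(pos[:, 0] - x, pos[:, 1] - y)
            i = int(np.argmin(d))
            if d[i] <= self.phantom.nuclei[i].spot_radius:
                target = self.phantom.nuclei[i]
        if target is None:
            sp, _ = _generate_spectrum_with_truth(
                next(iter(self.spectral_params.peaks)), self.spectral_params, self.cam,
                t_acq, self.axis, seed, cr=0.0, cb=None, noise=True, id="substrate",
            )
            return sp
        return generate_spectrum(
            target.label, self.spectral_params, self.cam, t_acq, self.axis,
            seed=seed, id=f"cell_{x:.1f}_{y:.1f}",
        )
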