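"""Synthetic capture emulator.

Generates raw multi-angle hyperspectral capture sets with known ground truth
(per-class albedo spectra, surface relief, lesion masks), so that the whole
downstream pipeline — reflectance calibration, photometric stereo, depth
integration, window sampling, CNN training and majority voting — can be
exercised and tested without any acquired data.

The forward model is Lambertian: per band ``b`` and light direction ``l``,

    counts = dark + (white - dark) * albedo_b * max(0, n . l) + noise

with surface normals ``n`` derived from the phantom height field.  White
reference frames are rendered from a unit-albedo flat target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import gaussian_filter, gaussian_filter1d

#: All class labels understood by the emulator and the classifiers.
HEALTHY = "healthy"
PIGMENTED_CLASSES = ("MM", "PN")
NONPIGMENTED_CLASSES = ("BCC", "SCC", "ID")
LESION_CLASSES = PIGMENTED_CLASSES + NONPIGMENTED_CLASSES
ALL_CLASSES = (HEALTHY,) + LESION_CLASSES

_CLASS_INDEX = {name: i for i, name in enumerate(ALL_CLASSES)}

N_BANDS = 33
WAVELENGTH_MIN_NM = 477.0
WAVELENGTH_MAX_NM = 891.0


# --------------------------------------------------------------------------- #
# configuration types
# --------------------------------------------------------------------------- #


def default_wavelengths() -> np.ndarray:
    """33 evenly spaced band centers spanning the device's 477-891 nm range."""
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, N_BANDS)


def _default_vis_band_count(wavelengths: np.ndarray) -> int:
    """Bands strictly below 700 nm form the VIS group (conventional boundary)."""
    return int(np.searchsorted(np.asarray(wavelengths), 700.0, side="left"))


@dataclass(frozen=True)
class SensorConfig:
    """Geometry and radiometry of the emulated imager."""

    height_px: int = 256
    width_px: int = 256
    wavelengths_nm: tuple = field(default_factory=lambda: tuple(default_wavelengths()))
    vis_band_count: int | None = None
    dark_level: float = 64.0
    white_level: float = 4000.0
    noise_sd: float = 0.0
    pixel_pitch_um: float = 24.0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.size != N_BANDS:
            raise ValueError(f"expected {N_BANDS} wavebands, got {wl.size}")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN_NM or wl[-1] > WAVELENGTH_MAX_NM:
            raise ValueError(
                f"wavelengths must lie in [{WAVELENGTH_MIN_NM}, {WAVELENGTH_MAX_NM}] nm"
            )
        if self.vis_band_count is None:
            object.__setattr__(self, "vis_band_count", _default_vis_band_count(wl))
        if not 0 < self.vis_band_count < N_BANDS:
            raise ValueError("vis_band_count must split the 33 bands into two groups")
        if not self.dark_level < self.white_level:
            raise ValueError("dark_level must be below white_level")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.asarray(self.wavelengths_nm, dtype=float)

    @property
    def vis_wavelengths(self) -> np.ndarray:
        return self.wavelengths[: self.vis_band_count]

    @property
    def vnir_wavelengths(self) -> np.ndarray:
        return self.wavelengths[self.vis_band_count :]

    @property
    def shape(self) -> tuple:
        return (self.height_px, self.width_px)


def default_light_directions(zenith_deg: float = 40.0, azimuths_deg=(0.0, 120.0, 240.0)) -> np.ndarray:
    """Three symmetric illumination directions (well-conditioned 3x3 system)."""
    z = np.deg2rad(zenith_deg)
    out = []
    for a in np.deg2rad(np.asarray(azimuths_deg, dtype=float)):
        out.append([np.sin(z) * np.cos(a), np.sin(z) * np.sin(a), np.cos(z)])
    return np.asarray(out)


@dataclass(frozen=True)
class LightGeometry:
    """Three unit vectors pointing from the surface toward each LED set."""

    directions: np.ndarray = field(default_factory=default_light_directions)

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        if d.shape != (3, 3):
            raise ValueError("exactly three 3-vectors required")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("light directions must be unit vectors")
        if np.any(d[:, 2] <= 0):
            raise ValueError("light directions must have positive z-component")
        if abs(np.linalg.det(d)) < 1e-9:
            raise ValueError("light direction matrix is singular")
        object.__setattr__(self, "directions", d)

    @property
    def matrix(self) -> np.ndarray:
        return self.directions


@dataclass(frozen=True)
class SpectrumParams:
    """Knobs of the per-class reflectance generator.

    ``separation`` linearly interpolates every lesion spectrum between the
    healthy-skin spectrum (0) and its fully separated shape (1); sweeping it
    down makes the classes progressively indistinguishable.  ``min_separation``
    documents the per-band gap guaranteed between healthy skin and every
    lesion class at separation 1.
    """

    separation: float = 1.0
    jitter_sd: float = 0.005
    smoothness_bound: float = 0.12
    min_separation: float = 0.05
    hem_width_nm: float = 18.0


# Base curve coefficients: reflectance = offset + slope*u**shape - hem*hem(wl),
# u = normalized wavelength.  Offsets are spread so that healthy skin keeps a
# per-band gap >= ~0.09 from every lesion class and pairwise mean distances
# stay above SpectrumParams.min_separation.  MM rises convexly (shape 3) so
# lesion-border mixtures of MM and healthy skin do not collapse onto the PN
# curve.
_BASE_CURVES = {
    "healthy": (0.76, 0.10, 0.02, 1.0),
    "MM": (0.10, 0.22, 0.0, 3.0),
    "PN": (0.26, 0.26, 0.0, 1.0),
    "BCC": (0.58, 0.12, 0.14, 1.0),
    "SCC": (0.44, 0.14, 0.10, 1.0),
    "ID": (0.66, 0.08, 0.01, 1.0),
}


def _hem_profile(wavelengths: np.ndarray, width_nm: float) -> np.ndarray:
    """Haemoglobin-like double absorption dip near 545 and 575 nm."""
    wl = np.asarray(wavelengths, dtype=float)
    return np.exp(-(((wl - 545.0) / width_nm) ** 2)) + np.exp(
        -(((wl - 575.0) / width_nm) ** 2)
    )


def _raw_curve(name: str, wavelengths: np.ndarray, params: SpectrumParams, seed: int) -> np.ndarray:
    offset, slope, hem_depth, shape = _BASE_CURVES[name]
    wl = np.asarray(wavelengths, dtype=float)
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _CLASS_INDEX[name]]))
    jitter = rng.standard_normal(wl.size)
    jitter = gaussian_filter1d(jitter, 2.0, mode="nearest")
    jitter = params.jitter_sd * jitter / max(np.std(jitter), 1e-12)
    if name in PIGMENTED_CLASSES:
        # Melanin slope: strictly increasing by construction — jitter modulates
        # the positive per-band increments instead of the curve itself.
        incr = np.diff(offset + slope * u**shape)
        rel = np.clip(jitter[1:] / max(slope / wl.size, 1e-12) * 0.05, -0.5, 0.5)
        curve = offset + jitter[0] + np.concatenate([[0.0], np.cumsum(incr * (1.0 + rel))])
    else:
        curve = (offset + slope * u**shape
                 - hem_depth * _hem_profile(wl, params.hem_width_nm) + jitter)
    return curve


def class_spectrum(
    lesion_class: str,
    wavelengths=None,
    params: SpectrumParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-band true albedo for one class.

    Deterministic given ``seed``; lesion spectra are interpolated toward the
    healthy spectrum by ``params.separation``.
    """
    if lesion_class not in ALL_CLASSES:
        raise ValueError(f"unknown class label {lesion_class!r}; expected one of {ALL_CLASSES}")
    if wavelengths is None:
        wavelengths = default_wavelengths()
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be sorted ascending")
    params = params or SpectrumParams()
    healthy = _raw_curve(HEALTHY, wl, params, seed)
    if lesion_class == HEALTHY:
        curve = healthy
    else:
        target = _raw_curve(lesion_class, wl, params, seed)
        curve = healthy + params.separation * (target - healthy)
    return np.clip(curve, 0.02, 0.98)


# --------------------------------------------------------------------------- #
# phantoms
# --------------------------------------------------------------------------- #


@dataclass
class ScenePhantom:
    """Ground-truth scene: relief, per-band albedo and the lesion mask."""

    height_map: np.ndarray
    albedo_cube: np.ndarray
    lesion_mask: np.ndarray
    lesion_class: str
    fov_mask: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self):
        if self.albedo_cube.shape[:2] != self.height_map.shape:
            raise ValueError("albedo_cube and height_map spatial shapes differ")
        if np.any(self.lesion_mask & ~self.fov_mask):
            raise ValueError("lesion_mask must lie inside fov_mask")


def fov_radius(sensor: SensorConfig, inset_px: int = 4) -> float:
    return min(sensor.height_px, sensor.width_px) / 2.0 - inset_px


def make_phantom(
    sensor: SensorConfig,
    lesion_class: str,
    lesion_radius_px: int,
    seed: int,
    params: SpectrumParams | None = None,
    healthy_annulus_px: int = 40,
    dome_height_px: float = 6.0,
    relief_sd_px: float = 1.0,
    relief_scale_px: float = 18.0,
    texture_sd: float = 0.03,
    n_artifacts: int = 6,
    artifact_radius_px: float = 3.0,
) -> ScenePhantom:
    """Smooth random relief plus a raised lesion dome with a class spectrum.

    Besides the chromophore-driven spectra, each scene carries a few small
    broadband artifacts on the surrounding skin — dark (hair-like) and bright
    (reflection-like) spots, as seen on real captures — which anchor the
    dynamic range of every band.

    Raises if the lesion (plus the required healthy annulus) does not fit in
    the circular field of view.
    """
    if lesion_radius_px < 1:
        raise ValueError("lesion_radius_px must be >= 1")
    if lesion_class not in ALL_CLASSES:
        raise ValueError(f"unknown class label {lesion_class!r}")
    params = params or SpectrumParams()
    h, w = sensor.shape
    r_fov = fov_radius(sensor)
    if lesion_radius_px + healthy_annulus_px > r_fov:
        need = 2 * (lesion_radius_px + healthy_annulus_px + 4)
        raise ValueError(
            f"lesion radius {lesion_radius_px} px with a {healthy_annulus_px} px healthy "
            f"annulus needs a frame of at least {need}x{need} px (got {h}x{w})"
        )
    rng = np.random.default_rng(seed)

    rows = np.arange(h)[:, None] - (h - 1) / 2.0
    cols = np.arange(w)[None, :] - (w - 1) / 2.0
    rr = np.hypot(rows, cols)
    fov = rr <= r_fov
    lesion = rr <= lesion_radius_px

    base = gaussian_filter(rng.standard_normal((h, w)), relief_scale_px, mode="wrap")
    base *= relief_sd_px / max(np.std(base), 1e-12)
    dome_w = 0.6 * lesion_radius_px
    height = base + dome_height_px * np.exp(-((rr / dome_w) ** 2))

    healthy_spec = class_spectrum(HEALTHY, sensor.wavelengths, params, seed)
    lesion_spec = class_spectrum(lesion_class, sensor.wavelengths, params, seed)
    albedo = np.where(lesion[..., None], lesion_spec, healthy_spec)
    texture = gaussian_filter(rng.standard_normal((h, w)), 6.0, mode="reflect")
    texture *= texture_sd / max(np.std(texture), 1e-12)
    albedo = np.clip(albedo * (1.0 + texture[..., None]), 0.01, 0.99)

    # hair-like dark and reflection-like bright broadband spots on the
    # surrounding skin (kept off the lesion)
    for k in range(n_artifacts):
        for _ in range(50):
            cr = rng.uniform(-r_fov + 8, r_fov - 8)
            cc = rng.uniform(-r_fov + 8, r_fov - 8)
            if np.hypot(cr, cc) < r_fov - 6 and np.hypot(cr, cc) > lesion_radius_px + 6:
                break
        spot = np.hypot(rows - cr, cols - cc) <= artifact_radius_px
        albedo[spot] = 0.02 if k % 2 == 0 else 0.98

    return ScenePhantom(
        height_map=height,
        albedo_cube=albedo,
        lesion_mask=lesion & fov,
        lesion_class=lesion_class,
        fov_mask=fov,
        wavelengths_nm=sensor.wavelengths,
    )


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #


def spectral_gradient(height: np.ndarray) -> tuple:
    """Gradients (d/dcol, d/drow) via Fourier differentiation.

    Matches the transfer function of the Frankot-Chellappa depth integrator,
    so render -> solve -> integrate round-trips to machine precision.  Height
    fields are generated with periodic statistics (see make_phantom) so the
    periodic basis introduces no edge ringing.
    """
    h, w = height.shape
    wy = 2.0 * np.pi * sp_fft.fftfreq(h)[:, None]
    wx = 2.0 * np.pi * sp_fft.fftfreq(w)[None, :]
    spec = sp_fft.fft2(height)
    gx = sp_fft.ifft2(1j * wx * spec).real
    gy = sp_fft.ifft2(1j * wy * spec).real
    return gx, gy


def surface_normals(height: np.ndarray) -> np.ndarray:
    """Unit normals of the height field, (H, W, 3), z > 0."""
    gx, gy = spectral_gradient(height)
    n = np.stack([-gx, -gy, np.ones_like(height)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return n


@dataclass
class RawCaptureSet:
    """Six raw band-stacks (2 channel groups x 3 lights) plus references."""

    frames: dict  # (group, light_index) -> (H, W, n_bands) counts
    dark_frame: np.ndarray
    white_frames: dict  # group -> (H, W, n_bands) counts
    band_centers: dict  # group -> wavelengths (nm)
    light_geometry: LightGeometry
    sensor: SensorConfig

    GROUPS = ("vis", "vnir")

    def __post_init__(self):
        if len(self.frames) != 6:
            raise ValueError("expected 6 raw stacks (2 groups x 3 lights)")
        for key, stack in self.frames.items():
            group, _ = key
            if stack.shape[-1] != len(self.band_centers[group]):
                raise ValueError(f"band count mismatch in raw stack {key}")
            if np.any(stack < 0):
                raise ValueError("raw counts must be non-negative")


def render_capture(
    phantom: ScenePhantom,
    lights: LightGeometry,
    sensor: SensorConfig,
    seed: int = 0,
    dtype=np.float64,
) -> RawCaptureSet:
    """Lambertian forward render of a phantom into six raw stacks."""
    if phantom.height_map.shape != sensor.shape:
        raise ValueError("phantom and sensor shapes disagree")
    rng = np.random.default_rng(seed)
    dark, white, sd = sensor.dark_level, sensor.white_level, sensor.noise_sd
    gain = white - dark

    normals = surface_normals(phantom.height_map)
    shading = np.einsum("hwc,lc->lhw", normals, lights.matrix)
    np.maximum(shading, 0.0, out=shading)

    nv = sensor.vis_band_count
    band_slices = {"vis": slice(0, nv), "vnir": slice(nv, N_BANDS)}
    band_centers = {
        "vis": sensor.vis_wavelengths.copy(),
        "vnir": sensor.vnir_wavelengths.copy(),
    }

    def noisy(arr):
        if sd > 0:
            arr = arr + rng.normal(0.0, sd, size=arr.shape)
        return np.maximum(arr, 0.0).astype(dtype, copy=False)

    frames = {}
    for group, sl in band_slices.items():
        albedo = phantom.albedo_cube[:, :, sl].astype(dtype, copy=False)
        for li in range(3):
            signal = dark + gain * albedo * shading[li][..., None].astype(dtype)
            frames[(group, li)] = noisy(signal)
    white_frames = {
        group: noisy(np.full(sensor.shape + (sl.stop - sl.start,), white, dtype=dtype))
        for group, sl in band_slices.items()
    }
    dark_frame = noisy(np.full(sensor.shape, dark, dtype=dtype))
    return RawCaptureSet(
        frames=frames,
        dark_frame=dark_frame,
        white_frames=white_frames,
        band_centers=band_centers,
        light_geometry=lights,
        sensor=sensor,
    )


# --------------------------------------------------------------------------- #
# cohorts
# --------------------------------------------------------------------------- #


@dataclass
class CohortItem:
    capture: RawCaptureSet
    annotation: np.ndarray  # binary ground-truth lesion mask
    label: str
    phantom: ScenePhantom


def make_cohort(
    n_lesions: int,
    class_mix: dict,
    sensor: SensorConfig,
    seed: int,
    lights: LightGeometry | None = None,
    params: SpectrumParams | None = None,
    radius_range: tuple | None = None,
    healthy_annulus_px: int = 40,
    dtype=np.float64,
    **phantom_kwargs,
) -> list:
    """One rendered capture per lesion, with per-lesion derived seeds."""
    if not class_mix:
        raise ValueError("class_mix must not be empty")
    if sum(class_mix.values()) != n_lesions:
        raise ValueError("class_mix counts must sum to n_lesions")
    for name in class_mix:
        if name not in ALL_CLASSES:
            raise ValueError(f"unknown class label {name!r}")
    lights = lights or LightGeometry()
    if radius_range is None:
        avail = fov_radius(sensor) - healthy_annulus_px
        radius_range = (int(0.60 * avail), int(0.72 * avail))

    labels = [name for name, count in sorted(class_mix.items()) for _ in range(count)]
    children = np.random.SeedSequence(seed).spawn(n_lesions)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    cohort = []
    for label, child in zip(labels, children):
        sub = child.generate_state(2)
        radius = int(rng.integers(radius_range[0], radius_range[1] + 1))
        phantom = make_phantom(
            sensor,
            label,
            radius,
            seed=int(sub[0]),
            params=params,
            healthy_annulus_px=healthy_annulus_px,
            **phantom_kwargs,
        )
        capture = render_capture(phantom, lights, sensor, seed=int(sub[1]), dtype=dtype)
        cohort.append(
            CohortItem(
                capture=capture,
                annotation=phantom.lesion_mask.copy(),
                label=label,
                phantom=phantom,
            )
        )
    return cohort


# --------------------------------------------------------------------------- #
# persistence: per-band TIFF stacks + JSON sidecar, masks as 8-bit PNG
# --------------------------------------------------------------------------- #


def save_capture(capture: RawCaptureSet, out_dir) -> None:
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (group, li), stack in capture.frames.items():
        tifffile.imwrite(out / f"raw_{group}_light{li}.tif", np.moveaxis(stack, -1, 0))
    for group, stack in capture.white_frames.items():
        tifffile.imwrite(out / f"white_{group}.tif", np.moveaxis(stack, -1, 0))
    tifffile.imwrite(out / "dark.tif", capture.dark_frame)
    sidecar = {
        "band_centers": {g: list(map(float, wl)) for g, wl in capture.band_centers.items()},
        "light_directions": capture.light_geometry.matrix.tolist(),
        "dark_level": capture.sensor.dark_level,
        "white_level": capture.sensor.white_level,
        "noise_sd": capture.sensor.noise_sd,
        "wavelengths_nm": list(map(float, capture.sensor.wavelengths)),
        "vis_band_count": capture.sensor.vis_band_count,
        "height_px": capture.sensor.height_px,
        "width_px": capture.sensor.width_px,
    }
    (out / "capture.json").write_text(json.dumps(sidecar, indent=2))


def load_capture(in_dir) -> RawCaptureSet:
    import tifffile

    src = Path(in_dir)
    meta = json.loads((src / "capture.json").read_text())
    sensor = SensorConfig(
        height_px=meta["height_px"],
        width_px=meta["width_px"],
        wavelengths_nm=tuple(meta["wavelengths_nm"]),
        vis_band_count=meta["vis_band_count"],
        dark_level=meta["dark_level"],
        white_level=meta["white_level"],
        noise_sd=meta["noise_sd"],
    )
    lights = LightGeometry(np.asarray(meta["light_directions"]))
    frames = {}
    for group in RawCaptureSet.GROUPS:
        for li in range(3):
            stack = tifffile.imread(src / f"raw_{group}_light{li}.tif")
            frames[(group, li)] = np.moveaxis(stack, 0, -1)
    white_frames = {
        group: np.moveaxis(tifffile.imread(src / f"white_{group}.tif"), 0, -1)
        for group in RawCaptureSet.GROUPS
    }
    return RawCaptureSet(
        frames=frames,
        dark_frame=tifffile.imread(src / "dark.tif"),
        white_frames=white_frames,
        band_centers={g: np.asarray(wl) for g, wl in meta["band_centers"].items()},
        light_geometry=lights,
        sensor=sensor,
    )


def save_mask(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(Path(path))) >= 128
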