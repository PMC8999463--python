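"""Raw-image pre-processing.

Reflectance calibration against dark/white references, per-waveband Lambertian
photometric stereo (albedo + surface normals from three light directions),
depth-map integration (Frankot-Chellappa), Gaussian smoothing, assembly of the
66-channel processed cube (33 albedo frames followed by 33 smoothed surface
models) and RGB reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import gaussian_filter

from hsiderm.synthdata import LightGeometry, RawCaptureSet

N_BANDS = 33
N_CHANNELS = 2 * N_BANDS


@dataclass
class ReflectanceCube:
    """Per-pixel per-band reflectance for one light direction."""

    values: np.ndarray  # (H, W, B)
    band_centers_nm: np.ndarray
    valid: np.ndarray | None = None  # (H, W) pixels with white > dark

    def __post_init__(self):
        self.band_centers_nm = np.asarray(self.band_centers_nm, dtype=float)
        if self.values.shape[-1] != self.band_centers_nm.size:
            raise ValueError("band count mismatch between values and band_centers_nm")
        if self.valid is None:
            self.valid = np.ones(self.values.shape[:2], dtype=bool)


@dataclass
class PhotometricProducts:
    albedo: np.ndarray  # (H, W, 33) in [0, 1]
    normals: np.ndarray  # (H, W, 33, 3) unit length, z > 0 where valid
    shadow_mask: np.ndarray  # (H, W, 33) True where the solve was invalid
    band_centers_nm: np.ndarray


@dataclass
class ProcessedCube:
    """(H, W, 66) stack: channels 0-32 albedo, 33-65 smoothed depth maps."""

    values: np.ndarray
    band_centers_nm: np.ndarray

    def __post_init__(self):
        if self.values.shape[-1] != N_CHANNELS:
            raise ValueError(f"processed cube must have {N_CHANNELS} channels")
        if np.asarray(self.band_centers_nm).size != N_BANDS:
            raise ValueError(f"expected {N_BANDS} band centers")

    @property
    def albedo(self) -> np.ndarray:
        return self.values[:, :, :N_BANDS]

    @property
    def depth(self) -> np.ndarray:
        return self.values[:, :, N_BANDS:]


# --------------------------------------------------------------------------- #
# calibration and merging
# --------------------------------------------------------------------------- #


def calibrate_reflectance(raw: np.ndarray, dark: np.ndarray, white: np.ndarray,
                          band_centers_nm=None) -> ReflectanceCube:
    """Flat-field calibration: R = (raw - dark) / (white - dark).

    Pixels whose white reference does not exceed the dark level get R = 0 and
    are flagged invalid.
    """
    raw = np.asarray(raw)
    dark = np.asarray(dark)
    white = np.asarray(white)
    if raw.shape != white.shape or dark.shape != raw.shape[:2]:
        raise ValueError(
            f"shape mismatch: raw {raw.shape}, dark {dark.shape}, white {white.shape}"
        )
    denom = white - dark[..., None]
    ok = denom > 0
    refl = np.zeros_like(raw, dtype=raw.dtype if raw.dtype.kind == "f" else np.float64)
    np.divide(raw - dark[..., None], denom, out=refl, where=ok)
    if band_centers_nm is None:
        band_centers_nm = np.arange(raw.shape[-1], dtype=float)
    return ReflectanceCube(values=refl, band_centers_nm=band_centers_nm,
                           valid=ok.all(axis=-1))


def calibrate_capture(capture: RawCaptureSet, dtype=None) -> list:
    """Calibrate all six raw stacks of a capture; returns 6 ReflectanceCubes
    keyed implicitly as [(group, light)] in capture order."""
    cubes = {}
    for (group, li), stack in capture.frames.items():
        cube = calibrate_reflectance(
            stack if dtype is None else stack.astype(dtype),
            capture.dark_frame if dtype is None else capture.dark_frame.astype(dtype),
            capture.white_frames[group] if dtype is None else capture.white_frames[group].astype(dtype),
            band_centers_nm=capture.band_centers[group],
        )
        cubes[(group, li)] = cube
    return cubes


def merge_channel_groups(vis: ReflectanceCube, vnir: ReflectanceCube) -> ReflectanceCube:
    """Concatenate the two channel groups of one light direction into a single
    33-band cube ordered by wavelength."""
    all_bands = np.concatenate([vis.band_centers_nm, vnir.band_centers_nm])
    if np.unique(all_bands).size != all_bands.size:
        raise ValueError("channel groups have overlapping band centers")
    if all_bands.size != N_BANDS:
        raise ValueError(f"merged cube must have {N_BANDS} bands, got {all_bands.size}")
    values = np.concatenate([vis.values, vnir.values], axis=-1)
    order = np.argsort(all_bands, kind="stable")
    return ReflectanceCube(
        values=values[:, :, order],
        band_centers_nm=all_bands[order],
        valid=vis.valid & vnir.valid,
    )


# --------------------------------------------------------------------------- #
# photometric stereo
# --------------------------------------------------------------------------- #


def solve_photometric_stereo(cubes, lights: LightGeometry) -> PhotometricProducts:
    """Per pixel and band, solve the Lambertian system I = rho * (n . l).

    g = L^-1 I, rho = ||g||, n = g / ||g||.  Pixels with any non-positive
    intensity, a zero solution, or a downward normal are flagged in the shadow
    mask and set to rho = 0, n = (0, 0, 1).  Albedo is clipped to [0, 1].
    """
    if len(cubes) != 3:
        raise ValueError("exactly three reflectance cubes required")
    bands = cubes[0].band_centers_nm
    for c in cubes[1:]:
        if not np.array_equal(c.band_centers_nm, bands):
            raise ValueError("cubes must share identical band sets")
    L = lights.matrix
    if abs(np.linalg.det(L)) < 1e-9:
        raise ValueError("light direction matrix is singular")
    linv_t = np.linalg.inv(L).T.astype(cubes[0].values.dtype, copy=False)

    h, w, nb = cubes[0].values.shape
    albedo = np.empty((h, w, nb), dtype=cubes[0].values.dtype)
    normals = np.empty((h, w, nb, 3), dtype=cubes[0].values.dtype)
    shadow = np.empty((h, w, nb), dtype=bool)
    valid_px = cubes[0].valid & cubes[1].valid & cubes[2].valid
    for b in range(nb):  # band loop keeps peak memory flat at full resolution
        intens = np.stack([c.values[:, :, b] for c in cubes], axis=-1)
        g = intens @ linv_t
        rho = np.linalg.norm(g, axis=-1)
        bad = (intens <= 0).any(axis=-1) | (rho == 0) | (g[..., 2] <= 0) | ~valid_px
        with np.errstate(invalid="ignore", divide="ignore"):
            n = g / rho[..., None]
        n[bad] = (0.0, 0.0, 1.0)
        rho[bad] = 0.0
        albedo[:, :, b] = np.clip(rho, 0.0, 1.0)
        normals[:, :, b] = n
        shadow[:, :, b] = bad
    return PhotometricProducts(
        albedo=albedo, normals=normals, shadow_mask=shadow, band_centers_nm=bands
    )


# --------------------------------------------------------------------------- #
# depth integration and smoothing
# --------------------------------------------------------------------------- #


def integrate_depth(normals: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Frankot-Chellappa least-squares integration of a normal map.

    Gradients p = -nx/nz, q = -ny/nz (x = column axis) are integrated in the
    frequency domain under the periodic basis; the mean (planar) gradient is
    integrated in closed form so tilted planes are recovered exactly.  The
    result is returned zero-mean.  Invalid pixels contribute zero gradient.
    """
    normals = np.asarray(normals)
    if valid is None:
        valid = np.ones(normals.shape[:2], dtype=bool)
    if not valid.any():
        raise ValueError("no valid pixels to integrate")
    nz = np.where(valid, normals[..., 2], 1.0)
    nz = np.where(np.abs(nz) < 1e-12, 1e-12, nz)
    p = np.where(valid, -normals[..., 0] / nz, 0.0)
    q = np.where(valid, -normals[..., 1] / nz, 0.0)

    h, w = p.shape
    # the DC gradient has no periodic antiderivative: integrate it as a plane
    p_mean, q_mean = p.mean(), q.mean()
    p = p - p_mean
    q = q - q_mean
    wy = 2.0 * np.pi * sp_fft.fftfreq(h)[:, None]
    wx = 2.0 * np.pi * sp_fft.fftfreq(w)[None, :]
    denom = wx**2 + wy**2
    denom[0, 0] = 1.0
    spec = (-1j * wx * sp_fft.fft2(p) - 1j * wy * sp_fft.fft2(q)) / denom
    spec[0, 0] = 0.0
    depth = sp_fft.ifft2(spec).real
    depth = depth + p_mean * np.arange(w)[None, :] + q_mean * np.arange(h)[:, None]
    return depth - depth.mean()


def smooth_depth(depth: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with reflective boundary; sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.array(depth, copy=True)
    return gaussian_filter(depth, sigma, mode="reflect")


# --------------------------------------------------------------------------- #
# cube assembly and display
# --------------------------------------------------------------------------- #


def assemble_cube(products: PhotometricProducts, depths: np.ndarray) -> ProcessedCube:
    """Stack 33 albedo channels then the 33 smoothed depth maps, band order
    preserved (ascending wavelength)."""
    depths = np.asarray(depths)
    if depths.shape != products.albedo.shape:
        raise ValueError(
            f"depth stack shape {depths.shape} does not match albedo {products.albedo.shape}"
        )
    values = np.concatenate([products.albedo, depths], axis=-1)
    return ProcessedCube(values=values, band_centers_nm=products.band_centers_nm)


def render_rgb(cube: ProcessedCube, band_triplet) -> np.ndarray:
    """Min-max scaled 3-channel reconstruction from three albedo channels
    (given in R, G, B order)."""
    triplet = list(band_triplet)
    if len(triplet) != 3 or any(not 0 <= b < N_BANDS for b in triplet):
        raise ValueError(f"band_triplet must be three indices in [0, {N_BANDS - 1}]")
    out = np.empty(cube.values.shape[:2] + (3,), dtype=np.float64)
    for i, b in enumerate(triplet):
        chan = cube.albedo[:, :, b].astype(np.float64)
        lo, hi = chan.min(), chan.max()
        out[..., i] = 0.0 if hi == lo else (chan - lo) / (hi - lo)
    return out


# --------------------------------------------------------------------------- #
# full pre-processing pipeline
# --------------------------------------------------------------------------- #


def preprocess_capture(
    capture: RawCaptureSet,
    sigma: float = 2.0,
    dtype=None,
    return_products: bool = False,
):
    """Full raw pre-processing: calibrate -> merge groups -> photometric
    stereo -> per-band depth integration -> smoothing -> 66-channel cube."""
    cal = calibrate_capture(capture, dtype=dtype)
    merged = [
        merge_channel_groups(cal[("vis", li)], cal[("vnir", li)]) for li in range(3)
    ]
    del cal
    products = solve_photometric_stereo(merged, capture.light_geometry)
    del merged
    depths = np.empty_like(products.albedo)
    for b in range(products.albedo.shape[-1]):
        depth = integrate_depth(products.normals[:, :, b], ~products.shadow_mask[:, :, b])
        depths[:, :, b] = smooth_depth(depth, sigma)
    cube = assemble_cube(products, depths)
    if return_products:
        return cube, products
    return cube


def save_cube(cube: ProcessedCube, path) -> None:
    """Persist as a 66-band TIFF stack plus a JSON sidecar."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(cube.values, -1, 0))
    sidecar = {
        "band_centers_nm": list(map(float, cube.band_centers_nm)),
        "layout": "channels 0-32 albedo, 33-65 smoothed depth, ascending wavelength",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_cube(path) -> ProcessedCube:
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    values = np.moveaxis(tifffile.imread(path), 0, -1)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ProcessedCube(values=values, band_centers_nm=np.asarray(meta["band_centers_nm"]))
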