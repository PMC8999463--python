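"""Machine-learning pre-processing.

Ground-truth masks with margins, selection of the 34 classification channels
(33 albedo + one chosen skin-surface frame), [0, 1] normalization, vertical
train/test slicing, quota-based window sampling, class balancing by random
over-sampling, and flip augmentation.

Window convention: for the even window side (default 30) the "middle pixel"
of a patch is at offset (15, 15); the patch spans rows [r-15, r+15) and
columns [c-15, c+15), half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import dilation, disk, erosion

from hsiderm.photometric import N_BANDS, ProcessedCube

N_FEATURE_CHANNELS = N_BANDS + 1  # 33 albedo + 1 surface frame
DEFAULT_WINDOW = 30
DEFAULT_SURFACE_BAND_NM = 575.0
DEFAULT_N_LESION = 250
DEFAULT_N_HEALTHY = 100


def _disk(radius: int) -> np.ndarray:
    return disk(radius, decomposition=None) if radius <= 8 else disk(radius, decomposition="sequence")


@dataclass
class MaskSet:
    """Sampling regions derived from the annotation.

    ``lesion_core`` is the annotation eroded by the stated margin;
    ``exclusion_band`` covers the lesion-border band where no pixels are
    sampled; ``healthy_region`` is the annulus outside that band.
    """

    annotation: np.ndarray
    lesion_core: np.ndarray
    exclusion_band: np.ndarray
    healthy_region: np.ndarray
    fov_mask: np.ndarray

    def __post_init__(self):
        if np.any(self.lesion_core & self.healthy_region):
            raise ValueError("lesion_core and healthy_region must be disjoint")
        if np.any(self.exclusion_band & (self.lesion_core | self.healthy_region)):
            raise ValueError("exclusion_band must be disjoint from the sampling regions")


def build_masks(
    annotation: np.ndarray,
    fov: np.ndarray,
    erosion_px: int = 30,
    margin_px: int = 60,
    annulus_outer_px: int = 200,
) -> MaskSet:
    """Morphological sampling-region construction.

    lesion_core = erode(annotation, erosion_px); the healthy annulus is
    (dilate(annotation, annulus_outer_px) \\ dilate(annotation, margin_px))
    restricted to erode(fov, erosion_px).
    """
    annotation = np.asarray(annotation, dtype=bool)
    fov = np.asarray(fov, dtype=bool)
    if not annotation.any():
        raise ValueError("annotation is empty")
    if np.any(annotation & ~fov):
        raise ValueError("annotation must lie inside the field of view")
    core = erosion(annotation, _disk(erosion_px))
    if not core.any():
        raise ValueError(
            f"lesion core empty after erosion by {erosion_px} px; "
            "use a smaller erosion or a larger lesion"
        )
    margin = dilation(annotation, _disk(margin_px))
    outer = dilation(annotation, _disk(annulus_outer_px))
    fov_eroded = erosion(fov, _disk(erosion_px))
    healthy = outer & ~margin & fov_eroded
    exclusion = margin & ~core
    return MaskSet(
        annotation=annotation,
        lesion_core=core,
        exclusion_band=exclusion,
        healthy_region=healthy,
        fov_mask=fov,
    )


# --------------------------------------------------------------------------- #
# feature channels and normalization
# --------------------------------------------------------------------------- #


@dataclass
class FeatureCube:
    """(H, W, 34) classification stack: 33 albedo + one surface frame."""

    values: np.ndarray
    band_centers_nm: np.ndarray
    surface_band_nm: float

    def __post_init__(self):
        if self.values.shape[-1] != N_FEATURE_CHANNELS:
            raise ValueError(f"feature cube must have {N_FEATURE_CHANNELS} channels")


def select_channels(cube: ProcessedCube, surface_band_nm: float = DEFAULT_SURFACE_BAND_NM) -> FeatureCube:
    """All 33 albedo channels plus the depth channel whose band center is
    nearest ``surface_band_nm`` (ties -> lower wavelength)."""
    bands = np.asarray(cube.band_centers_nm, dtype=float)
    dist = np.abs(bands - surface_band_nm)
    idx = int(np.argmin(dist))  # argmin takes the first (lower-wavelength) tie
    values = np.concatenate(
        [cube.albedo, cube.depth[:, :, idx : idx + 1]], axis=-1
    )
    return FeatureCube(values=values, band_centers_nm=bands, surface_band_nm=float(bands[idx]))


def normalize(values: np.ndarray, fov: np.ndarray | None = None,
              band_centers_nm=None, surface_band_nm: float = float("nan")) -> FeatureCube:
    """Non-finite values -> 0, then per-channel min-max scaling to [0, 1]
    computed over field-of-view pixels; constant channels map to all zeros."""
    values = np.asarray(values, dtype=np.float32).copy()
    if values.shape[-1] != N_FEATURE_CHANNELS:
        raise ValueError(f"expected {N_FEATURE_CHANNELS} channels")
    values[~np.isfinite(values)] = 0.0
    if fov is None:
        fov = np.ones(values.shape[:2], dtype=bool)
    sel = values[fov]  # (n_fov, C)
    lo = sel.min(axis=0)
    hi = sel.max(axis=0)
    span = hi - lo
    scaled = np.where(span > 0, (values - lo) / np.where(span > 0, span, 1.0), 0.0)
    values = np.clip(scaled, 0.0, 1.0).astype(np.float32)
    if band_centers_nm is None:
        band_centers_nm = np.arange(N_BANDS, dtype=float)
    return FeatureCube(values=values, band_centers_nm=np.asarray(band_centers_nm),
                       surface_band_nm=surface_band_nm)


def prepare_features(cube: ProcessedCube, fov: np.ndarray,
                     surface_band_nm: float = DEFAULT_SURFACE_BAND_NM) -> FeatureCube:
    """select_channels followed by normalization over the field of view."""
    raw = select_channels(cube, surface_band_nm)
    return normalize(raw.values, fov, band_centers_nm=raw.band_centers_nm,
                     surface_band_nm=raw.surface_band_nm)


# --------------------------------------------------------------------------- #
# vertical slicing
# --------------------------------------------------------------------------- #


@dataclass
class HalfImage:
    """One vertical half of a feature cube with its sliced masks."""

    cube: FeatureCube
    masks: MaskSet
    side: str  # "train" | "test"
    col_offset: int  # column of the half's left edge in the full frame
    label: str | None = None


def split_vertical(cube: FeatureCube, masks: MaskSet, label: str | None = None) -> tuple:
    """Slice through the column of the annotation centroid: columns left of it
    form the training half, the rest the test half."""
    if not masks.lesion_core.any():
        raise ValueError("lesion_core is empty")
    cols = np.nonzero(masks.annotation)[1]
    split_col = int(round(cols.mean()))

    def take(sl, side, offset):
        sliced = MaskSet(
            annotation=masks.annotation[:, sl],
            lesion_core=masks.lesion_core[:, sl],
            exclusion_band=masks.exclusion_band[:, sl],
            healthy_region=masks.healthy_region[:, sl],
            fov_mask=masks.fov_mask[:, sl],
        )
        half_cube = FeatureCube(
            values=cube.values[:, sl],
            band_centers_nm=cube.band_centers_nm,
            surface_band_nm=cube.surface_band_nm,
        )
        return HalfImage(cube=half_cube, masks=sliced, side=side, col_offset=offset, label=label)

    train = take(slice(0, split_col), "train", 0)
    test = take(slice(split_col, cube.values.shape[1]), "test", split_col)
    for half in (train, test):
        if not half.masks.lesion_core.any():
            raise ValueError(f"{half.side} half lost all lesion_core pixels")
    return train, test


# --------------------------------------------------------------------------- #
# window sampling
# --------------------------------------------------------------------------- #


@dataclass
class WindowSample:
    patch: np.ndarray  # (window, window, 34)
    label: str
    center: tuple  # (row, col) in half coordinates
    side: str


def _eligible_centers(region: np.ndarray, window: int) -> np.ndarray:
    """Region pixels whose half-open window [r-w//2, r+w//2) fits the frame."""
    h, w = region.shape
    half = window // 2
    ok = np.zeros_like(region)
    lo_r, hi_r = half, h - (window - half)
    lo_c, hi_c = half, w - (window - half)
    if hi_r >= lo_r and hi_c >= lo_c:
        ok[lo_r : hi_r + 1, lo_c : hi_c + 1] = True
    rows, cols = np.nonzero(region & ok)
    return np.stack([rows, cols], axis=1)


def extract_patch(values: np.ndarray, center, window: int = DEFAULT_WINDOW) -> np.ndarray:
    r, c = center
    half = window // 2
    return values[r - half : r - half + window, c - half : c - half + window]


def sample_windows(
    half: HalfImage,
    n_lesion: int = DEFAULT_N_LESION,
    n_healthy: int = DEFAULT_N_HEALTHY,
    window: int = DEFAULT_WINDOW,
    seed: int = 0,
) -> list:
    """Uniformly sample window centers without replacement: ``n_lesion`` from
    the lesion core and ``n_healthy`` from the healthy annulus."""
    if half.label is None:
        raise ValueError("half image carries no lesion label")
    rng = np.random.default_rng(seed)
    quotas = [
        ("lesion", half.masks.lesion_core, n_lesion, half.label),
        ("healthy", half.masks.healthy_region, n_healthy, "healthy"),
    ]
    shortfalls = []
    samples = []
    for name, region, quota, label in quotas:
        centers = _eligible_centers(region, window)
        if len(centers) < quota:
            shortfalls.append(f"{name}: need {quota}, have {len(centers)}")
            continue
        chosen = centers[rng.choice(len(centers), size=quota, replace=False)]
        for r, c in chosen:
            samples.append(
                WindowSample(
                    patch=extract_patch(half.cube.values, (r, c), window),
                    label=label,
                    center=(int(r), int(c)),
                    side=half.side,
                )
            )
    if shortfalls:
        raise ValueError("insufficient eligible window centers — " + "; ".join(shortfalls))
    return samples


def balance_oversample(samples: list, seed: int = 0) -> list:
    """Random over-sampling: duplicate minority-class samples (uniformly, with
    replacement) until every class matches the majority count."""
    labels = [s.label for s in samples]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes to balance")
    rng = np.random.default_rng(seed)
    counts = {c: labels.count(c) for c in classes}
    majority = max(counts.values())
    out = list(samples)
    for c in classes:
        deficit = majority - counts[c]
        if deficit:
            pool = [s for s in samples if s.label == c]
            picks = rng.integers(0, len(pool), size=deficit)
            out.extend(pool[i] for i in picks)
    return out


def augment_flips(samples: list) -> list:
    """Originals plus vertical and horizontal flips of every patch (3x count);
    spatial axes only, channel order untouched."""
    out = list(samples)
    for s in samples:
        out.append(WindowSample(patch=s.patch[::-1, :].copy(), label=s.label,
                                center=s.center, side=s.side))
    for s in samples:
        out.append(WindowSample(patch=s.patch[:, ::-1].copy(), label=s.label,
                                center=s.center, side=s.side))
    return out


def rolling_windows(
    cube: FeatureCube,
    fov: np.ndarray,
    window: int = DEFAULT_WINDOW,
    stride: int = 1,
):
    """Yield (center, patch) for every field-of-view pixel whose window fits
    inside the frame, row-major, with the given stride (default 1)."""
    h, w = cube.values.shape[:2]
    if window > min(h, w):
        raise ValueError(f"window {window} larger than frame {h}x{w}")
    half = window // 2
    for r in range(half, h - (window - half) + 1, stride):
        for c in range(half, w - (window - half) + 1, stride):
            if fov[r, c]:
                yield (r, c), extract_patch(cube.values, (r, c), window)


def make_validation_split(samples: list, fraction: float = 0.2, seed: int = 0) -> tuple:
    """Stratified-by-class random split, applied before balancing and
    augmentation; returns (train, validation)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for i, s in enumerate(samples):
        by_class.setdefault(s.label, []).append(i)
    train_idx, val_idx = [], []
    for label in sorted(by_class):
        idx = np.asarray(by_class[label])
        n_val = int(round(fraction * len(idx)))
        if n_val == 0 or n_val == len(idx):
            raise ValueError(
                f"fraction {fraction} empties a stratum for class {label!r} (n={len(idx)})"
            )
        perm = rng.permutation(len(idx))
        val_idx.extend(idx[perm[:n_val]])
        train_idx.extend(idx[perm[n_val:]])
    train_idx.sort()
    val_idx.sort()
    return [samples[i] for i in train_idx], [samples[i] for i in val_idx]


# --------------------------------------------------------------------------- #
# persistence
# --------------------------------------------------------------------------- #


def save_windows(samples: list, out_dir, seed: int | None = None, quotas: dict | None = None) -> None:
    """Single array container (.npz) plus a JSON manifest."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patches = np.stack([s.patch for s in samples]) if samples else np.empty((0,))
    np.savez(out / "windows.npz", patches=patches)
    manifest = {
        "labels": [s.label for s in samples],
        "centers": [list(s.center) for s in samples],
        "sides": [s.side for s in samples],
        "seed": seed,
        "quotas": quotas,
    }
    (out / "manifest.json").write_text(json.dumps(manifest))


def load_windows(in_dir) -> list:
    import json
    from pathlib import Path

    src = Path(in_dir)
    patches = np.load(src / "windows.npz")["patches"]
    manifest = json.loads((src / "manifest.json").read_text())
    return [
        WindowSample(patch=patches[i], label=lab, center=tuple(ctr), side=side)
        for i, (lab, ctr, side) in enumerate(
            zip(manifest["labels"], manifest["centers"], manifest["sides"])
        )
    ]
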