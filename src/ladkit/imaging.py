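"""Nuclear image quantification: total intensity, radial shells, TEM ratios.

Radial position is measured by the Euclidean distance transform of the
nucleus mask: each mask pixel's normalized depth r = 1 - EDT / max(EDT)
runs from 0 at the most interior point to ~1 at the envelope, and is cut
into n_shells equal-depth shells, shell 1 = center, shell N = periphery.
Analyses are 2-D, matching quantification of a single central z slice per
nucleus; no background subtraction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import GenomicInterval  # noqa: F401  (package-level re-exports)


@dataclass
class NucleusImage:
    """Named 2-D intensity channels over a single-nucleus binary mask."""

    channels: Dict[str, np.ndarray]
    mask: np.ndarray
    pixel_size: float  # um per pixel

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for name, ch in self.channels.items():
            ch = np.asarray(ch, dtype=float)
            if ch.shape != self.mask.shape:
                raise ValueError(f"channel {name!r} shape differs from mask")
            if np.any(ch < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = ch
        n_components = ndimage.label(self.mask)[1]
        if n_components != 1:
            raise ValueError(
                f"mask must have exactly one connected component, found {n_components}"
            )

    def depth(self) -> np.ndarray:
        """Normalized depth r in [0, 1) per mask pixel (NaN outside).

        r = 1 - EDT/max(EDT); boundary pixels (EDT = 1 px to the
        complement) have the largest r, the innermost pixel has r = 0.
        """
        edt = ndimage.distance_transform_edt(self.mask)
        dmax = edt.max()
        if dmax <= 1:
            raise ValueError("mask is only one pixel thick; shells undefined")
        r = np.full(self.mask.shape, np.nan)
        r[self.mask] = 1.0 - edt[self.mask] / dmax
        return r


@dataclass(frozen=True)
class RadialProfile:
    """Per-shell intensity and area fractions; shell 1 center, N periphery."""

    n_shells: int
    intensity_fraction: np.ndarray
    area_fraction: np.ndarray
    normalized_mean: np.ndarray  # per-shell mean intensity per pixel

    def cumulative_from_periphery(self) -> np.ndarray:
        return np.cumsum(self.intensity_fraction[::-1])[::-1]


@dataclass(frozen=True)
class TEMQuantification:
    """Envelope vs nucleoplasm integrated-density comparison."""

    square_um: float
    n_ne: int
    n_np: int
    mean_ne: float
    mean_np: float

    @property
    def ratio(self) -> float:
        return self.mean_ne / self.mean_np


def _load_array(path) -> np.ndarray:
    """Read a 2-D image array from plain text, TIFF or PNG."""
    from pathlib import Path

    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    if suffix == ".png":
        from PIL import Image

        return np.asarray(Image.open(path), dtype=float)
    return np.loadtxt(path)


def load_nucleus_image(
    image_path, mask_path, pixel_size: float, channel: str = "marker"
) -> NucleusImage:
    """Build a NucleusImage from an intensity image and a binary mask file
    (plain-text array, TIFF or PNG)."""
    channel_arr = _load_array(image_path)
    mask = _load_array(mask_path) > 0.5
    return NucleusImage(
        channels={channel: channel_arr}, mask=mask, pixel_size=pixel_size
    )


def save_nucleus_image(image: NucleusImage, image_path, mask_path,
                       channel: str = "marker") -> None:
    """Write a channel and mask as TIFF (or plain text for .txt paths)."""
    from pathlib import Path

    if Path(image_path).suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(image_path,
                         image.channels[channel].astype(np.float32))
        tifffile.imwrite(mask_path, image.mask.astype(np.uint8))
    else:
        np.savetxt(image_path, image.channels[channel])
        np.savetxt(mask_path, image.mask.astype(int), fmt="%d")


def total_intensity(image: NucleusImage, channel: str) -> float:
    """Sum of a channel's intensities over the mask."""
    if channel not in image.channels:
        raise KeyError(f"no channel {channel!r}")
    if not image.mask.any():
        raise ValueError("empty mask")
    return float(image.channels[channel][image.mask].sum())


def shell_indices(image: NucleusImage, n_shells: int) -> np.ndarray:
    """Shell index (1..n_shells) per mask pixel, 0 outside the mask.

    k = min(ceil(r * n_shells), n_shells), with r = 0 mapped to shell 1, so
    every mask pixel belongs to exactly one shell.
    """
    if n_shells < 2:
        raise ValueError("need n_shells >= 2")
    r = image.depth()
    k = np.zeros(image.mask.shape, dtype=int)
    rm = r[image.mask]
    km = np.minimum(np.ceil(rm * n_shells).astype(int), n_shells)
    km[km < 1] = 1
    k[image.mask] = km
    return k


def radial_shell_profile(
    image: NucleusImage, channel: str, n_shells: int = 25
) -> RadialProfile:
    """Distribute a channel's intensity over equal-depth radial shells."""
    if channel not in image.channels:
        raise KeyError(f"no channel {channel!r}")
    k = shell_indices(image, n_shells)
    ch = image.channels[channel]
    intensity = np.array(
        [ch[k == s].sum() for s in range(1, n_shells + 1)], dtype=float
    )
    area = np.array([(k == s).sum() for s in range(1, n_shells + 1)], dtype=float)
    total = intensity.sum()
    total_area = area.sum()
    if total_area == 0:
        raise ValueError("empty mask")
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized_mean = np.where(area > 0, intensity / area, np.nan)
        intensity_fraction = (
            intensity / total if total > 0 else np.full(n_shells, np.nan)
        )
    return RadialProfile(
        n_shells=n_shells,
        intensity_fraction=intensity_fraction,
        area_fraction=area / total_area,
        normalized_mean=normalized_mean,
    )


def tem_periphery_ratio(
    image_array: np.ndarray,
    ne_points: Sequence[Tuple[int, int]],
    np_points: Sequence[Tuple[int, int]],
    square_um: float = 0.2,
    pixel_size: float = 0.02,
) -> TEMQuantification:
    """Nuclear-envelope : nucleoplasm signal ratio from centered squares.

    At each (row, col) point a square of side round(square_um / pixel_size)
    px (minimum 1) is centered; its integrated density is the sum of pixel
    values. The ratio is mean(NE squares) / mean(nucleoplasm squares).
    """
    img = np.asarray(image_array, dtype=float)
    if not ne_points or not np_points:
        raise ValueError("both point sets must be non-empty")
    side = max(1, round(square_um / pixel_size))
    half_lo = side // 2
    half_hi = side - half_lo

    def integrated(points, region):
        sums = []
        for (row, col) in points:
            r0, r1 = row - half_lo, row + half_hi
            c0, c1 = col - half_lo, col + half_hi
            if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
                raise ValueError(
                    f"{region} square at ({row}, {col}) exceeds image bounds"
                )
            sums.append(img[r0:r1, c0:c1].sum())
        return float(np.mean(sums))

    mean_ne = integrated(ne_points, "NE")
    mean_np = integrated(np_points, "nucleoplasm")
    if mean_np == 0:
        raise ValueError("mean nucleoplasm signal is zero; ratio undefined")
    return TEMQuantification(
        square_um=square_um,
        n_ne=len(ne_points),
        n_np=len(np_points),
        mean_ne=mean_ne,
        mean_np=mean_np,
    )


def sample_region_points(
    mask: np.ndarray,
    region: str,
    n: int,
    seed: int = 0,
    pixel_size: float = 0.02,
    r_ne: float = 0.9,
    r_np: float = 0.6,
) -> List[Tuple[int, int]]:
    """Sample pixel coordinates beneath the envelope or in the nucleoplasm.

    NE points come from pixels with normalized depth r > r_ne, nucleoplasm
    points from r < r_np; sampling is uniform without replacement and
    deterministic given the seed.
    """
    image = NucleusImage(channels={}, mask=mask, pixel_size=pixel_size)
    r = image.depth()
    if region == "NE":
        eligible = np.argwhere(r > r_ne)
    elif region == "nucleoplasm":
        eligible = np.argwhere(r < r_np)
    else:
        raise ValueError("region must be 'NE' or 'nucleoplasm'")
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible pixels for region {region!r}, need {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [tuple(map(int, eligible[i])) for i in idx]
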