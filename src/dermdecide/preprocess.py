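"""Standardised preprocessing to the canonical 512x512 analysis frame.

Every input image goes through the same chain: rescale so the larger
dimension is 1000 px, segment the lesion (Chan-Vese), crop to the mask's
tight bounding box, pad the shorter side symmetrically with blank (zero)
pixels to a square, and bilinearly resample to 512x512.  Blank padding is
kept in the frame and seen by the feature extractor; no hair removal,
colour normalisation or other cleanup is applied.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .errors import InvalidInputError, SegmentationError

__all__ = ["rescale_max_dim", "crop_pad_square", "preprocess_image", "as_rgb01"]


def as_rgb01(image: np.ndarray) -> np.ndarray:
    """Coerce an array to float RGB in [0,1]; integer dtypes are divided by
    their max value, an alpha channel is dropped, grayscale is replicated."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(float) / np.iinfo(image.dtype).max
    else:
        image = image.astype(float)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[-1] not in (3, 4):
        raise InvalidInputError(f"cannot interpret shape {image.shape} as RGB")
    image = image[..., :3]
    if not np.all(np.isfinite(image)):
        raise InvalidInputError("image contains non-finite values")
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise InvalidInputError("image values must lie in [0,1]")
    return np.clip(image, 0.0, 1.0)


def _resize_bilinear(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = resize(image, shape + image.shape[2:], order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def rescale_max_dim(image: np.ndarray, target: int = 1000) -> np.ndarray:
    """Rescale (up or down) so that max(H, W) == target, preserving aspect
    ratio; the non-maximal dimension is rounded half-up.  Bilinear."""
    image = as_rgb01(image)
    h, w = image.shape[:2]
    if target < 2:
        raise InvalidInputError("target must be >= 2")
    if h < 2 or w < 2:
        raise InvalidInputError(f"image too small to rescale: {h}x{w}")
    if max(h, w) == target:
        return image
    scale = target / max(h, w)
    # round half up, never below 1 px
    new_h = target if h >= w else max(1, int(np.floor(h * scale + 0.5)))
    new_w = target if w > h else max(1, int(np.floor(w * scale + 0.5)))
    return _resize_bilinear(image, (new_h, new_w))


def crop_pad_square(image: np.ndarray, mask: np.ndarray, side: int = 512,
                    pad_before_resize: bool = True) -> np.ndarray:
    """Crop to the mask's tight bounding box, square up with blank pixels,
    and resample to side x side.

    The shorter dimension of the crop is padded symmetrically with zeros
    (the extra pixel of an odd deficit goes after the crop).  With
    ``pad_before_resize=False`` the crop is resampled first and padded
    afterwards, an alternative reading of the same frame-construction rule.
    """
    image = as_rgb01(image)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape[:2]:
        raise InvalidInputError(
            f"mask shape {mask.shape} does not match image {image.shape[:2]}"
        )
    if not mask.any():
        raise SegmentationError("empty lesion mask: nothing to crop")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    crop = image[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]

    def pad_square(arr: np.ndarray) -> np.ndarray:
        h, w = arr.shape[:2]
        d = abs(h - w)
        before, after = d // 2, d - d // 2
        pad = ((before, after), (0, 0), (0, 0)) if h < w else \
              ((0, 0), (before, after), (0, 0))
        return np.pad(arr, pad, mode="constant", constant_values=0.0)

    if pad_before_resize:
        return _resize_bilinear(pad_square(crop), (side, side))
    h, w = crop.shape[:2]
    if h >= w:
        resized = _resize_bilinear(crop, (side, max(1, int(np.floor(w * side / h + 0.5)))))
    else:
        resized = _resize_bilinear(crop, (max(1, int(np.floor(h * side / w + 0.5))), side))
    out = pad_square(resized)
    # odd rounding can leave a 1-px mismatch; snap to side x side
    if out.shape[:2] != (side, side):
        out = _resize_bilinear(out, (side, side))
    return out


def preprocess_image(image: np.ndarray, target: int = 1000, side: int = 512,
                     cv_params=None, pad_before_resize: bool = True,
                     return_mask: bool = False):
    """The full canonical-frame pipeline: rescale -> segment -> crop/pad.

    Returns the side x side x 3 frame (and the lesion mask in the rescaled
    frame when ``return_mask`` is set).
    """
    from .segmentation import segment_chan_vese  # local import, avoids cycle

    rescaled = rescale_max_dim(image, target)
    mask = segment_chan_vese(rescaled, cv_params)
    frame = crop_pad_square(rescaled, mask, side, pad_before_resize)
    return (frame, mask) if return_mask else frame
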