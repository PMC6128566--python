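"""Seeded generators for synthetic lesion images and feature tables.

The original dermoscopic photographs are not redistributable, so every
stage of the pipeline is exercised on synthetic material with known ground
truth:

* **Images** — a skin-toned background with a darker elliptical lesion
  whose border is perturbed by a random low-order sinusoid (irregular,
  poorly defined borders) and whose interior carries multi-octave value
  noise (texture at several length scales).  The excise-class defaults
  have strictly stronger fine-scale texture and border irregularity than
  the benign defaults, so wavelet detail statistics genuinely separate the
  classes.  The generating ellipse-with-perturbed-border region is
  returned as the ground-truth mask.
* **Feature tables** — rows drawn from correlated Gaussian blocks (the
  block structure mimics the strong within-level / within-statistic
  correlations of real wavelet features); the excise class is shifted by a
  standardised effect size delta on a recorded set of informative columns.
  Class sizes default to the study scale, 165 excise / 85 benign.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidSpecError
from .io import FeatureTable

__all__ = [
    "SyntheticImageSpec", "SyntheticTableSpec",
    "make_lesion_image", "make_feature_table",
]

# plausible dermoscopy tones (RGB in [0,1]); exact values are cosmetic
_SKIN = np.array([0.82, 0.64, 0.56])
_LESION = np.array([0.42, 0.27, 0.20])


@dataclass
class SyntheticImageSpec:
    """Recipe for one synthetic lesion image.

    ``texture_amps`` are per-octave amplitudes, coarse first; the last
    entry drives near-pixel-scale detail (the level-1 wavelet bands).
    ``border_irregularity`` scales the sinusoidal radial perturbation of
    the ellipse outline.
    """

    seed: int = 0
    class_label: str = "benign"              # "excise" | "benign"
    side: int = 512
    axes: tuple[float, float] = (0.30, 0.22)  # semi-axes as fractions of side
    orientation: float = 0.5                  # radians
    contrast: float = 1.0                     # scales lesion/skin separation
    texture_amps: tuple[float, ...] | None = None
    border_irregularity: float | None = None

    def __post_init__(self):
        if self.class_label not in ("excise", "benign"):
            raise InvalidSpecError(f"unknown class_label {self.class_label!r}")
        if self.side < 32:
            raise InvalidSpecError("side must be >= 32")
        if min(self.axes) <= 0:
            raise InvalidSpecError("ellipse axes must be positive")
        if self.texture_amps is None:
            self.texture_amps = (0.05, 0.035, 0.030) if self.class_label == "excise" \
                else (0.04, 0.02, 0.008)
        if self.border_irregularity is None:
            self.border_irregularity = 0.14 if self.class_label == "excise" else 0.04
        # the perturbed ellipse must stay on the canvas
        reach = max(self.axes) * (1.0 + self.border_irregularity * 4) * self.side
        if reach >= self.side / 2:
            raise InvalidSpecError(
                f"lesion (reach {reach:.0f}px) exceeds canvas of side {self.side}"
            )


def _value_noise(rng: np.random.Generator, side: int, cells: int) -> np.ndarray:
    """Smooth noise: a coarse Gaussian grid bilinearly upsampled to side."""
    grid = rng.standard_normal((cells, cells))
    zoom = side / cells
    out = ndimage.zoom(grid, zoom, order=1, mode="grid-wrap")
    return out[:side, :side]


def make_lesion_image(spec: SyntheticImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the image described by *spec*; returns (image, ground-truth
    mask).  Deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    s = spec.side
    yy, xx = np.mgrid[:s, :s].astype(float)
    cy = cx = (s - 1) / 2.0
    ct, st = np.cos(spec.orientation), np.sin(spec.orientation)
    u = ((xx - cx) * ct + (yy - cy) * st) / (spec.axes[0] * s)
    v = (-(xx - cx) * st + (yy - cy) * ct) / (spec.axes[1] * s)
    radius = np.sqrt(u ** 2 + v ** 2)
    theta = np.arctan2(v, u)

    # low-order sinusoidal border perturbation
    wobble = np.zeros_like(theta)
    for k in range(2, 6):
        ck, sk = rng.normal(size=2)
        wobble += ck * np.cos(k * theta) + sk * np.sin(k * theta)
    mask = radius <= 1.0 + spec.border_irregularity * wobble

    lesion_rgb = _SKIN + (_LESION - _SKIN) * spec.contrast
    image = np.ones((s, s, 3)) * _SKIN
    image[mask] = lesion_rgb

    # multi-octave texture inside the lesion, common to all channels
    texture = np.zeros((s, s))
    n_oct = len(spec.texture_amps)
    for o, amp in enumerate(spec.texture_amps):
        cells = max(4, s // 2 ** (n_oct + 1 - o))
        texture += amp * _value_noise(rng, s, cells)
    image[mask] += texture[mask][:, None]

    # faint illumination gradient over the skin, as in real photographs
    image += 0.02 * ((yy - cy) / s)[..., None]
    return np.clip(image, 0.0, 1.0), mask


@dataclass
class SyntheticTableSpec:
    """Recipe for a synthetic per-lesion feature table."""

    seed: int = 0
    n_pos: int = 165            # excise rows
    n_neg: int = 85             # no-excision rows
    q: int = 1152
    n_informative: int = 20
    delta: float = 2.0          # standardised mean shift on informative columns
    block_size: int = 12
    rho: float = 0.5            # within-block correlation

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise InvalidSpecError("class counts must be positive")
        if not 0 <= self.rho < 1:
            raise InvalidSpecError("rho must lie in [0, 1)")
        if self.n_informative > self.q:
            raise InvalidSpecError("n_informative cannot exceed q")
        if self.block_size < 1:
            raise InvalidSpecError("block_size must be >= 1")


def make_feature_table(spec: SyntheticTableSpec) -> tuple[FeatureTable, np.ndarray]:
    """Draw a labelled table; returns (table, informative column indices).

    Columns come in consecutive blocks of ``block_size`` with equal
    pairwise correlation ``rho`` (unit marginal variance); excise-class
    rows are shifted by ``delta`` on the informative columns only.  The
    informative columns are spread over distinct blocks where possible.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    X = np.empty((n, spec.q))
    for start in range(0, spec.q, spec.block_size):
        width = min(spec.block_size, spec.q - start)
        shared = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, width))
        X[:, start:start + width] = np.sqrt(spec.rho) * shared \
            + np.sqrt(1.0 - spec.rho) * eps

    n_blocks = int(np.ceil(spec.q / spec.block_size))
    if spec.n_informative <= n_blocks:
        blocks = rng.choice(n_blocks, size=spec.n_informative, replace=False)
        informative = np.sort(np.array(
            [b * spec.block_size + int(rng.integers(min(spec.block_size,
                                                        spec.q - b * spec.block_size)))
             for b in blocks], dtype=int))
    else:
        informative = np.sort(rng.choice(spec.q, size=spec.n_informative,
                                         replace=False))

    y = np.concatenate([np.ones(spec.n_pos, dtype=int),
                        np.zeros(spec.n_neg, dtype=int)])
    X[: spec.n_pos, informative] += spec.delta
    return FeatureTable(X, y), informative
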