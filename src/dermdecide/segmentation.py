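"""Two-region Chan-Vese active-contour segmentation for colour images.

The contour is the zero level set of a signed function phi evolved by
gradient descent on the piecewise-constant Mumford-Shah energy

    f(c1, c2, phi) = mu1 * L(contour) + mu2 * A(inside)
                     + lambda1 * sum_inside  |F - c1|^2
                     + lambda2 * sum_outside |F - c2|^2

where c1 and c2 are the per-channel means of the image F inside and
outside the contour, recomputed every iteration, and the fidelity terms
sum over the RGB channels (vector-valued Chan-Vese with a single shared
contour).  The Heaviside and delta functions are smoothed over ~1 px; phi
starts from a checkerboard so the contour can form anywhere.  Each descent
step is accepted only if it does not increase the (smoothed) energy, with
the time step halved otherwise, so the energy trace is non-increasing by
construction.

Lesions are pigmented and darker than the surrounding skin, so by default
the region with the lower mean luminance is returned as the lesion mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateImageError, InvalidInputError
from .preprocess import as_rgb01

__all__ = ["ChanVeseParams", "ChanVeseState", "segment_chan_vese", "chan_vese_energy"]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ChanVeseParams:
    """Energy weights and iteration controls.  The defaults are the classic
    choices: a mild length penalty, no area penalty, equal level penalties."""

    mu1: float = 0.25        # length penalty
    mu2: float = 0.0         # area penalty
    lambda1: float = 1.0     # inside fidelity
    lambda2: float = 1.0     # outside fidelity
    max_iter: int = 500
    tol: float = 1e-3        # relative phi change at convergence
    dt: float = 0.5          # initial explicit time step
    epsilon: float = 1.0     # Heaviside/delta smoothing width (px)

    def __post_init__(self) -> None:
        if self.mu1 < 0 or self.mu2 < 0:
            raise InvalidInputError("penalties mu1, mu2 must be >= 0")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise InvalidInputError("level penalties lambda1, lambda2 must be > 0")
        if self.max_iter < 1 or self.tol <= 0 or self.dt <= 0 or self.epsilon <= 0:
            raise InvalidInputError("max_iter, tol, dt, epsilon must be positive")


@dataclass
class ChanVeseState:
    """Snapshot of the level-set evolution."""

    phi: np.ndarray
    c1: np.ndarray                     # per-channel mean inside (phi > 0)
    c2: np.ndarray                     # per-channel mean outside
    energy: float
    energy_history: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def _heaviside(phi: np.ndarray, eps: float) -> np.ndarray:
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / eps))


def _delta(phi: np.ndarray, eps: float) -> np.ndarray:
    return (eps / np.pi) / (eps ** 2 + phi ** 2)


def _region_means(image: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel means of F inside (phi > 0) and outside the contour."""
    H = (phi > 0)[..., None]
    w_in = H.sum()
    c1 = (image * H).sum(axis=(0, 1)) / max(w_in, 1e-12)
    c2 = (image * ~H).sum(axis=(0, 1)) / max(image[..., 0].size - w_in, 1e-12)
    return c1, c2


def _grad_mag(phi: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(phi)
    return np.sqrt(gx ** 2 + gy ** 2)


def _smoothed_energy(image: np.ndarray, phi: np.ndarray, c1: np.ndarray,
                     c2: np.ndarray, p: ChanVeseParams) -> float:
    """The energy monitored during descent: the fidelity and area terms use
    the sharp partition (whose means c1, c2 minimise them), the length term
    its smooth relaxation so it varies continuously with phi."""
    H = (phi > 0).astype(float)
    length = float((_delta(phi, p.epsilon) * _grad_mag(phi)).sum())
    area = float(H.sum())
    fid1 = float((((image - c1) ** 2).sum(axis=-1) * H).sum())
    fid2 = float((((image - c2) ** 2).sum(axis=-1) * (1.0 - H)).sum())
    return p.mu1 * length + p.mu2 * area + p.lambda1 * fid1 + p.lambda2 * fid2


def _curvature(phi: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(phi)
    norm = np.sqrt(gx ** 2 + gy ** 2) + 1e-8
    nyy, _ = np.gradient(gy / norm)
    _, nxx = np.gradient(gx / norm)
    return nxx + nyy


def chan_vese_energy(image: np.ndarray, state: ChanVeseState,
                     params: ChanVeseParams | None = None) -> float:
    """Evaluate the (sharp) segmentation energy of a given state.

    The inside region D is phi > 0; the length term is the total variation
    of the binary indicator (the count of 4-neighbour boundary edges), the
    area term the inside pixel count, and each fidelity term sums squared
    per-channel deviations from the state's region means.
    """
    params = params or ChanVeseParams()
    image = as_rgb01(image)
    phi = np.asarray(state.phi, dtype=float)
    if phi.shape != image.shape[:2]:
        raise InvalidInputError(
            f"phi shape {phi.shape} does not match image {image.shape[:2]}"
        )
    H = (phi > 0).astype(float)
    length = float(np.abs(np.diff(H, axis=0)).sum() + np.abs(np.diff(H, axis=1)).sum())
    area = float(H.sum())
    c1 = np.atleast_1d(np.asarray(state.c1, dtype=float))
    c2 = np.atleast_1d(np.asarray(state.c2, dtype=float))
    fid1 = float((((image - c1) ** 2).sum(axis=-1) * H).sum())
    fid2 = float((((image - c2) ** 2).sum(axis=-1) * (1.0 - H)).sum())
    return (params.mu1 * length + params.mu2 * area
            + params.lambda1 * fid1 + params.lambda2 * fid2)


def _checkerboard(shape: tuple[int, int]) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return np.sin(np.pi * yy / 5.0) * np.sin(np.pi * xx / 5.0)


def segment_chan_vese(image: np.ndarray, params: ChanVeseParams | None = None,
                      select: str = "darker",
                      return_state: bool = False):
    """Segment a lesion by minimising the two-region Chan-Vese energy.

    Parameters
    ----------
    image : HxWx3 (or HxW) array in [0,1]
    params : ChanVeseParams, optional
    select : "darker" | "lighter"
        Which of the two regions to return as the lesion; pigmented lesions
        are darker than skin, hence the default.
    return_state : bool
        Also return the final :class:`ChanVeseState` (with energy history).

    Returns the boolean lesion mask (and the state if requested).  Emits a
    warning when max_iter is reached without convergence and returns the
    best mask so far; raises :class:`DegenerateImageError` for a constant
    image.
    """
    params = params or ChanVeseParams()
    if select not in ("darker", "lighter"):
        raise InvalidInputError("select must be 'darker' or 'lighter'")
    image = as_rgb01(image)
    if np.ptp(image) < 1e-8:
        raise DegenerateImageError("constant image admits no two-region partition")

    phi = _checkerboard(image.shape[:2])
    c1, c2 = _region_means(image, phi)
    energy = _smoothed_energy(image, phi, c1, c2, params)
    history = [energy]
    dt = params.dt
    converged = False
    it = 0

    for it in range(1, params.max_iter + 1):
        delta = _delta(phi, params.epsilon)
        fid1 = ((image - c1) ** 2).sum(axis=-1)
        fid2 = ((image - c2) ** 2).sum(axis=-1)
        force = delta * (params.mu1 * _curvature(phi) - params.mu2
                         - params.lambda1 * fid1 + params.lambda2 * fid2)
        # line search over a bidirectional step ladder: only a step that
        # lowers the energy is ever accepted, so the trace is monotone
        best = None
        for factor in (8.0, 4.0, 2.0, 1.0, 0.5, 0.25, 0.125, 0.0625):
            trial_dt = dt * factor
            phi_new = phi + trial_dt * force
            c1_new, c2_new = _region_means(image, phi_new)
            e_new = _smoothed_energy(image, phi_new, c1_new, c2_new, params)
            if e_new <= energy - 1e-12 and (best is None or e_new < best[0]):
                best = (e_new, trial_dt, phi_new, c1_new, c2_new)
        if best is None:
            converged = True
            break
        e_new, dt, phi_new, c1_new, c2_new = best
        step = np.abs(phi_new - phi).max() / max(np.abs(phi).max(), 1e-12)
        phi, c1, c2, energy = phi_new, c1_new, c2_new, e_new
        history.append(energy)
        if step < params.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"Chan-Vese did not converge in {params.max_iter} iterations; "
            "returning best-so-far mask", RuntimeWarning, stacklevel=2)

    inside = phi > 0
    if not inside.any() or inside.all():
        raise DegenerateImageError("segmentation collapsed to a single region")
    luma = image @ _LUMA
    inside_darker = luma[inside].mean() < luma[~inside].mean()
    want_inside = inside_darker if select == "darker" else not inside_darker
    mask = inside if want_inside else ~inside

    if return_state:
        state = ChanVeseState(phi=phi, c1=c1, c2=c2, energy=energy,
                              energy_history=history, iterations=it,
                              converged=converged)
        return mask, state
    return mask
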