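"""Reconstruction and regularization objectives.

The training objective is a structural-similarity (SSIM) reconstruction
loss, optionally combined with a Kullback–Leibler regularizer on a
variational latent:

    SSIM(x, y)  = (2 μx μy + C1)(2 σxy + C2) /
                  ((μx² + μy² + C1)(σx² + σy² + C2))
    SSIM_loss   = mean_i (1 − SSIM(x_i, y_i))
    KLD_loss    = Σ_i σi² + μi² − log(σi) − 1
    L           = SSIM_loss + β · KLD_loss

SSIM is computed with GLOBAL moments over the whole volume (population
variance/covariance), not the sliding-window SSIM of common practice; a
uniform cubic-window variant is available behind ``windowed=True`` for
experimentation.  The KLD term is evaluated exactly as written above —
note the log of σ (not σ²) and the absence of the conventional ½ factor,
so the per-unit term has minimum ≈ −0.1534 at σ = 1/√2 rather than 0.  A
standard Gaussian KLD is available behind ``standard=True``.

Because the network engine has no autodiff, ``ssim_grad``/``kld_grads``
provide closed-form gradients used by the trainer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter


@dataclass(frozen=True)
class SSIMParams:
    """Stabilizers for the SSIM denominators.

    Defaults follow the conventional k1=0.01, k2=0.03 with dynamic range
    L=1 (intensities here are z-scored, so L is a convention, not a fact
    about the data): C1 = 1e-4, C2 = 9e-4.
    """

    C1: float = 1e-4
    C2: float = 9e-4

    def __post_init__(self) -> None:
        if self.C1 < 0 or self.C2 < 0:
            raise ValueError("C1 and C2 must be non-negative")


@dataclass(frozen=True)
class LossConfig:
    """Weighting of the combined objective L = SSIM_loss + beta * KLD_loss.

    ``windowed`` switches the SSIM term to the uniform-cubic-window
    variant (side ``window``), which is far better conditioned for
    gradient-based training on z-scored volumes than the global form
    (whose luminance term collapses whenever the output mean drifts by
    more than ~sqrt(C1) from the near-zero input mean).  Default OFF:
    the global form is the reference objective.
    """

    beta: float = 1e-4
    ssim_params: SSIMParams = field(default_factory=SSIMParams)
    windowed: bool = False
    window: int = 7

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.window < 2:
            raise ValueError("window must be >= 2")


def _moments(x: np.ndarray, y: np.ndarray):
    mx = x.mean()
    my = y.mean()
    vx = x.var()  # population variance
    vy = y.var()
    cov = ((x - mx) * (y - my)).mean()
    return mx, my, vx, vy, cov


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None,
         windowed: bool = False, window: int = 7) -> float:
    """Structural similarity between two equal-shape grids.

    Global-moment form by default; symmetric in (x, y); range [-1, 1].
    """
    params = params or SSIMParams()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in SSIM input")
    if windowed:
        return float(_ssim_windowed(x, y, params, window))
    mx, my, vx, vy, cov = _moments(x, y)
    num = (2 * mx * my + params.C1) * (2 * cov + params.C2)
    den = (mx * mx + my * my + params.C1) * (vx + vy + params.C2)
    return float(num / den)


def _ufilt(a, window):
    # zero-padded box filter: self-adjoint, so the gradient reuses it
    return uniform_filter(a, window, mode="constant", cval=0.0)


def _ssim_windowed(x, y, params, window):
    mx = _ufilt(x, window)
    my = _ufilt(y, window)
    vx = _ufilt(x * x, window) - mx * mx
    vy = _ufilt(y * y, window) - my * my
    cov = _ufilt(x * y, window) - mx * my
    num = (2 * mx * my + params.C1) * (2 * cov + params.C2)
    den = (mx * mx + my * my + params.C1) * (vx + vy + params.C2)
    return (num / den).mean()


def ssim_grad_windowed(x: np.ndarray, y: np.ndarray,
                       params: SSIMParams | None = None,
                       window: int = 7) -> np.ndarray:
    """d/dy of the windowed SSIM mean (adjoint of the box filter)."""
    params = params or SSIMParams()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    n = x.size
    mx = _ufilt(x, window)
    my = _ufilt(y, window)
    vy = _ufilt(y * y, window) - my * my
    vx = _ufilt(x * x, window) - mx * mx
    cov = _ufilt(x * y, window) - mx * my
    A1 = 2 * mx * my + params.C1
    A2 = 2 * cov + params.C2
    B1 = mx * mx + my * my + params.C1
    B2 = vx + vy + params.C2
    N = A1 * A2
    D = B1 * B2
    f_my = (2 * mx * A2 * D - N * 2 * my * B2) / (D * D)
    f_vy = -N * B1 / (D * D)
    f_c = 2 * A1 / D
    # chain rule through my = U y, vy = U(y^2) - my^2, cov = U(xy) - mx my
    term = (_ufilt(f_my, window) - 2 * _ufilt(f_vy * my, window)
            + 2 * y * _ufilt(f_vy, window) + x * _ufilt(f_c, window)
            - _ufilt(f_c * mx, window))
    return term / n


def ssim_grad(x: np.ndarray, y: np.ndarray,
              params: SSIMParams | None = None) -> np.ndarray:
    """d SSIM(x, y) / d y for the global-moment form (closed form)."""
    params = params or SSIMParams()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    n = x.size
    mx, my, vx, vy, cov = _moments(x, y)
    A1 = 2 * mx * my + params.C1
    A2 = 2 * cov + params.C2
    B1 = mx * mx + my * my + params.C1
    B2 = vx + vy + params.C2
    # dN/dy_i and dD/dy_i with dmy = 1/n, dvy = 2(y_i - my)/n,
    # dcov = (x_i - mx)/n
    dN = (2 * mx / n) * A2 + A1 * (2 * (x - mx) / n)
    dD = (2 * my / n) * B2 + B1 * (2 * (y - my) / n)
    D = B1 * B2
    return (dN * D - (A1 * A2) * dD) / (D * D)


def ssim_loss(batch_x, batch_y, params: SSIMParams | None = None) -> float:
    """Mean over the batch of 1 − SSIM per (input, reconstruction) pair."""
    if len(batch_x) != len(batch_y):
        raise ValueError("batch length mismatch")
    if len(batch_x) == 0:
        raise ValueError("empty batch")
    return float(np.mean([1.0 - ssim(x, y, params)
                          for x, y in zip(batch_x, batch_y)]))


def kld_loss(mu: np.ndarray, sigma: np.ndarray, standard: bool = False) -> float:
    """KL regularizer toward a standard normal latent, as-printed form.

    As-printed: sum_i sigma_i^2 + mu_i^2 - log(sigma_i) - 1.  With
    ``standard=True`` the conventional Gaussian KLD
    ½ Σ (σ² + μ² − log σ² − 1) is used instead.
    """
    mu = np.asarray(mu, dtype=np.float64).ravel()
    sigma = np.asarray(sigma, dtype=np.float64).ravel()
    if mu.shape != sigma.shape:
        raise ValueError("mu and sigma must have equal length")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    if standard:
        return float(0.5 * np.sum(sigma**2 + mu**2 - np.log(sigma**2) - 1.0))
    return float(np.sum(sigma**2 + mu**2 - np.log(sigma) - 1.0))


def kld_grads(mu: np.ndarray, sigma: np.ndarray, standard: bool = False):
    """(dKLD/dmu, dKLD/dsigma) for the chosen KLD form."""
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if standard:
        return mu, sigma - 1.0 / sigma
    return 2.0 * mu, 2.0 * sigma - 1.0 / sigma


def ssim_of(x: np.ndarray, y: np.ndarray, config: LossConfig) -> float:
    """SSIM under a LossConfig (global or windowed form)."""
    return ssim(x, y, config.ssim_params, windowed=config.windowed,
                window=config.window)


def ssim_grad_of(x: np.ndarray, y: np.ndarray, config: LossConfig) -> np.ndarray:
    """dSSIM/dy under a LossConfig (global or windowed form)."""
    if config.windowed:
        return ssim_grad_windowed(x, y, config.ssim_params, config.window)
    return ssim_grad(x, y, config.ssim_params)


def total_loss(ssim_l: float, kld_l: float, config: LossConfig | None = None) -> float:
    """Combined objective ssim_l + beta * kld_l (beta=0 for conventional)."""
    config = config or LossConfig()
    return float(ssim_l + config.beta * kld_l)
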