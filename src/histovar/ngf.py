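"""Normalized gradient fields (NGF) distance and its derivatives.

NGF compares gradient *directions* instead of intensities, so it is
minimal when edges align and is insensitive to the monotone intensity
changes produced by different stains.  With the regularized inner
product ``<a, b>_eps = a.b + eps**2`` and norm ``|a|_eps = sqrt(a.a +
eps**2)``, the distance between a reference R and a warped template
T(y(.)) sampled on the reference grid (pixel size h, N pixels) is

    NGF = (h**2 / 2) * sum_i  1 - q_i**2,
    q_i = <grad T(y(x_i)), grad R(x_i)>_eps
          / (|grad T(y(x_i))|_eps * |grad R(x_i)|_eps).

Each summand lies in [0, 1], so 0 <= NGF <= N h**2 / 2.  The edge
parameter eps (intensity per micrometer, the units of the discrete
gradients) separates meaningful edges from noise-level gradients.

Differentiation convention: the template is warped first and the
gradient of the *warped* values is taken on the reference grid with the
same finite-difference stencil used for R.  The chain rule through the
warp therefore runs through (a) the stencil, which is linear in the
warped values, and (b) the spatial derivative of the bilinear
interpolant at the mapped points.  All analytic derivatives below follow
exactly this computational path, so they agree with finite differences
of the implemented objective to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import Image
from .transforms import DeformationGrid, Transform, sample_bilinear

__all__ = [
    "GradientField",
    "NgfSettings",
    "image_gradient",
    "ngf_distance",
    "ngf_objective",
    "ngf_derivative",
    "ngf_value_and_derivative",
]


@dataclass
class NgfSettings:
    """Edge parameter ``epsilon`` in intensity-per-micrometer units."""

    epsilon: float = 0.1

    def __post_init__(self) -> None:
        self.epsilon = float(self.epsilon)
        if not (self.epsilon > 0):
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


@dataclass
class GradientField:
    """Discrete partial derivatives of an image (intensity per um)."""

    gx: np.ndarray
    gy: np.ndarray

    def __post_init__(self) -> None:
        self.gx = np.asarray(self.gx, dtype=np.float64)
        self.gy = np.asarray(self.gy, dtype=np.float64)
        if self.gx.shape != self.gy.shape:
            raise ValueError("gx and gy must have the same shape")
        if not (np.all(np.isfinite(self.gx)) and np.all(np.isfinite(self.gy))):
            raise ValueError("gradient values must be finite")


def _diff_x(a: np.ndarray, h: float) -> np.ndarray:
    g = np.empty_like(a)
    g[:, 1:-1] = (a[:, 2:] - a[:, :-2]) / (2 * h)
    g[:, 0] = (a[:, 1] - a[:, 0]) / h
    g[:, -1] = (a[:, -1] - a[:, -2]) / h
    return g


def _diff_y(a: np.ndarray, h: float) -> np.ndarray:
    g = np.empty_like(a)
    g[1:-1, :] = (a[2:, :] - a[:-2, :]) / (2 * h)
    g[0, :] = (a[1, :] - a[0, :]) / h
    g[-1, :] = (a[-1, :] - a[-2, :]) / h
    return g


def _diff_x_adjoint(w: np.ndarray, h: float) -> np.ndarray:
    a = np.zeros_like(w)
    a[:, 2:] += w[:, 1:-1] / (2 * h)
    a[:, :-2] -= w[:, 1:-1] / (2 * h)
    a[:, 1] += w[:, 0] / h
    a[:, 0] -= w[:, 0] / h
    a[:, -1] += w[:, -1] / h
    a[:, -2] -= w[:, -1] / h
    return a


def _diff_y_adjoint(w: np.ndarray, h: float) -> np.ndarray:
    a = np.zeros_like(w)
    a[2:, :] += w[1:-1, :] / (2 * h)
    a[:-2, :] -= w[1:-1, :] / (2 * h)
    a[1, :] += w[0, :] / h
    a[0, :] -= w[0, :] / h
    a[-1, :] += w[-1, :] / h
    a[-2, :] -= w[-1, :] / h
    return a


def image_gradient(image: Image) -> GradientField:
    """Finite-difference gradient: central differences in the interior,
    one-sided at the boundary, scaled by the physical pixel size."""
    h = image.spacing_um
    return GradientField(_diff_x(image.data, h), _diff_y(image.data, h))


def _gradient_arrays(values: np.ndarray, h: float):
    return _diff_x(values, h), _diff_y(values, h)


def _ngf_ratio(gRx, gRy, gTx, gTy, eps):
    """Per-pixel regularized gradient-alignment ratio q and the norms."""
    inner = gTx * gRx + gTy * gRy + eps * eps
    nT = np.sqrt(gTx * gTx + gTy * gTy + eps * eps)
    nR = np.sqrt(gRx * gRx + gRy * gRy + eps * eps)
    return inner / (nT * nR), nT, nR


def ngf_distance(ref_image: Image, warped_template, settings: NgfSettings,
                 warped_gradient: GradientField | None = None) -> float:
    """NGF distance between a reference and an already-warped template.

    ``warped_template`` is an :class:`Image` (or bare array) on the same
    grid as ``ref_image``; its gradient is computed with the standard
    stencil unless supplied.
    """
    tw = warped_template.data if isinstance(warped_template, Image) else np.asarray(
        warped_template, dtype=np.float64
    )
    if tw.shape != ref_image.shape:
        raise ValueError(
            f"shape mismatch: reference {ref_image.shape} vs warped template "
            f"{tw.shape}"
        )
    h = ref_image.spacing_um
    gR = image_gradient(ref_image)
    if warped_gradient is None:
        gTx, gTy = _gradient_arrays(tw, h)
    else:
        gTx, gTy = warped_gradient.gx, warped_gradient.gy
    q, _, _ = _ngf_ratio(gR.gx, gR.gy, gTx, gTy, settings.epsilon)
    return float(0.5 * h * h * np.sum(np.maximum(1.0 - q * q, 0.0)))


def _warp_and_ratio(ref: Image, template: Image, transform: Transform,
                    settings: NgfSettings, need_gradients: bool):
    """Common forward pass: warp, stencil gradients, per-pixel ratio.

    Returns (q, pieces) where pieces carries the intermediates needed for
    the backward pass when ``need_gradients`` is set.
    """
    h = ref.spacing_um
    x = ref.pixel_centers()
    y = transform.map_points(x)
    if need_gradients:
        tw, tgrad = sample_bilinear(template, y, with_gradient=True)
    else:
        tw = sample_bilinear(template, y)
        tgrad = None
    gTx, gTy = _gradient_arrays(tw, h)
    gR = image_gradient(ref)
    q, nT, nR = _ngf_ratio(gR.gx, gR.gy, gTx, gTy, settings.epsilon)
    pieces = (x, y, tgrad, gR, gTx, gTy, nT, nR, h)
    return q, pieces


def ngf_objective(ref: Image, template: Image, transform: Transform,
                  settings: NgfSettings) -> float:
    """NGF(R, T, y): warp the template by the transform and evaluate."""
    q, (_, _, _, _, _, _, _, _, h) = _warp_and_ratio(
        ref, template, transform, settings, need_gradients=False
    )
    # each summand is mathematically in [0, 1]; clamp rounding noise
    return float(0.5 * h * h * np.sum(np.maximum(1.0 - q * q, 0.0)))


def _dq_dgT(q, gR, gTx, gTy, nT, nR):
    """Partial derivatives of the ratio w.r.t. the warped-template
    gradient components."""
    dq_dgTx = gR.gx / (nT * nR) - q * gTx / (nT * nT)
    dq_dgTy = gR.gy / (nT * nR) - q * gTy / (nT * nT)
    return dq_dgTx, dq_dgTy


def ngf_value_and_derivative(ref: Image, template: Image, transform: Transform,
                             settings: NgfSettings):
    """Objective value and its gradient w.r.t. the transform's parameters.

    Rigid transforms expose 3 parameters (phi, t1, t2), affine 6, and a
    deformation grid one per node displacement component (flattened in
    the grid's own parameter order).
    """
    q, pieces = _warp_and_ratio(ref, template, transform, settings, True)
    x, y, tgrad, gR, gTx, gTy, nT, nR, h = pieces
    value = float(0.5 * h * h * np.sum(np.maximum(1.0 - q * q, 0.0)))
    dq_dgTx, dq_dgTy = _dq_dgT(q, gR, gTx, gTy, nT, nR)
    # dJ/d(gTx, gTy), then back through the (linear) stencil to dJ/dTw
    wx = (-h * h * q) * dq_dgTx
    wy = (-h * h * q) * dq_dgTy
    dJ_dTw = _diff_x_adjoint(wx, h) + _diff_y_adjoint(wy, h)
    # through the interpolant: dJ/dy_i = dJ/dTw_i * grad T(y_i)
    dJ_dy = dJ_dTw[..., None] * tgrad
    if isinstance(transform, DeformationGrid):
        i0, j0, w00, w01, w10, w11 = transform.node_weights(x)
        m1, m2 = transform.grid_shape
        grad = np.zeros((m1, m2, 2))
        flat_idx = (i0 * m2 + j0).ravel()
        gflat = grad.reshape(-1, 2)
        contrib = dJ_dy.reshape(-1, 2)
        np.add.at(gflat, flat_idx, contrib * w00.ravel()[:, None])
        np.add.at(gflat, flat_idx + 1, contrib * w01.ravel()[:, None])
        np.add.at(gflat, flat_idx + m2, contrib * w10.ravel()[:, None])
        np.add.at(gflat, flat_idx + m2 + 1, contrib * w11.ravel()[:, None])
        return value, grad.ravel()
    jac = transform.parameter_jacobian(x)  # (..., 2, p)
    grad = np.einsum("ijc,ijcp->p", dJ_dy, jac)
    return value, grad


def ngf_derivative(ref: Image, template: Image, transform: Transform,
                   settings: NgfSettings) -> np.ndarray:
    """Gradient of the NGF objective w.r.t. the transform parameters."""
    return ngf_value_and_derivative(ref, template, transform, settings)[1]


def ngf_residuals_and_jacobian(ref: Image, template: Image, transform: Transform,
                               settings: NgfSettings):
    """Per-pixel ratios q and their Jacobian w.r.t. the parameters.

    Used by the Gauss-Newton solver for rigid/affine steps:
    J_obj = (h^2/2) sum (1 - q^2), grad = -h^2 J^T q, H ~ h^2 J^T J.
    Returns ``(value, q_flat, jac (N, p), h)``.
    """
    if isinstance(transform, DeformationGrid):
        raise TypeError("Gauss-Newton residuals are only built for rigid/affine")
    q, pieces = _warp_and_ratio(ref, template, transform, settings, True)
    x, y, tgrad, gR, gTx, gTy, nT, nR, h = pieces
    value = float(0.5 * h * h * np.sum(np.maximum(1.0 - q * q, 0.0)))
    dq_dgTx, dq_dgTy = _dq_dgT(q, gR, gTx, gTy, nT, nR)
    pjac = transform.parameter_jacobian(x)  # (..., 2, p)
    p = pjac.shape[-1]
    cols = np.empty(q.shape + (p,))
    for k in range(p):
        # dTw/dp_k through the interpolant, then through the stencil
        dTw = np.einsum("ijc,ijc->ij", tgrad, pjac[..., k])
        cols[..., k] = dq_dgTx * _diff_x(dTw, h) + dq_dgTy * _diff_y(dTw, h)
    return value, q.ravel(), cols.reshape(-1, p), h
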