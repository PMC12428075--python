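"""Squared-exponential (RBF) kernel with ARD lengthscales.

The kernel variance is fixed to 1 by default: in a linear model of
coregionalization the product ``w**2 * kernel_variance`` is not identifiable,
so output scale is carried entirely by the mixing weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RBFKernel:
    """k(x, x') = variance * exp(-0.5 * sum_p ((x_p - x'_p) / l_p)^2)."""

    lengthscales: np.ndarray
    variance: float = 1.0

    def __post_init__(self) -> None:
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if self.variance <= 0 or np.any(self.lengthscales <= 0):
            raise ValueError("kernel hyperparameters must be strictly positive")

    def __call__(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return rbf_gram(self, A, B)


def _scaled_sqdist(A: np.ndarray, B: np.ndarray, ell: np.ndarray) -> np.ndarray:
    As = A / ell
    Bs = B / ell
    d2 = (
        np.sum(As**2, axis=1)[:, None]
        + np.sum(Bs**2, axis=1)[None, :]
        - 2.0 * As @ Bs.T
    )
    return np.maximum(d2, 0.0)


def rbf_gram(kernel: RBFKernel, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gram matrix of the ARD squared-exponential kernel between A (n x P) and B (m x P)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != kernel.lengthscales.size or B.shape[1] != kernel.lengthscales.size:
        raise ValueError("input dimension does not match kernel lengthscales")
    return kernel.variance * np.exp(-0.5 * _scaled_sqdist(A, B, kernel.lengthscales))


def rbf_gram_grads(
    kernel: RBFKernel,
    A: np.ndarray,
    B: np.ndarray,
    K: np.ndarray,
    Gbar: np.ndarray,
    *,
    symmetric: bool = False,
):
    """Backpropagate an adjoint ``Gbar = dF/dK`` through the RBF Gram matrix.

    Returns ``(grad_log_ell, grad_B)`` where ``grad_log_ell[p]`` is the
    gradient with respect to ``log(lengthscale_p)`` and ``grad_B`` the gradient
    with respect to the second input's coordinates.  When ``symmetric`` is true
    A and B are the same array (an inducing Gram matrix) and grad_B accounts
    for both argument slots.
    """
    ell = kernel.lengthscales
    GK = Gbar * K  # elementwise; jitter on the diagonal has zero derivative
    # d k / d log l_p = k * d_p^2 / l_p^2 with d_p = a_p - b_p
    grad_logl = np.empty(ell.size)
    diff_scaled_sum = None
    for p in range(ell.size):
        D = (A[:, p][:, None] - B[:, p][None, :]) / ell[p]
        grad_logl[p] = float(np.sum(GK * D**2))
    # d k(a, b) / d b_p = k * (a_p - b_p) / l_p^2
    if symmetric:
        S = GK + GK.T
        grad_B = np.empty_like(B)
        for p in range(ell.size):
            D = (A[:, p][:, None] - B[:, p][None, :]) / ell[p] ** 2
            grad_B[:, p] = np.sum(S * D, axis=0)
    else:
        grad_B = np.empty_like(B)
        for p in range(ell.size):
            D = (A[:, p][:, None] - B[:, p][None, :]) / ell[p] ** 2
            grad_B[:, p] = np.sum(GK * D, axis=0)
    return grad_logl, grad_B
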