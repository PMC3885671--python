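"""Plug-in bandwidth selection for bivariate kernel density estimation.

Implements the two-stage unconstrained plug-in selector with the
sum-of-asymptotic-mean-squared-error (SAMSE) pilot for the full 2x2
bandwidth matrix H of a Gaussian-kernel density estimate.  The selector
minimizes the asymptotic MISE approximation

    PI(H) = n^-1 (4 pi)^-1 |H|^(-1/2) + (1/4) vech(H)' Psi4 vech(H)

where Psi4 collects the fourth-order integrated density derivative
functionals psi_r = int f^(r)(x) f(x) dx, |r| = 4.  The psi_r are estimated
by kernel double sums with an isotropic pilot bandwidth g chosen to
minimize the summed asymptotic MSE of all fourth-order functionals, with
the sixth-order functionals needed by that pilot taken from the normal
reference.  Data are pre-sphered (whitened by the sample covariance) so the
normal-reference derivatives factorize, and the selected matrix is mapped
back through the sphering transform, which makes the selector exactly
affine-equivariant.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import hermite_e
from scipy import optimize

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _hermite_at(u: np.ndarray, order: int) -> np.ndarray:
    """Probabilists' Hermite polynomial He_order evaluated elementwise."""
    coef = np.zeros(order + 1)
    coef[order] = 1.0
    return hermite_e.hermeval(u, coef)


def _gauss_deriv_1d(u: np.ndarray, order: int) -> np.ndarray:
    """order-th derivative of the standard normal pdf at u."""
    return (-1.0) ** order * _hermite_at(u, order) * np.exp(-0.5 * u * u) / _SQRT2PI


def _he_at_zero(order: int) -> float:
    if order % 2 == 1:
        return 0.0
    # He_{2m}(0) = (-1)^m (2m-1)!!
    m = order // 2
    dfact = 1.0
    for i in range(1, 2 * m, 2):
        dfact *= i
    return (-1.0) ** m * dfact


def _psi_normal_reference(r: tuple[int, int], sigma2: float = 2.0) -> float:
    """psi_r for a standard bivariate normal density: phi_{2I}^{(r)}(0).

    With sphered data the reference covariance is the identity, so the
    convolution phi_Sigma * phi_Sigma = phi_{2 Sigma} has diagonal
    covariance ``sigma2 * I`` and the derivative factorizes over axes.
    """
    s = np.sqrt(sigma2)
    out = 1.0
    for k in r:
        out *= (-1.0) ** k * _he_at_zero(k) * (1.0 / _SQRT2PI) / s ** (k + 1)
    return out


def _kernel_deriv_at_zero(r: tuple[int, int]) -> float:
    """D^r of the standard bivariate Gaussian kernel at the origin."""
    out = 1.0
    for k in r:
        out *= (-1.0) ** k * _he_at_zero(k) / _SQRT2PI
    return out


_R4 = [(4, 0), (3, 1), (2, 2), (1, 3), (0, 4)]


def _samse_pilot(n: int) -> float:
    """Isotropic pilot g minimizing the summed asymptotic MSE of psi_r, |r|=4.

    The asymptotic bias of psi_hat_r(g) is
    n^-1 g^-(d+|r|) K^(r)(0) + (g^2 / 2) (psi_{r+2e1} + psi_{r+2e2});
    SAMSE minimizes the sum of squared biases over all |r| = 4, with the
    sixth-order functionals at their (sphered) normal-reference values.
    """
    d = 2

    def samse(log_g: float) -> float:
        g = np.exp(log_g)
        total = 0.0
        for r in _R4:
            lead = _kernel_deriv_at_zero(r) / (n * g ** (d + 4))
            psi6 = (_psi_normal_reference((r[0] + 2, r[1]))
                    + _psi_normal_reference((r[0], r[1] + 2)))
            bias = lead + 0.5 * g * g * psi6
            total += bias * bias
        return total

    res = optimize.minimize_scalar(samse, bounds=(np.log(1e-3), np.log(10.0)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return float(np.exp(res.x))


def _psi4_hat(z: np.ndarray, g: float, chunk: int = 256) -> dict[tuple[int, int], float]:
    """Kernel double-sum estimates of all fourth-order psi_r on sphered data.

    psi_hat_r = n^-2 sum_i sum_j K_{g^2 I}^{(r)}(Z_i - Z_j), including the
    i = j diagonal terms.  Chunked over rows to bound memory at ~n*chunk.
    """
    n = len(z)
    sums = {r: 0.0 for r in _R4}
    for start in range(0, n, chunk):
        block = z[start:start + chunk]
        u1 = (block[:, None, 0] - z[None, :, 0]) / g
        u2 = (block[:, None, 1] - z[None, :, 1]) / g
        phi1 = {k: _gauss_deriv_1d(u1, k) for k in range(5)}
        phi2 = {k: _gauss_deriv_1d(u2, k) for k in range(5)}
        for r in _R4:
            sums[r] += float(np.sum(phi1[r[0]] * phi2[r[1]]))
    scale = 1.0 / (n * n * g ** (2 + 4))
    return {r: s * scale for r, s in sums.items()}


def _psi4_matrix(psi: dict[tuple[int, int], float]) -> np.ndarray:
    """3x3 quadratic form so that vech(H)' Psi4 vech(H) equals
    the integrated squared bias term  int (tr(H Hess f))^2 / 4-free part,
    with vech(H) = (h11, h12, h22)."""
    p40, p31, p22, p13, p04 = (psi[r] for r in _R4)
    return np.array([
        [p40, 2.0 * p31, p22],
        [2.0 * p31, 4.0 * p22, 2.0 * p13],
        [p22, 2.0 * p13, p04],
    ])


def plugin_bandwidth(points: np.ndarray, rel_tol: float = 1e-6) -> np.ndarray:
    """Two-stage SAMSE plug-in bandwidth matrix for bivariate data.

    Parameters
    ----------
    points : (n, 2) array
        At least 10 distinct planar points; degenerate (collinear or
        effectively one-dimensional) configurations are rejected.

    Returns
    -------
    (2, 2) ndarray
        Symmetric positive-definite bandwidth matrix H in squared data
        units.  Deterministic for fixed input.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(x)
    if len(np.unique(x, axis=0)) < 10:
        raise ValueError("plug-in bandwidth needs at least 10 distinct points")
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 0 or evals.min() / evals.max() < 1e-12:
        raise ValueError("degenerate point configuration: "
                         "points are collinear or coincident")

    # pre-sphere
    s_inv_half = evecs @ np.diag(evals ** -0.5) @ evecs.T
    s_half = evecs @ np.diag(evals ** 0.5) @ evecs.T
    z = (x - x.mean(axis=0)) @ s_inv_half

    g = _samse_pilot(n)
    psi4 = _psi4_matrix(_psi4_hat(z, g))

    rk = 1.0 / (4.0 * np.pi)  # roughness of the bivariate Gaussian kernel

    def objective(theta: np.ndarray) -> float:
        # Cholesky parameterization guarantees positive definiteness
        l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
        h11 = l11 * l11
        h12 = l11 * l21
        h22 = l21 * l21 + l22 * l22
        det = h11 * h22 - h12 * h12
        vech = np.array([h11, h12, h22])
        bias = float(vech @ psi4 @ vech)
        return rk / (n * np.sqrt(det)) + 0.25 * bias

    h0 = n ** (-1.0 / 3.0)  # normal-scale start on sphered data
    theta0 = np.array([0.5 * np.log(h0), 0.0, 0.5 * np.log(h0)])
    res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                            options={"xatol": rel_tol, "fatol": rel_tol,
                                     "maxiter": 4000})
    l11, l21, l22 = np.exp(res.x[0]), res.x[1], np.exp(res.x[2])
    h_sphered = np.array([[l11 * l11, l11 * l21],
                          [l11 * l21, l21 * l21 + l22 * l22]])
    h = s_half @ h_sphered @ s_half
    return 0.5 * (h + h.T)


def normal_scale_bandwidth(points: np.ndarray) -> np.ndarray:
    """Normal reference rule H = n^(-1/3) * Sigma_hat (bivariate Gaussian)."""
    x = np.asarray(points, dtype=float)
    return len(x) ** (-1.0 / 3.0) * np.cov(x, rowvar=False)
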