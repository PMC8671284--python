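"""Generalized polynomial chaos over one uniformly distributed parameter.

The uncertain split value α ~ U(low, high) is expanded in Legendre
polynomials, the natural orthogonal family for a uniform weight.  The
basis used here is orthonormal with respect to the *probability* measure
of α:  Φ_k(α) = √(2k+1) · P_k(u),  u = (2α − low − high)/(high − low),
so that ⟨Φ_j, Φ_k⟩ = δ_jk and every Galerkin projection denominator is 1.

A quantity of interest X(α) — a scalar or a whole time-resolved waveform —
is evaluated at a handful of Gauss–Legendre collocation nodes, projected
onto the basis by the matching quadrature, and thereafter interrogated
through the cheap surrogate: stochastic mean, standard deviation, sampled
probability density, convergence diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = [
    "UncertainParam",
    "GPCExpansion",
    "quadrature_nodes",
    "basis_matrix",
    "project",
    "project_lstsq",
    "evaluate",
    "moments",
    "pdf",
    "convergence_check",
    "n_terms",
]


@dataclass(frozen=True)
class UncertainParam:
    """Uniform uncertain parameter on [low, high] expanded to degree `order`."""

    low: float = -0.15
    high: float = -0.08
    order: int = 3

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("require low < high")
        if self.order < 0:
            raise ValueError("order must be nonnegative")

    def to_standard(self, x):
        """Affine map [low, high] → [−1, 1]."""
        return (2.0 * np.asarray(x, dtype=float) - self.low - self.high) / (self.high - self.low)

    def from_standard(self, u):
        return 0.5 * ((self.high - self.low) * np.asarray(u, dtype=float) + self.low + self.high)


def n_terms(orders) -> int:
    """Number of expansion terms Λ+1 = Π(Pᵢ+1) for a full tensor basis.

    With a single parameter this reduces to order + 1.
    """
    orders = np.atleast_1d(orders)
    return int(np.prod(orders + 1))


@dataclass
class GPCExpansion:
    """Coefficients a_k of X(α) = Σ a_k Φ_k(α), Φ orthonormal Legendre.

    ``coeffs`` has shape (order+1,) for a scalar quantity or
    (order+1, n_samples) for a time-resolved one.
    """

    coeffs: np.ndarray
    param: UncertainParam

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape[0] != self.param.order + 1:
            raise ValueError("coefficient count must equal order + 1")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite expansion coefficients")

    @property
    def order(self) -> int:
        return self.param.order


def quadrature_nodes(param: UncertainParam, n: int):
    """Gauss–Legendre nodes on [low, high] with probability weights (Σw = 1)."""
    if n < 1:
        raise ValueError("need at least one quadrature node")
    u, w = np.polynomial.legendre.leggauss(n)
    nodes = param.from_standard(u)
    weights = w / 2.0  # standard weights sum to 2; normalize to a PDF
    return nodes, weights


def basis_matrix(param: UncertainParam, x) -> np.ndarray:
    """Φ_k(x) for k = 0..order; shape (len(x), order+1)."""
    u = np.atleast_1d(param.to_standard(x))
    cols = []
    for k in range(param.order + 1):
        ck = np.zeros(k + 1)
        ck[k] = 1.0
        cols.append(np.sqrt(2 * k + 1) * npleg.legval(u, ck))
    return np.stack(cols, axis=-1)


def project(evaluations, param: UncertainParam, nodes=None, weights=None) -> GPCExpansion:
    """Galerkin coefficients a_k = Σ_q w_q X(α_q) Φ_k(α_q) by quadrature.

    ``evaluations`` holds X at the quadrature nodes, shape (n_nodes, ...);
    by default the nodes are the Gauss rule with as many points as
    evaluations, which integrates the required degree exactly provided
    n_nodes ≥ order + 1.
    """
    evals = np.asarray(evaluations, dtype=float)
    n_nodes = evals.shape[0]
    if n_nodes < param.order + 1:
        raise ValueError(
            f"{n_nodes} nodes cannot resolve order {param.order}; "
            "need at least order + 1"
        )
    if nodes is None:
        nodes, weights = quadrature_nodes(param, n_nodes)
    phi = basis_matrix(param, nodes)  # (n_nodes, order+1)
    wx = weights[:, None] * phi       # (n_nodes, order+1)
    coeffs = np.tensordot(wx, evals, axes=(0, 0))  # (order+1, ...)
    return GPCExpansion(coeffs=coeffs, param=param)


def project_lstsq(evaluations, param: UncertainParam, nodes) -> GPCExpansion:
    """Least-squares projection for arbitrary (e.g. rounded) node locations.

    Accepts any node set with more points than the order; useful when the
    forward model was run at hand-picked α values rather than at the exact
    Gauss abscissae.
    """
    evals = np.asarray(evaluations, dtype=float)
    nodes = np.asarray(nodes, dtype=float)
    if nodes.size <= param.order:
        raise ValueError("need more nodes than the polynomial order")
    phi = basis_matrix(param, nodes)
    flat = evals.reshape(nodes.size, -1)
    coeffs, *_ = np.linalg.lstsq(phi, flat, rcond=None)
    return GPCExpansion(coeffs=coeffs.reshape((param.order + 1,) + evals.shape[1:]),
                        param=param)


def evaluate(exp: GPCExpansion, xi):
    """Evaluate the truncated expansion at α = xi (scalar or array)."""
    xi_arr = np.atleast_1d(np.asarray(xi, dtype=float))
    if np.any(xi_arr < exp.param.low) or np.any(xi_arr > exp.param.high):
        warnings.warn("evaluating the gPC surrogate outside its support",
                      stacklevel=2)
    phi = basis_matrix(exp.param, xi_arr)  # (m, order+1)
    out = np.tensordot(phi, exp.coeffs, axes=(1, 0))  # (m, ...)
    if np.isscalar(xi) or np.ndim(xi) == 0:
        return out[0]
    return out


def moments(exp: GPCExpansion):
    """Stochastic mean and standard deviation from the coefficients.

    With an orthonormal basis the mean is a₀ and the variance is the sum
    of the squared higher coefficients.
    """
    mean = exp.coeffs[0]
    std = np.sqrt(np.sum(exp.coeffs[1:] ** 2, axis=0))
    return mean, std


def pdf(exp: GPCExpansion, n_samples: int = 100_000, seed: int = 0, bins: int = 50):
    """Sampled probability density of the surrogate output.

    Draws uniform α, evaluates the expansion and histograms the result.
    For a time-resolved quantity the histogram is built per time sample,
    yielding a (time × value) probability map.  Returns (bin_edges,
    density); density integrates to 1 along the value axis.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be at least 1000")
    rng = np.random.default_rng(seed)
    xi = rng.uniform(exp.param.low, exp.param.high, n_samples)
    samples = evaluate(exp, xi)  # (n_samples, ...) or (n_samples,)
    samples = np.atleast_2d(samples.T if samples.ndim > 1 else samples[None, :])
    # samples is now (n_components, n_samples)
    lo = samples.min()
    hi = samples.max()
    if hi == lo:  # constant surrogate: one occupied bin
        hi = lo + max(abs(lo), 1.0) * 1e-12
    edges = np.linspace(lo, hi, bins + 1)
    dens = np.stack([np.histogram(row, bins=edges, density=True)[0]
                     for row in samples])
    if dens.shape[0] == 1:
        dens = dens[0]
    return edges, dens


def convergence_check(exp: GPCExpansion) -> float:
    """Relative contribution of the highest-order term, |a_Λ| / ‖a‖.

    For a time-resolved quantity the maximum over time samples is
    returned.  Small values indicate the truncation order suffices.
    """
    if exp.order < 1:
        raise ValueError("convergence check needs order >= 1")
    norm = np.sqrt(np.sum(exp.coeffs ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(norm > 0, np.abs(exp.coeffs[-1]) / norm, 0.0)
    return float(np.max(ratio))
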