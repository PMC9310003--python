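"""Orientation-averaged intensities over uniform (Haar) random orientation.

Averaging an intensity over all molecular orientations replaces the squared
field contractions by rotation invariants of the mode tensors:

* IR: ``⟨|e·Rμ′|²⟩ = |μ′|²/3`` for any unit e, so ``⟨I^A⟩ = C_A|μ′|²/3``.

* Raman: with the Placzek invariants ``a′ = tr ᾱ′/3`` and
  ``γ′² = ½[(α′xx−α′yy)² + (α′yy−α′zz)² + (α′zz−α′xx)²] + 3(α′xy²+α′yz²+α′zx²)``,
  the averaged squared contraction is ``(45a′² + 4γ′²)/45`` for parallel
  in/out polarizations and ``3γ′²/45`` for crossed ones; oblique pairs
  interpolate bilinearly in ``(e_in·e_out)²``.

* SFG: the IR and Raman factors share the rotation, so the average of the
  product does not factorize; ``⟨|e_IR·Rμ′|²·(e_out·Rᾱ′Rᵀ·e_in)²⟩`` is a
  degree-6 polynomial in the rotation entries and is evaluated in closed
  form through the exact sixth-moment tensor of the orthogonal group
  (Weingarten calculus over the 15 pair matchings of six indices, computed
  once in exact rational arithmetic at import).

An independent product-Gauss quadrature oracle over Euler angles
(:func:`haar_average`) evaluates the same averages to machine precision for
polynomial integrands and is used in the test suite to pin the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Callable

import numpy as np

from .constants import C, C_A
from .orientation import EulerOrientation, FieldSetup, rotation_matrix
from .intensities import raman_prefactor
from .vibrecord import NormalMode

# ----------------------------------------------------------------------
# Placzek invariants


@dataclass(frozen=True)
class TensorInvariants:
    """Rotation invariants of a symmetric polarizability-derivative tensor."""

    a_prime: float
    gamma2_prime: float


def tensor_invariants(alpha: np.ndarray) -> TensorInvariants:
    """Mean polarizability derivative a′ and anisotropy γ′² of a 3×3 tensor."""
    alpha = np.asarray(alpha, dtype=float).reshape(3, 3)
    a = float(np.trace(alpha)) / 3.0
    d = np.diag(alpha)
    gamma2 = 0.5 * (
        (d[0] - d[1]) ** 2 + (d[1] - d[2]) ** 2 + (d[2] - d[0]) ** 2
    ) + 3.0 * (alpha[0, 1] ** 2 + alpha[1, 2] ** 2 + alpha[2, 0] ** 2)
    return TensorInvariants(a_prime=a, gamma2_prime=float(gamma2))


# ----------------------------------------------------------------------
# Quadrature oracle: exact Haar average for polynomial integrands

_N_THETA = 12  # Gauss–Legendre nodes in cosθ (exact to polynomial degree 23)
_N_AZIMUTH = 16  # uniform nodes in ϕ and ξ (exact to trig degree 15)


def haar_average(f: Callable[[np.ndarray], float], degree: int = 6) -> float:
    """Uniform-measure SO(3) average of ``f(R)`` by product Gauss quadrature.

    Exact (to quadrature precision) whenever ``f`` is a polynomial of total
    degree ≤ ``degree`` in the rotation-matrix entries.  The fixed node
    counts (12 Gauss–Legendre in cosθ, 16 uniform in ϕ and ξ) are exact for
    degree ≤ 15 with margin.
    """
    if degree > 15:
        raise ValueError(f"node counts are exact only up to degree 15, got {degree}")
    x, w = np.polynomial.legendre.leggauss(_N_THETA)  # x = cosθ on [-1, 1]
    thetas = np.arccos(x)
    azimuths = 2.0 * np.pi * np.arange(_N_AZIMUTH) / _N_AZIMUTH
    total = 0.0
    for theta, wt in zip(thetas, w):
        for phi in azimuths:
            for xi in azimuths:
                r = rotation_matrix(EulerOrientation(phi, theta, xi))
                total += wt * f(r)
    # weights integrate d(cosθ)/2 × dϕ/2π × dξ/2π
    return total / (2.0 * _N_AZIMUTH * _N_AZIMUTH)


# ----------------------------------------------------------------------
# Exact sixth-moment machinery (orthogonal Weingarten calculus)


def _pair_matchings(elems: tuple[int, ...]) -> list[tuple[tuple[int, int], ...]]:
    if not elems:
        return [()]
    a, rest = elems[0], elems[1:]
    out = []
    for i, b in enumerate(rest):
        remaining = rest[:i] + rest[i + 1 :]
        for m in _pair_matchings(remaining):
            out.append(((a, b),) + m)
    return out


def _loop_count(s, t) -> int:
    adj: dict[int, list[int]] = {}
    for a, b in (*s, *t):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    seen: set[int] = set()
    comps = 0
    for v in adj:
        if v in seen:
            continue
        comps += 1
        stack = [v]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(adj[u])
    return comps


def _weingarten(matchings) -> np.ndarray:
    """Exact rational inverse of the Gram matrix G_{στ} = 3^{#loops(σ,τ)}."""
    n = len(matchings)
    aug = [
        [Fraction(3) ** _loop_count(matchings[i], matchings[j]) for j in range(n)]
        + [Fraction(int(i == j)) for j in range(n)]
        for i in range(n)
    ]
    for col in range(n):
        piv = next(r for r in range(col, n) if aug[r][col] != 0)
        aug[col], aug[piv] = aug[piv], aug[col]
        inv = aug[col][col]
        aug[col] = [x / inv for x in aug[col]]
        for r in range(n):
            if r != col and aug[r][col] != 0:
                fac = aug[r][col]
                aug[r] = [x - fac * y for x, y in zip(aug[r], aug[col])]
    return np.array([[float(aug[i][n + j]) for j in range(n)] for i in range(n)])


_MATCHINGS = _pair_matchings(tuple(range(6)))
_WG6 = _weingarten(_MATCHINGS)

# einsum subscripts contracting a 3^6 tensor with each delta pattern
_LETTERS = "abcdef"
_EINSUM6 = []
for _m in _MATCHINGS:
    _sub = [""] * 6
    for _k, (_i, _j) in enumerate(_m):
        _sub[_i] = _sub[_j] = _LETTERS[_k]
    _EINSUM6.append("".join(_sub) + "->")


def _matching_contractions(t: np.ndarray) -> np.ndarray:
    return np.array([np.einsum(sub, t) for sub in _EINSUM6])


def isotropic_product_average(
    mu: np.ndarray, alpha: np.ndarray, e_ir: np.ndarray, e_in: np.ndarray, e_out: np.ndarray
) -> float:
    """Closed-form ``⟨|e_IR·Rμ|² · (e_out·RαRᵀ·e_in)²⟩`` over uniform SO(3).

    The integrand is a degree-6 polynomial in the entries of R; the uniform
    average of the six-fold tensor power of R is expressed through the
    orthogonal Weingarten matrix over pair matchings (even degree, so the
    SO(3) and O(3) averages coincide).
    """
    mu = np.asarray(mu, float).reshape(3)
    alpha = np.asarray(alpha, float).reshape(3, 3)
    left = np.einsum("a,b,c,d,e,f->abcdef", e_ir, e_ir, e_out, e_in, e_out, e_in)
    right = np.einsum("a,b,cd,ef->abcdef", mu, mu, alpha, alpha)
    lv = _matching_contractions(left)
    rv = _matching_contractions(right)
    return float(lv @ _WG6 @ rv)


# ----------------------------------------------------------------------
# Averaged intensities


def average_ir(m: NormalMode) -> float:
    """Orientation-averaged IR intensity ``C_A|μ′|²/3`` (km/mol)."""
    return C_A * float(np.dot(m.dipole_derivative, m.dipole_derivative)) / 3.0


def average_raman_contraction(alpha: np.ndarray, e_in, e_out) -> float:
    """Averaged squared contraction ``⟨(e_out·RαRᵀ·e_in)²⟩`` for unit fields.

    Exact bilinear form in ``c² = (e_in·e_out)²``:
    ``u·c² + v·(1 + c²)`` with ``u = (2S1 − S2)/15``, ``v = (3S2 − S1)/30``,
    ``S1 = (tr α)²``, ``S2 = tr(α²)``; equivalently ``(45a′²+4γ′²)/45`` for
    parallel and ``3γ′²/45`` for crossed polarizations.
    """
    alpha = np.asarray(alpha, float).reshape(3, 3)
    s1 = float(np.trace(alpha)) ** 2
    s2 = float(np.sum(alpha * alpha.T))
    u = (2.0 * s1 - s2) / 15.0
    v = (3.0 * s2 - s1) / 30.0
    c2 = float(np.dot(np.asarray(e_in, float), np.asarray(e_out, float))) ** 2
    return u * c2 + v * (1.0 + c2)


def average_raman(m: NormalMode, f: FieldSetup, bare: bool = False) -> float:
    """Orientation-averaged Stokes Raman cross-section (cm²/sr)."""
    contraction = average_raman_contraction(m.polarizability_derivative, f.e_in, f.e_out)
    if bare:
        return contraction
    return raman_prefactor(m.wavenumber, f, stokes=True) * contraction


def average_sfg(m: NormalMode, f: FieldSetup) -> float:
    """Orientation-averaged SFG coefficient.

    The IR and Raman tensor factors are averaged *jointly* — the molecule's
    orientation is shared, so the average of the product differs from the
    product of the averages whenever the Raman tensor is anisotropic.
    """
    joint = isotropic_product_average(
        m.dipole_derivative, m.polarizability_derivative, f.e_ir, f.e_in, f.e_out
    )
    return C_A * raman_prefactor(m.wavenumber, f, stokes=False) * joint


def average_intensity(m: NormalMode, f: FieldSetup, kind: str) -> float:
    """Dispatch on ``kind`` in {'ir', 'raman', 'sfg'} (orientation-averaged)."""
    kind = kind.lower()
    if kind == "ir":
        return average_ir(m)
    if kind == "raman":
        return average_raman(m, f)
    if kind == "sfg":
        return average_sfg(m, f)
    raise ValueError(f"unknown intensity kind {kind!r}")
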