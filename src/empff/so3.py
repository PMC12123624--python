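"""Real spherical harmonics, Clebsch-Gordan tables, and symmetric coupling schemes.

Conventions
-----------
* Real spherical harmonics ``Y_lm`` with **unit L2 norm on the sphere**
  (``∫ Y_lm Y_l'm' dΩ = δ``), no Condon-Shortley phase: all Cartesian
  polynomial prefactors are positive, e.g. ``Y_11 = √(3/4π)·x/r``.
* Flattened (l, m) enumeration is l ascending, m ascending:
  index ``l² + l + m``; the l=1 block is therefore ordered ``(y, z, x)``.
* Real Clebsch-Gordan tables are the unique (up to sign) intertwiners
  ``V_l1 ⊗ V_l2 → V_l3`` of real SO(3) irreps, normalized so that
  ``Σ_{m1,m2} C² = 1`` for each m3, with the lexicographically first
  nonzero entry positive.  They are constructed numerically as the null
  space of the equivariance constraint under a fixed set of seeded
  rotations, which makes the construction convention-free and exactly
  consistent with :func:`rotate_features`.
* Coupling paths η for ν-fold symmetric products use a left-to-right
  binary coupling tree ``((l1 l2) l12) l3 → L`` with paths enumerated
  lexicographically in ``(l1, l2, l3, l12)``.

Everything is double precision and cached per (l_max, ν, L_max).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y


def lm_index(l: int, m: int) -> int:
    """Flattened index of (l, m): l ascending, m ascending within l."""
    return l * l + l + m


def num_lm(l_max: int) -> int:
    return (l_max + 1) ** 2


def lm_slice(l: int) -> slice:
    """Slice of the 2l+1 components of degree l in the flattened layout."""
    return slice(l * l, (l + 1) * (l + 1))


# ---------------------------------------------------------------------------
# Real solid harmonics P_lm = r^l Y_lm(r̂) as monomial tables (l ≤ 3).
# Each entry: list of (i, j, k, coefficient) for c · x^i y^j z^k.
# ---------------------------------------------------------------------------

_PI = math.pi
_SOLID_MONOMIALS: dict[tuple[int, int], list[tuple[int, int, int, float]]] = {
    (0, 0): [(0, 0, 0, math.sqrt(1 / (4 * _PI)))],
    (1, -1): [(0, 1, 0, math.sqrt(3 / (4 * _PI)))],
    (1, 0): [(0, 0, 1, math.sqrt(3 / (4 * _PI)))],
    (1, 1): [(1, 0, 0, math.sqrt(3 / (4 * _PI)))],
    (2, -2): [(1, 1, 0, math.sqrt(15 / (4 * _PI)))],
    (2, -1): [(0, 1, 1, math.sqrt(15 / (4 * _PI)))],
    (2, 0): [(0, 0, 2, 2 * math.sqrt(5 / (16 * _PI))),
             (2, 0, 0, -math.sqrt(5 / (16 * _PI))),
             (0, 2, 0, -math.sqrt(5 / (16 * _PI)))],
    (2, 1): [(1, 0, 1, math.sqrt(15 / (4 * _PI)))],
    (2, 2): [(2, 0, 0, math.sqrt(15 / (16 * _PI))),
             (0, 2, 0, -math.sqrt(15 / (16 * _PI)))],
    (3, -3): [(2, 1, 0, 3 * math.sqrt(35 / (32 * _PI))),
              (0, 3, 0, -math.sqrt(35 / (32 * _PI)))],
    (3, -2): [(1, 1, 1, math.sqrt(105 / (4 * _PI)))],
    (3, -1): [(0, 1, 2, 4 * math.sqrt(21 / (32 * _PI))),
              (2, 1, 0, -math.sqrt(21 / (32 * _PI))),
              (0, 3, 0, -math.sqrt(21 / (32 * _PI)))],
    (3, 0): [(0, 0, 3, 2 * math.sqrt(7 / (16 * _PI))),
             (2, 0, 1, -3 * math.sqrt(7 / (16 * _PI))),
             (0, 2, 1, -3 * math.sqrt(7 / (16 * _PI)))],
    (3, 1): [(1, 0, 2, 4 * math.sqrt(21 / (32 * _PI))),
             (3, 0, 0, -math.sqrt(21 / (32 * _PI))),
             (1, 2, 0, -math.sqrt(21 / (32 * _PI)))],
    (3, 2): [(2, 0, 1, math.sqrt(105 / (16 * _PI))),
             (0, 2, 1, -math.sqrt(105 / (16 * _PI)))],
    (3, 3): [(3, 0, 0, math.sqrt(35 / (32 * _PI))),
             (1, 2, 0, -3 * math.sqrt(35 / (32 * _PI)))],
}

LMAX_GRAD = 3  # largest degree with analytic Cartesian gradients


def _eval_solid(vecs: np.ndarray, l_max: int):
    """Solid harmonics P and their Cartesian gradients dP for l ≤ l_max ≤ 3.

    Returns ``P`` with shape (..., (l_max+1)²) and ``dP`` (..., (l_max+1)², 3).
    """
    if l_max > LMAX_GRAD:
        raise ValueError(f"analytic solid harmonics limited to l ≤ {LMAX_GRAD}")
    x, y, z = vecs[..., 0], vecs[..., 1], vecs[..., 2]
    shape = vecs.shape[:-1]
    P = np.zeros(shape + (num_lm(l_max),))
    dP = np.zeros(shape + (num_lm(l_max), 3))
    powx = [np.ones_like(x), x, x * x, x * x * x]
    powy = [np.ones_like(y), y, y * y, y * y * y]
    powz = [np.ones_like(z), z, z * z, z * z * z]
    for l in range(l_max + 1):
        for m in range(-l, l + 1):
            idx = lm_index(l, m)
            for (i, j, k, c) in _SOLID_MONOMIALS[(l, m)]:
                P[..., idx] += c * powx[i] * powy[j] * powz[k]
                if i > 0:
                    dP[..., idx, 0] += c * i * powx[i - 1] * powy[j] * powz[k]
                if j > 0:
                    dP[..., idx, 1] += c * j * powx[i] * powy[j - 1] * powz[k]
                if k > 0:
                    dP[..., idx, 2] += c * k * powx[i] * powy[j] * powz[k - 1]
    return P, dP


def real_spherical_harmonics(direction: np.ndarray, l_max: int) -> np.ndarray:
    """Real spherical harmonics of unit vector(s), flattened (l, m) layout.

    ``direction`` must be unit-norm to 1e-8.  Supports arbitrary ``l_max``
    (degrees above 3 are built from the complex harmonics of scipy).
    """
    direction = np.asarray(direction, dtype=float)
    if l_max < 0:
        raise ValueError("l_max must be non-negative")
    norms = np.linalg.norm(direction, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("direction must be a unit vector (‖v‖ = 1 within 1e-8)")
    if l_max <= LMAX_GRAD:
        P, _ = _eval_solid(direction, l_max)
        return P
    return _real_sph_any(direction, l_max)


def _real_sph_any(direction: np.ndarray, l_max: int) -> np.ndarray:
    """Real Y_lm for arbitrary l via scipy's complex harmonics (values only)."""
    x, y, z = direction[..., 0], direction[..., 1], direction[..., 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    out = np.zeros(direction.shape[:-1] + (num_lm(l_max),))
    for l in range(l_max + 1):
        for m in range(0, l + 1):
            ylm = sph_harm_y(l, m, theta, phi)
            if m == 0:
                out[..., lm_index(l, 0)] = ylm.real
            else:
                s = math.sqrt(2.0) * (-1.0) ** m
                out[..., lm_index(l, m)] = s * ylm.real
                out[..., lm_index(l, -m)] = s * ylm.imag
    return out


def spherical_harmonics_with_gradient(r_vec: np.ndarray, l_max: int):
    """Y_lm(r̂) and its gradient with respect to the (non-unit) vector r.

    Uses ``Y(r̂) = P(r)/r^l`` with P the solid harmonic, so
    ``∇Y = ∇P/r^l − l·P·r/r^{l+2}``.  l_max ≤ 3.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec, axis=-1)
    if np.any(r < 1e-12):
        raise ValueError("zero-length vector")
    P, dP = _eval_solid(r_vec, l_max)
    Y = np.empty_like(P)
    dY = np.empty_like(dP)
    for l in range(l_max + 1):
        sl = lm_slice(l)
        rl = r[..., None] ** l
        Y[..., sl] = P[..., sl] / rl
        dY[..., sl, :] = (dP[..., sl, :] / rl[..., None]
                          - l * P[..., sl, None] * r_vec[..., None, :]
                          / (r[..., None, None] ** (l + 2)))
    return Y, dY


# ---------------------------------------------------------------------------
# Real Wigner-D rotation of flattened features
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    ga = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = ga * i
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=-1)


def _check_rotation(R: np.ndarray):
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3×3 matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be orthogonal")
    if np.linalg.det(R) < 0:
        raise ValueError("improper rotation (determinant must be +1)")
    return R


def wigner_d_real(R: np.ndarray, l: int) -> np.ndarray:
    """Real Wigner-D block for degree l: ``Y_l(R·v) = D_l(R) · Y_l(v)``.

    Obtained by least squares over a dense set of sample directions; exact to
    solver precision (~1e-13) for all l.
    """
    R = _check_rotation(R)
    if l == 0:
        return np.ones((1, 1))
    pts = _fibonacci_sphere(max(4 * (2 * l + 1), 24))
    Yv = _real_sph_block(pts, l)
    YRv = _real_sph_block(pts @ R.T, l)
    Dt, *_ = np.linalg.lstsq(Yv, YRv, rcond=None)
    return Dt.T


def _real_sph_block(dirs: np.ndarray, l: int) -> np.ndarray:
    if l <= LMAX_GRAD:
        P, _ = _eval_solid(dirs, l)
        return P[..., lm_slice(l)]
    return _real_sph_any(dirs, l)[..., lm_slice(l)]


def rotate_features(features: np.ndarray, R: np.ndarray, l_max: int | None = None,
                    axis: int = -1) -> np.ndarray:
    """Apply the block-diagonal real Wigner-D action of a proper rotation.

    ``features`` carries a flattened (l, m) axis of length (l_max+1)²
    (by default the last axis).
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[axis]
    if l_max is None:
        l_max = int(round(math.sqrt(n))) - 1
    if num_lm(l_max) != n:
        raise ValueError("feature axis length is not a perfect square (l_max+1)²")
    R = _check_rotation(R)
    features = np.moveaxis(features, axis, -1)
    out = np.empty_like(features)
    for l in range(l_max + 1):
        D = wigner_d_real(R, l)
        sl = lm_slice(l)
        out[..., sl] = features[..., sl] @ D.T
    return np.moveaxis(out, -1, axis)


# ---------------------------------------------------------------------------
# Real Clebsch-Gordan tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CGTable:
    """Real coupling table for V_l1 ⊗ V_l2 → V_l3.

    ``coefficients[m1+l1, m2+l2, m3+l3]`` is the real coefficient; the array
    is all-zero when the triangle inequality fails.
    """
    l1: int
    l2: int
    l3: int
    coefficients: np.ndarray

    def coefficient(self, m1: int, m2: int, m3: int) -> float:
        return float(self.coefficients[m1 + self.l1, m2 + self.l2, m3 + self.l3])


_CG_ROT_SEEDS = (12345, 54321, 98765)


def _seeded_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@lru_cache(maxsize=None)
def _cg_array(l1: int, l2: int, l3: int) -> np.ndarray:
    d1, d2, d3 = 2 * l1 + 1, 2 * l2 + 1, 2 * l3 + 1
    if l3 < abs(l1 - l2) or l3 > l1 + l2:
        return np.zeros((d1, d2, d3))
    # Solve the intertwining equation (D1⊗D2) X = X D3 for seeded rotations.
    rows = []
    for seed in _CG_ROT_SEEDS:
        R = _seeded_rotation(seed)
        D1 = wigner_d_real(R, l1)
        D2 = wigner_d_real(R, l2)
        D3 = wigner_d_real(R, l3)
        # constraint on X viewed as matrix (d1*d2, d3):
        # kron(D1, D2) @ X - X @ D3 = 0
        K = np.kron(D1, D2)
        M = np.kron(K, np.eye(d3)) - np.kron(np.eye(d1 * d2), D3.T)
        rows.append(M)
    M = np.vstack(rows)
    _, s, Vt = np.linalg.svd(M)
    null = Vt[-1]
    if s[-1] > 1e-8:
        raise RuntimeError("no intertwiner found (triangle inequality violated?)")
    X = null.reshape(d1, d2, d3)
    # Normalize: total Frobenius norm² = 2l3+1 → Σ_{m1,m2} C² = 1 per m3.
    X = X * math.sqrt(d3) / np.linalg.norm(X)
    # Fix sign: first nonzero in lexicographic (m1, m2, m3) order positive.
    flat = X.reshape(-1)
    first = flat[np.abs(flat) > 1e-10][0]
    if first < 0:
        X = -X
    X[np.abs(X) < 1e-13] = 0.0
    return X


def clebsch_gordan_table(l1: int, l2: int, l3: int) -> CGTable:
    """Real CG table; all-zero if the triangle inequality fails."""
    for l in (l1, l2, l3):
        if not isinstance(l, (int, np.integer)) or l < 0:
            raise ValueError("degrees must be non-negative integers")
    return CGTable(l1, l2, l3, _cg_array(int(l1), int(l2), int(l3)).copy())


# ---------------------------------------------------------------------------
# Coupling schemes for symmetric products A⊗...⊗A → (L, M)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingPath:
    """One coupling path η: factor degrees, intermediates, and output L."""
    nu: int
    ls: tuple[int, ...]          # degrees of the ν factors
    intermediates: tuple[int, ...]  # (l12,) for ν=3, () otherwise
    L: int
    coeffs: np.ndarray           # shape (2l1+1, ..., 2lν+1, 2L+1)


@dataclass(frozen=True)
class CouplingScheme:
    """All coupling paths for ν-fold symmetric products, l ≤ l_max, L ≤ L_max.

    Paths are enumerated deterministically: ν ascending, then lexicographic
    in (l1, ..., lν, intermediates), then L ascending.
    """
    l_max: int
    nu_max: int
    L_max: int
    paths: tuple[CouplingPath, ...]

    def paths_for(self, nu: int, L: int | None = None):
        return [p for p in self.paths
                if p.nu == nu and (L is None or p.L == L)]

    def dump(self) -> str:
        """Plain-text table of all coupling coefficients, for inspection."""
        lines = ["# nu  ls  intermediates  L  (m..,M)  coeff"]
        for p in self.paths:
            nz = np.argwhere(np.abs(p.coeffs) > 1e-13)
            for idx in nz:
                ms = tuple(int(idx[t] - p.ls[t]) for t in range(p.nu))
                M = int(idx[-1] - p.L)
                lines.append(f"{p.nu}  {p.ls}  {p.intermediates}  {p.L}  "
                             f"{ms + (M,)}  {p.coeffs[tuple(idx)]:.12g}")
        return "\n".join(lines)


@lru_cache(maxsize=None)
def build_coupling_scheme(l_max: int, nu: int, L_max: int) -> CouplingScheme:
    """Enumerate all symmetric-product coupling paths for ν ∈ {1, ..., nu}.

    ν=1 paths are identities (B = A), ν=2 pairwise CG tables, ν=3 the
    left-to-right tree ``((l1 l2) l12) l3 → L`` with all intermediates l12
    allowed by the triangle rules.
    """
    if nu not in (1, 2, 3):
        raise ValueError("nu must be in {1, 2, 3} (body order is fixed at ≤ 4)")
    if l_max < 0 or L_max < 0:
        raise ValueError("l_max and L_max must be non-negative")
    paths: list[CouplingPath] = []
    # ν = 1: identity couplings
    for L in range(0, min(l_max, L_max) + 1):
        d = 2 * L + 1
        paths.append(CouplingPath(1, (L,), (), L, np.eye(d)))
    # ν = 2
    if nu >= 2:
        for l1 in range(l_max + 1):
            for l2 in range(l_max + 1):
                for L in range(abs(l1 - l2), min(l1 + l2, L_max) + 1):
                    C = _cg_array(l1, l2, L)
                    paths.append(CouplingPath(2, (l1, l2), (), L, C))
    # ν = 3: tree ((l1 l2) l12) l3 → L
    if nu >= 3:
        for l1 in range(l_max + 1):
            for l2 in range(l_max + 1):
                for l3 in range(l_max + 1):
                    for l12 in range(abs(l1 - l2), l1 + l2 + 1):
                        for L in range(abs(l12 - l3), min(l12 + l3, L_max) + 1):
                            C12 = _cg_array(l1, l2, l12)
                            C123 = _cg_array(l12, l3, L)
                            C = np.einsum("abx,xcM->abcM", C12, C123)
                            paths.append(
                                CouplingPath(3, (l1, l2, l3), (l12,), L, C))
    return CouplingScheme(l_max, nu, L_max, tuple(paths))


def contract_symmetric(A: np.ndarray, scheme: CouplingScheme,
                       nu: int | None = None):
    """Contract features A (..., (l_max+1)²) into the symmetric product basis.

    Returns a list of (path, values) with values shaped (..., 2L+1); if
    ``nu`` is given only that body order is evaluated.
    """
    out = []
    for p in scheme.paths:
        if nu is not None and p.nu != nu:
            continue
        blocks = [A[..., lm_slice(l)] for l in p.ls]
        if p.nu == 1:
            vals = blocks[0].copy()
        elif p.nu == 2:
            vals = np.einsum("abM,...a,...b->...M", p.coeffs, *blocks)
        else:
            vals = np.einsum("abcM,...a,...b,...c->...M", p.coeffs, *blocks)
        out.append((p, vals))
    return out
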