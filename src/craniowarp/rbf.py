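"""Variance-weighted least-squares RBF displacement fields.

The warp engine behind both the surgical model and the shape-size
normalisation.  A vector-valued displacement field

    s(x) = c0 + C x + sum_i lambda_i phi(|x - x_i|)

is fitted per component to change vectors f_i at centres x_i by solving the
symmetric augmented system

    [ A + alpha * diag(sigma^2)   P ] [ lambda ]   [ f ]
    [ P^T                         0 ] [ c      ] = [ 0 ]

with A_ij = phi(|x_i - x_j|), P = [1 x y z] at the centres, and sigma_i^2
the per-centre variance.  The diagonal augmentation is classic
heteroscedastic spline smoothing: a zero-variance centre is interpolated
exactly for any alpha, while high-variance centres trade fidelity for
smoothness.  The affine term lives in the null space of the penalty, so any
affine displacement field (translations in particular) is reproduced
exactly regardless of smoothing.

The default basis phi(r) = r is the 3D biharmonic spline — the minimiser of
the thin-plate bending energy among interpolants, i.e. the "least wiggly"
field through the data; phi(r) = r^3 (triharmonic) is selectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist

from .errors import InputError, NumericalError
from .geometry import SurfaceMesh, _as_points

BASES = ("biharmonic_r", "triharmonic_r3")

#: centres closer than this (mm) are considered duplicates and rejected
DUPLICATE_TOL = 1e-6


def _phi(r: np.ndarray, basis_id: str) -> np.ndarray:
    if basis_id == "biharmonic_r":
        return r
    if basis_id == "triharmonic_r3":
        return r**3
    raise InputError(f"unknown basis {basis_id!r}; expected one of {BASES}")


@dataclass(frozen=True)
class WeightedSamples:
    """Scattered displacement samples with per-centre variances (mm^2)."""

    centres: np.ndarray
    target_vectors: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        c = _as_points(self.centres)
        t = _as_points(self.target_vectors)
        v = np.asarray(self.variances, dtype=float)
        if len(c) != len(t) or v.shape != (len(c),):
            raise InputError("centres, target_vectors and variances must have equal length")
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise InputError("non-finite sample data")
        if np.any(v < 0):
            raise InputError("variances must be non-negative")
        object.__setattr__(self, "centres", c)
        object.__setattr__(self, "target_vectors", t)
        object.__setattr__(self, "variances", v)

    def __len__(self) -> int:
        return len(self.centres)


@dataclass(frozen=True)
class RBFWarp:
    """A fitted vector-valued RBF displacement field."""

    centres: np.ndarray
    coefficients: np.ndarray  # (N, 3) per-centre weights
    affine: np.ndarray  # (3, 4): row k = [c0_k, Cx_k, Cy_k, Cz_k]
    basis_id: str
    smoothing_alpha: float
    centre_variances: np.ndarray

    def displacement(self, points) -> np.ndarray:
        """Evaluate the displacement s(x) at one point or an (M, 3) stack."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = _as_points(pts)
        if not np.all(np.isfinite(pts)):
            raise InputError("non-finite evaluation point")
        K = _phi(cdist(pts, self.centres), self.basis_id)
        out = K @ self.coefficients
        out += self.affine[:, 0] + pts @ self.affine[:, 1:].T
        return out[0] if single else out

    def __call__(self, points) -> np.ndarray:
        """Evaluate the warped positions x + s(x)."""
        pts = np.asarray(points, dtype=float)
        return pts + self.displacement(pts)

    def side_condition_residual(self) -> float:
        """Max violation of sum(lambda) = 0 and sum(lambda x^T) = 0."""
        P = _poly_matrix(self.centres)
        return float(np.abs(P.T @ self.coefficients).max())

    def to_dict(self) -> dict:
        return {
            "basis_id": self.basis_id,
            "alpha": self.smoothing_alpha,
            "centres": self.centres.tolist(),
            "variances": self.centre_variances.tolist(),
            "coefficients": self.coefficients.tolist(),
            "affine": self.affine.tolist(),
        }

    @staticmethod
    def from_dict(d: dict) -> "RBFWarp":
        return RBFWarp(
            centres=np.asarray(d["centres"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            affine=np.asarray(d["affine"], dtype=float),
            basis_id=d["basis_id"],
            smoothing_alpha=float(d["alpha"]),
            centre_variances=np.asarray(d["variances"], dtype=float),
        )

    def to_json(self) -> str:
        # repr-based float serialisation: bit-exact round trip for finite doubles
        return json.dumps(self.to_dict())

    @staticmethod
    def from_json(text: str) -> "RBFWarp":
        return RBFWarp.from_dict(json.loads(text))


def zero_warp(basis_id: str = "biharmonic_r") -> RBFWarp:
    """The identity field (no centres, zero affine)."""
    return RBFWarp(
        centres=np.zeros((0, 3)),
        coefficients=np.zeros((0, 3)),
        affine=np.zeros((3, 4)),
        basis_id=basis_id,
        smoothing_alpha=0.0,
        centre_variances=np.zeros(0),
    )


def _poly_matrix(centres: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((len(centres), 1)), centres])


def _check_centres(centres: np.ndarray) -> None:
    n = len(centres)
    if n < 4:
        raise InputError(f"need at least 4 centres for the affine term, got {n}")
    d = cdist(centres, centres)
    np.fill_diagonal(d, np.inf)
    if d.min() < DUPLICATE_TOL:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise InputError(
            f"duplicate centres {i} and {j} (distance {d.min():.2e} mm < {DUPLICATE_TOL})"
        )
    centred = centres - centres.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[2] <= 1e-9 * max(sv[0], 1.0):
        raise NumericalError(
            "centres are coplanar or collinear: the affine part is not identifiable"
        )


def fit_weighted_rbf(
    samples: WeightedSamples,
    basis_id: str = "biharmonic_r",
    smoothing_alpha: float = 1.0,
) -> RBFWarp:
    """Fit the weighted least-squares RBF field to displacement samples.

    With ``smoothing_alpha * variances == 0`` everywhere the fitted field
    interpolates the target vectors exactly at the centres; positive
    ``alpha * sigma_i^2`` relaxes fidelity at centre i in favour of
    smoothness.  The residual at centre i is ``-alpha sigma_i^2 lambda_i``.
    """
    if basis_id not in BASES:
        raise InputError(f"unknown basis {basis_id!r}; expected one of {BASES}")
    if smoothing_alpha < 0:
        raise InputError("smoothing_alpha must be non-negative")
    centres = samples.centres
    _check_centres(centres)
    n = len(centres)

    A = _phi(cdist(centres, centres), basis_id)
    A = A + smoothing_alpha * np.diag(samples.variances)
    P = _poly_matrix(centres)
    K = np.zeros((n + 4, n + 4))
    K[:n, :n] = A
    K[:n, n:] = P
    K[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = samples.target_vectors

    # symmetric equilibration: removes the artificial block-scale mismatch
    # between phi(r) entries (mm or mm^3) and the unit polynomial column
    d = 1.0 / np.sqrt(np.maximum(np.abs(K).max(axis=1), 1e-30))
    Keq = K * d[:, None] * d[None, :]
    cond = np.linalg.cond(Keq)
    if not np.isfinite(cond) or cond > 1e13:
        raise NumericalError(
            f"singular or near-singular RBF system (condition number {cond:.3e})"
        )
    sol = d[:, None] * solve(Keq, rhs * d[:, None], assume_a="sym")
    return RBFWarp(
        centres=centres.copy(),
        coefficients=sol[:n],
        affine=sol[n:].T,
        basis_id=basis_id,
        smoothing_alpha=float(smoothing_alpha),
        centre_variances=samples.variances.copy(),
    )


def evaluate_warp(warp: RBFWarp, points) -> np.ndarray:
    """Warped positions x + s(x) for one point or a stack of points."""
    return warp(points)


def warp_mesh(warp: RBFWarp, mesh: SurfaceMesh, stage: str | None = None) -> SurfaceMesh:
    """Transport every vertex through the warp; faces are unchanged."""
    return mesh.with_vertices(warp(mesh.vertices), stage=stage)


def warp_residuals(warp: RBFWarp, samples: WeightedSamples) -> np.ndarray:
    """Per-centre residual vectors s(x_i) - f_i (mm)."""
    return warp.displacement(samples.centres) - samples.target_vectors
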