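"""Three-compartment restriction spectrum imaging (RSI) model.

The diffusion-weighted signal in each voxel is modelled as a linear mixture of
three water pools:

* a **restricted** pool (intracellular; axially symmetric tensor with axial
  diffusivity 1e-3 mm^2/s and radial diffusivity 0), whose orientation
  structure is expanded in even-order real spherical harmonics up to l = 4;
* a **hindered** pool (extracellular; axial 1e-3, radial 0.9e-3 mm^2/s), same
  angular expansion;
* a **free** pool (CSF-like; isotropic, 3e-3 mm^2/s), order l = 0 only.

Because each compartment kernel is axially symmetric, the forward model is a
spherical convolution and therefore *linear* in the spherical-harmonic
coefficients of the per-compartment orientation distributions.  Fitting is a
single Tikhonov-regularised least-squares solve per voxel (spherical
deconvolution), and the normalised signal-fraction metrics (RNI, RND, RNT,
HNT, ...) are ratios of coefficient norms.

Spherical-harmonic convention
-----------------------------
Real, even-order, symmetric basis ("modified real" convention used throughout
diffusion MRI).  Columns are ordered by degree l ascending, and within a
degree by order m ascending (m = -l ... l):

    m < 0 : sqrt(2) * (-1)^m * Im(Y_l^|m|)
    m = 0 : Y_l^0
    m > 0 : sqrt(2) * (-1)^m * Re(Y_l^m)

With this convention the basis is orthonormal on the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "AcquisitionScheme",
    "CompartmentModel",
    "RSICoefficients",
    "RSIMetrics",
    "build_sh_basis",
    "compartment_response",
    "build_design_matrix",
    "fit_voxel",
    "compute_metrics",
    "fit_volume",
    "n_sh_coeffs",
    "METRIC_NAMES",
]

METRIC_NAMES = ("rni", "rnd", "rnt", "hni", "hnd", "hnt", "fni")

# quadrature order for the rotational responses; exact to machine precision
# for the smooth kernels exp(-b*D*u^2) with b*D <= 9 used here
_QUAD_NODES = 64


def n_sh_coeffs(lmax: int) -> int:
    """Number of even-order real SH coefficients up to degree ``lmax``."""
    return (lmax + 1) * (lmax + 2) // 2


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell diffusion acquisition: b-values and unit gradient directions.

    Parameters
    ----------
    bvals : (n,) array
        Diffusion weightings in s/mm^2, >= 0.
    bvecs : (n, 3) array
        Unit gradient directions; arbitrary (typically zero) for b = 0 rows.
    shell_index : (n,) int array, optional
        Shell label per volume.  Derived from unique b-values if omitted.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError("bvecs must have shape (n, 3)")
        if len(bvals) != len(bvecs):
            raise ValueError(
                f"bvals ({len(bvals)}) and bvecs ({len(bvecs)}) lengths differ"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be nonnegative")
        norms = np.linalg.norm(bvecs, axis=1)
        bad = (bvals > 0) & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            raise ValueError(
                f"{bad.sum()} gradient direction(s) with b > 0 are not unit norm"
            )
        if self.shell_index is None:
            shells = np.unique(bvals)
            idx = np.searchsorted(shells, bvals)
        else:
            idx = np.asarray(self.shell_index, dtype=int).ravel()
            if len(idx) != len(bvals):
                raise ValueError("shell_index length mismatch")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "shell_index", idx)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())


@dataclass(frozen=True)
class CompartmentModel:
    """Fixed-diffusivity three-compartment model (diffusivities in mm^2/s)."""

    restricted_axial_diffusivity: float = 1e-3
    restricted_radial_diffusivity: float = 0.0
    hindered_axial_diffusivity: float = 1e-3
    hindered_radial_diffusivity: float = 0.9e-3
    free_diffusivity: float = 3e-3
    lmax_restricted: int = 4
    lmax_hindered: int = 4
    lmax_free: int = 0

    def __post_init__(self):
        for name in (
            "restricted_axial_diffusivity",
            "restricted_radial_diffusivity",
            "hindered_axial_diffusivity",
            "hindered_radial_diffusivity",
            "free_diffusivity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("lmax_restricted", "lmax_hindered", "lmax_free"):
            l = getattr(self, name)
            if l < 0 or l % 2:
                raise ValueError(f"{name} must be an even integer >= 0")
        if self.lmax_free != 0:
            raise ValueError("the free compartment is isotropic (lmax_free == 0)")

    def diffusivities(self, compartment: str) -> tuple[float, float]:
        if compartment == "restricted":
            return (
                self.restricted_axial_diffusivity,
                self.restricted_radial_diffusivity,
            )
        if compartment == "hindered":
            return (
                self.hindered_axial_diffusivity,
                self.hindered_radial_diffusivity,
            )
        raise ValueError(f"unknown compartment {compartment!r}")

    def lmax(self, compartment: str) -> int:
        return {
            "restricted": self.lmax_restricted,
            "hindered": self.lmax_hindered,
            "free": self.lmax_free,
        }[compartment]


@dataclass
class RSICoefficients:
    """Fitted SH coefficients, partitioned by compartment.

    ``restricted`` and ``hindered`` are length-15 vectors ordered
    (l=0; l=2, m=-2..2; l=4, m=-4..4); ``free`` is the single l=0 scalar.
    """

    restricted: np.ndarray
    hindered: np.ndarray
    free: float
    fit_residual_norm: float = 0.0
    valid: bool = True

    def __post_init__(self):
        self.restricted = np.asarray(self.restricted, dtype=float).ravel()
        self.hindered = np.asarray(self.hindered, dtype=float).ravel()
        if len(self.restricted) != len(self.hindered):
            raise ValueError("restricted and hindered blocks must match in length")

    @property
    def full_vector(self) -> np.ndarray:
        return np.concatenate([self.restricted, self.hindered, [self.free]])

    @classmethod
    def invalid(cls, n_aniso: int = 15) -> "RSICoefficients":
        return cls(
            restricted=np.zeros(n_aniso),
            hindered=np.zeros(n_aniso),
            free=0.0,
            fit_residual_norm=np.nan,
            valid=False,
        )


@dataclass
class RSIMetrics:
    """Normalised signal fractions derived from fitted coefficients."""

    rni: float
    rnd: float
    rnt: float
    hni: float
    hnd: float
    hnt: float
    fni: float
    norm_mode: str = "sum"
    valid: bool = True

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def build_sh_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Evaluate the real even-order SH basis at unit ``directions``.

    Returns an ``(n_dirs, n_sh_coeffs(lmax))`` matrix; 1 column for lmax=0,
    6 for lmax=2, 15 for lmax=4.
    """
    if lmax < 0 or lmax % 2:
        raise ValueError(f"lmax must be an even integer >= 0, got {lmax}")
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    if dirs.shape[1] != 3:
        raise ValueError("directions must have shape (n, 3)")
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm direction encountered")
    dirs = dirs / norms[:, None]

    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar angle
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])

    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                col = np.sqrt(2.0) * (-1.0) ** m * y.imag
            elif m == 0:
                col = y.real
            else:
                col = np.sqrt(2.0) * (-1.0) ** m * y.real
            cols.append(col)
    return np.stack(cols, axis=1)


def compartment_response(
    bval: float,
    model: CompartmentModel,
    compartment: str,
    l: int,
) -> float:
    """Rotational harmonic response of one compartment at degree ``l``.

    For the axially symmetric restricted/hindered kernels
    ``S(u) = exp(-b (D_rad + (D_ax - D_rad) u^2))`` (u = cosine to the fiber
    axis) the degree-l response is the Legendre projection

        r_l(b) = 1/2 * Integral_{-1}^{1} S(u) P_l(u) du,

    evaluated by 64-node Gauss-Legendre quadrature; r_0 is the spherical mean
    and equals 1 at b = 0.  The free compartment is isotropic:
    ``exp(-b D_free)`` at l = 0, undefined for l > 0.
    """
    if bval < 0:
        raise ValueError("b-value must be nonnegative")
    if l < 0 or l % 2:
        raise ValueError(f"degree l must be even and >= 0, got {l}")
    if l > model.lmax(compartment):
        raise ValueError(
            f"l={l} exceeds lmax={model.lmax(compartment)} for {compartment!r}"
        )
    if compartment == "free":
        return float(np.exp(-bval * model.free_diffusivity))
    if bval == 0:
        return 1.0 if l == 0 else 0.0  # exact: P_l integrates to 2*delta_l0
    d_ax, d_rad = model.diffusivities(compartment)
    u, w = leggauss(_QUAD_NODES)
    s = np.exp(-bval * (d_rad + (d_ax - d_rad) * u**2))
    return float(0.5 * np.sum(w * s * eval_legendre(l, u)))


def _degree_of_column(lmax: int) -> np.ndarray:
    """Degree l of each column of the even-order basis up to ``lmax``."""
    return np.concatenate(
        [np.full(2 * l + 1, l, dtype=int) for l in range(0, lmax + 1, 2)]
    )


def build_design_matrix(
    scheme: AcquisitionScheme, model: CompartmentModel
) -> np.ndarray:
    """Forward-model matrix mapping SH coefficients to measured signals.

    Columns: restricted block (15 for lmax=4), hindered block (15), free (1).
    Entry (i, j) = r_l(b_i) * Y_lm(g_i) for the compartment/degree of column
    j.  For b = 0 rows the l > 0 responses vanish exactly, so the gradient
    direction (often recorded as the zero vector) is irrelevant there; a
    placeholder axis is substituted before basis evaluation.
    """
    bvecs = scheme.bvecs.copy()
    zero = np.linalg.norm(bvecs, axis=1) < 1e-12
    bvecs[zero] = [0.0, 0.0, 1.0]

    blocks = []
    for comp in ("restricted", "hindered"):
        lmax = model.lmax(comp)
        basis = build_sh_basis(bvecs, lmax)
        degrees = _degree_of_column(lmax)
        resp = np.empty((len(scheme), len(degrees)))
        for shell in np.unique(scheme.bvals):
            rows = scheme.bvals == shell
            r_by_l = {
                l: compartment_response(shell, model, comp, l)
                for l in range(0, lmax + 1, 2)
            }
            resp[rows] = [r_by_l[l] for l in degrees]
        blocks.append(basis * resp)

    y00 = build_sh_basis(np.array([[0.0, 0.0, 1.0]]), 0)[0, 0]
    free_col = np.exp(-scheme.bvals * model.free_diffusivity)[:, None] * y00
    blocks.append(free_col)
    return np.hstack(blocks)


def _svd_solver(design: np.ndarray, ridge_lambda: float):
    """Precompute a Tikhonov solver for repeated right-hand sides.

    The design is column-equilibrated (each column scaled to unit norm)
    before the SVD; the ridge, ``ridge_lambda`` relative to the largest
    singular value, acts in the equilibrated basis.  Equilibration matters:
    the raw design mixes columns whose norms span four orders of magnitude
    (the near-isotropic hindered kernel barely excites l = 4), and without
    it the relative ridge visibly biases the small-response coefficients.
    """
    scale = np.linalg.norm(design, axis=0)
    scale[scale == 0] = 1.0
    u, s, vt = np.linalg.svd(design / scale, full_matrices=False)
    lam = ridge_lambda * s[0]
    filt = s / (s**2 + lam**2)

    def solve(signal: np.ndarray) -> np.ndarray:
        return (vt.T @ (filt * (u.T @ signal))) / scale

    return solve


def fit_voxel(
    signal: np.ndarray,
    design: np.ndarray,
    ridge_lambda: float = 1e-6,
    b0_mask: np.ndarray | None = None,
    n_aniso: int = 15,
    nonneg_isotropic: bool = False,
    _solver=None,
) -> RSICoefficients:
    """Spherical deconvolution of one voxel's signal.

    Solves ``min ||A c - s||^2 + (lam * sigma_max)^2 ||c||^2`` by SVD, where
    ``lam`` is ``ridge_lambda`` relative to the largest singular value, then
    partitions ``c`` into restricted / hindered / free blocks.  Voxels with
    non-finite signal, or nonpositive mean b0 signal (mean over ``b0_mask``
    rows when given, else over all rows), are flagged invalid with all-zero
    coefficients rather than raising.

    ``nonneg_isotropic=True`` additionally constrains the three isotropic
    (l = 0) coefficients to be nonnegative (bound-constrained solve; slower,
    and only engaged when the unconstrained solution violates the bounds).
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if len(signal) != design.shape[0]:
        raise ValueError(
            f"signal length {len(signal)} != design rows {design.shape[0]}"
        )
    if design.shape[1] != 2 * n_aniso + 1:
        raise ValueError("design column count inconsistent with n_aniso")

    ref = signal[b0_mask] if b0_mask is not None else signal
    if not np.all(np.isfinite(signal)) or len(ref) == 0 or np.mean(ref) <= 0:
        return RSICoefficients.invalid(n_aniso)

    solve = _solver if _solver is not None else _svd_solver(design, ridge_lambda)
    coeffs = solve(signal)
    iso = [0, n_aniso, 2 * n_aniso]
    if nonneg_isotropic and np.any(coeffs[iso] < 0):
        from scipy.optimize import lsq_linear

        lower = np.full(design.shape[1], -np.inf)
        lower[iso] = 0.0
        coeffs = lsq_linear(design, signal, bounds=(lower, np.inf)).x
    resid = float(np.linalg.norm(design @ coeffs - signal))
    return RSICoefficients(
        restricted=coeffs[:n_aniso],
        hindered=coeffs[n_aniso : 2 * n_aniso],
        free=float(coeffs[-1]),
        fit_residual_norm=resid,
        valid=True,
    )


def compute_metrics(coeffs: RSICoefficients, norm_mode: str = "sum") -> RSIMetrics:
    """Normalised signal fractions from fitted coefficients.

    The denominator is the Euclidean norm of the full coefficient vector.
    RNI is the isotropic (l = 0, spherical-mean) restricted fraction, RND the
    directional (l = 2, 4) restricted fraction; HNI/HND analogously for the
    hindered pool, FNI for free water.  Totals combine the two parts either
    additively (``sum``, the default: RNT = RNI + RND) or in quadrature
    (``euclidean``: RNT = sqrt(RNI^2 + RND^2)).  Outputs are clipped to
    [0, 1]; a zero or invalid coefficient vector yields invalid zero metrics.
    """
    if norm_mode not in ("sum", "euclidean"):
        raise ValueError(f"norm_mode must be 'sum' or 'euclidean', got {norm_mode!r}")
    n = float(np.linalg.norm(coeffs.full_vector))
    if not coeffs.valid or n == 0.0 or not np.isfinite(n):
        return RSIMetrics(0, 0, 0, 0, 0, 0, 0, norm_mode=norm_mode, valid=False)

    def clip(x: float) -> float:
        return float(np.clip(x, 0.0, 1.0))

    rni = clip(abs(coeffs.restricted[0]) / n)
    rnd = clip(np.linalg.norm(coeffs.restricted[1:]) / n)
    hni = clip(abs(coeffs.hindered[0]) / n)
    hnd = clip(np.linalg.norm(coeffs.hindered[1:]) / n)
    fni = clip(abs(coeffs.free) / n)
    if norm_mode == "sum":
        rnt, hnt = clip(rni + rnd), clip(hni + hnd)
    else:
        rnt = clip(np.hypot(rni, rnd))
        hnt = clip(np.hypot(hni, hnd))
    return RSIMetrics(rni, rnd, rnt, hni, hnd, hnt, fni, norm_mode=norm_mode)


def fit_volume(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    model: CompartmentModel | None = None,
    mask: np.ndarray | None = None,
    norm_mode: str = "sum",
    ridge_lambda: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Fit the RSI model voxelwise and return one 3D map per metric.

    Voxels outside ``mask`` and invalid fits are NaN.  Deterministic given
    its inputs (the design matrix and its SVD are computed once).
    """
    model = model or CompartmentModel()
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be a 4D array (x, y, z, volume)")
    if dwi.shape[3] != len(scheme):
        raise ValueError(
            f"dwi has {dwi.shape[3]} volumes but scheme has {len(scheme)}"
        )
    spatial = dwi.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError(f"mask shape {mask.shape} != volume shape {spatial}")

    design = build_design_matrix(scheme, model)
    solver = _svd_solver(design, ridge_lambda)
    n_aniso = n_sh_coeffs(model.lmax_restricted)
    b0 = scheme.b0_mask

    maps = {name: np.full(spatial, np.nan, dtype=np.float32) for name in METRIC_NAMES}
    for ijk in np.argwhere(mask):
        i, j, k = ijk
        coeffs = fit_voxel(
            dwi[i, j, k], design, ridge_lambda, b0_mask=b0,
            n_aniso=n_aniso, _solver=solver,
        )
        metrics = compute_metrics(coeffs, norm_mode=norm_mode)
        if metrics.valid:
            for name in METRIC_NAMES:
                maps[name][i, j, k] = getattr(metrics, name)
    return maps
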