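"""Synthetic-data generators.

Two generators stand in for data the study design assumes but which cannot be
shipped with the package:

* multi-shell diffusion MRI signals from voxels with known compartment
  fractions, on the study's acquisition protocol (b = 0/500/1000/2000/3000
  s/mm^2 with 6/6/15/15/60 directions), optionally corrupted with Rician
  noise; and
* a cohort table with the statistical structure the ROI regression analysis
  assumes: two diagnostic groups (ADHD n=81, TD n=78) with near-identical
  anthropometric distributions, covariates, standardized brain-metric
  outcomes carrying a configurable BMI slope, and missing-at-random gaps in
  waist circumference (13.8%) and percent body fat (12.6%).

Gradient directions use a seeded Fibonacci-sphere layout per shell (the
study's own direction tables are not published); the layout is deterministic
per seed, which keeps regression fixtures stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .rsi_core import AcquisitionScheme, CompartmentModel, build_design_matrix

__all__ = [
    "VoxelGroundTruth",
    "CohortSpec",
    "fibonacci_sphere",
    "make_study_scheme",
    "simulate_signal",
    "simulate_truth_signal_sh",
    "simulate_cohort",
]

# study acquisition: (b-value s/mm^2, n directions)
SHELLS = ((0, 6), (500, 6), (1000, 15), (2000, 15), (3000, 60))


@dataclass(frozen=True)
class VoxelGroundTruth:
    """Known compartment composition of one synthetic voxel.

    Fractions are signal weights at b = 0 (nonnegative, typically summing to
    1).  ``dispersion`` spreads the restricted/hindered orientation around
    ``fiber_direction`` with a Watson-style distribution; 0 means an ideal
    stick (no dispersion), larger values mean broader spread (the Watson
    concentration is 1/dispersion).
    """

    restricted_fraction: float
    hindered_fraction: float
    free_fraction: float
    fiber_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    dispersion: float = 0.0

    def __post_init__(self):
        for name in ("restricted_fraction", "hindered_fraction", "free_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        mu = np.asarray(self.fiber_direction, dtype=float)
        n = np.linalg.norm(mu)
        if n < 1e-12:
            raise ValueError("fiber_direction must be nonzero")
        object.__setattr__(self, "fiber_direction", tuple(mu / n))


def fibonacci_sphere(n: int, seed: int = 0) -> np.ndarray:
    """``n`` near-uniform unit vectors from a golden-angle spiral.

    A seeded random rotation is applied to the whole set so different seeds
    give different (but internally near-uniform) layouts.
    """
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)

    rng = np.random.default_rng(seed)
    # random rotation via QR of a Gaussian matrix
    q, rr = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(rr))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return pts @ q.T


def make_study_scheme(seed: int = 0) -> AcquisitionScheme:
    """The study's 108-volume multi-shell protocol.

    6 b=0 volumes plus 6/15/15/60 directions at b = 500/1000/2000/3000
    s/mm^2; per-shell Fibonacci-sphere directions, deterministic per seed.
    """
    bvals, bvecs, shell_idx = [], [], []
    for k, (b, ndirs) in enumerate(SHELLS):
        bvals.extend([float(b)] * ndirs)
        shell_idx.extend([k] * ndirs)
        if b == 0:
            bvecs.append(np.zeros((ndirs, 3)))
        else:
            bvecs.append(fibonacci_sphere(ndirs, seed=seed * len(SHELLS) + k))
    return AcquisitionScheme(
        bvals=np.array(bvals),
        bvecs=np.vstack(bvecs),
        shell_index=np.array(shell_idx),
    )


def _tensor_signal(
    bvals: np.ndarray, bvecs: np.ndarray, mu: np.ndarray, d_ax: float, d_rad: float
) -> np.ndarray:
    cos2 = (bvecs @ mu) ** 2
    return np.exp(-bvals * (d_rad + (d_ax - d_rad) * cos2))


def _watson_axes(mu: np.ndarray, dispersion: float, n: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature axes and normalised weights for a Watson distribution.

    Density on the sphere proportional to exp(kappa (mu.u)^2) with
    kappa = 1/dispersion, discretised on a Fibonacci grid.
    """
    axes = fibonacci_sphere(n, seed=0)
    kappa = 1.0 / dispersion
    w = np.exp(kappa * ((axes @ mu) ** 2 - 1.0))  # shifted for stability
    return axes, w / w.sum()


def simulate_signal(
    truth: VoxelGroundTruth,
    scheme: AcquisitionScheme,
    model: CompartmentModel | None = None,
    snr: float = np.inf,
    seed: int | None = None,
    s0: float = 1.0,
    bandlimit: bool = False,
) -> np.ndarray:
    """Clean or Rician-noised DWI signal for one voxel.

    The clean signal is the fraction-weighted sum of the restricted and
    hindered axially symmetric tensor signals (around ``fiber_direction``,
    Watson-averaged when ``dispersion > 0``) and the isotropic free signal.
    Rician noise is applied as sqrt((S + e1)^2 + e2^2) with independent
    Gaussian e ~ N(0, sigma^2), sigma = S(b=0) / snr.

    With ``bandlimit=True`` the anisotropic compartments emit only their
    even-spherical-harmonic content up to the model's lmax (the part of an
    ideal stick the deconvolution model can represent); the default emits
    the full tensor signal, which carries an l > lmax remainder.
    """
    model = model or CompartmentModel()
    if not (snr > 0):
        raise ValueError("snr must be positive (np.inf for noiseless)")
    mu = np.asarray(truth.fiber_direction)
    b, g = scheme.bvals, scheme.bvecs

    def one_axis(axis, d_ax, d_rad, comp):
        if not bandlimit:
            return _tensor_signal(b, g, axis, d_ax, d_rad)
        # Funk-Hecke: tensor kernel = sum_l r_l(b) * 4pi Y_lm(axis) Y_lm(g)
        from .rsi_core import build_sh_basis, compartment_response, _degree_of_column

        lmax = model.lmax(comp)
        gq = g.copy()
        gq[np.linalg.norm(gq, axis=1) < 1e-12] = [0.0, 0.0, 1.0]
        basis_g = build_sh_basis(gq, lmax)
        basis_mu = build_sh_basis(axis[None, :], lmax)[0]
        degrees = _degree_of_column(lmax)
        out = np.zeros(len(b))
        for shell in np.unique(b):
            rows = b == shell
            resp = np.array(
                [compartment_response(shell, model, comp, int(l)) for l in degrees]
            )
            out[rows] = basis_g[rows] @ (4 * np.pi * resp * basis_mu)
        return out

    def aniso(d_ax: float, d_rad: float, comp: str) -> np.ndarray:
        if truth.dispersion == 0:
            return one_axis(mu, d_ax, d_rad, comp)
        axes, w = _watson_axes(mu, truth.dispersion)
        sig = np.zeros(len(b))
        for ax, wi in zip(axes, w):
            sig += wi * one_axis(ax, d_ax, d_rad, comp)
        return sig

    signal = truth.free_fraction * np.exp(-b * model.free_diffusivity)
    signal += truth.restricted_fraction * aniso(
        model.restricted_axial_diffusivity,
        model.restricted_radial_diffusivity,
        "restricted",
    )
    signal += truth.hindered_fraction * aniso(
        model.hindered_axial_diffusivity,
        model.hindered_radial_diffusivity,
        "hindered",
    )
    signal *= s0

    if np.isfinite(snr):
        s_b0 = s0 * (
            truth.free_fraction + truth.restricted_fraction + truth.hindered_fraction
        )
        sigma = s_b0 / snr
        rng = np.random.default_rng(seed)
        e1, e2 = rng.normal(0, sigma, (2, len(b)))
        signal = np.sqrt((signal + e1) ** 2 + e2**2)
    return signal


def simulate_truth_signal_sh(
    coeffs: np.ndarray,
    scheme: AcquisitionScheme,
    model: CompartmentModel | None = None,
) -> np.ndarray:
    """Noiseless signal synthesised directly from the linear forward model.

    ``coeffs`` is the full 31-vector (restricted 15, hindered 15, free 1).
    Signals built this way lie exactly in the model class, so deconvolution
    recovers the coefficients to solver precision (unlike the tensor route,
    which carries an l > lmax truncation remainder).
    """
    model = model or CompartmentModel()
    design = build_design_matrix(scheme, model)
    coeffs = np.asarray(coeffs, dtype=float).ravel()
    if len(coeffs) != design.shape[1]:
        raise ValueError("coefficient vector length mismatch")
    return design @ coeffs


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: group sizes 81 (ADHD) / 78 (TD),
    anthropometric means and SDs per group, a standardized brain-on-BMI slope
    of 0.22 (the magnitude of the strongest observed associations), and
    missing-at-random rates of 13.8% (waist) / 12.6% (percent body fat).
    ``effect_columns`` limits the BMI effect to selected metric_roi columns
    (None applies it to all generated outcome columns).
    """

    n_adhd: int = 81
    n_td: int = 78
    bmi_mean: tuple[float, float] = (16.68, 16.48)       # (ADHD, TD)
    bmi_sd: tuple[float, float] = (2.39, 2.27)
    bodyfat_mean: tuple[float, float] = (23.04, 22.31)
    bodyfat_sd: tuple[float, float] = (8.11, 6.77)
    waist_mean: tuple[float, float] = (57.93, 57.34)
    waist_sd: tuple[float, float] = (7.94, 5.69)
    anthro_corr: float = 0.6     # latent correlation between the 3 measures
    brain_effect_beta: float = 0.22
    interaction_beta: float = 0.0
    covariate_effects: tuple[float, float, float, float] = (0.10, 0.05, -0.05, -0.10)
    missing_rate_waist: float = 0.138
    missing_rate_bodyfat: float = 0.126
    obesity_cutoff_percentile: float = 85.0
    metrics: tuple[str, ...] = ("rni",)
    rois: tuple[str, ...] = ("nacc",)
    effect_columns: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_adhd <= 0 or self.n_td <= 0:
            raise ValueError("group sizes must be positive")
        for r in (self.missing_rate_waist, self.missing_rate_bodyfat):
            if not (0 <= r < 1):
                raise ValueError("missing rates must be in [0, 1)")


def _calibrated_intercept(eta: np.ndarray, rate: float) -> float:
    """Intercept a such that mean(sigmoid(a + eta)) == rate."""
    if rate == 0:
        return -np.inf
    return brentq(lambda a: expit(a + eta).mean() - rate, -30, 30)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one synthetic cohort table; fully reproducible per ``spec.seed``.

    Columns: subject_id, group (1=ADHD, 0=TD), age, sex, parent_education,
    movement, bmi, body_fat, waist, obesity, and one standardized outcome
    column per ``<metric>_<roi>`` pair.  Outcomes are built as
    beta * z(BMI) + covariate effects + Gaussian noise with total variance 1.
    Waist and body-fat values are deleted MAR with probability logistic in
    group and age, calibrated so the expected rates match the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_adhd + spec.n_td
    group = np.concatenate([np.ones(spec.n_adhd, int), np.zeros(spec.n_td, int)])

    # anthropometrics: correlated latent z-scores scaled per group
    corr = np.full((3, 3), spec.anthro_corr) + (1 - spec.anthro_corr) * np.eye(3)
    z = rng.multivariate_normal(np.zeros(3), corr, size=n)
    g = 1 - group  # index 0 = ADHD, 1 = TD
    bmi = np.array(spec.bmi_mean)[g] + np.array(spec.bmi_sd)[g] * z[:, 0]
    bodyfat = np.array(spec.bodyfat_mean)[g] + np.array(spec.bodyfat_sd)[g] * z[:, 1]
    waist = np.array(spec.waist_mean)[g] + np.array(spec.waist_sd)[g] * z[:, 2]
    bodyfat = np.clip(bodyfat, 1.0, None)

    age = rng.uniform(4.0, 7.0, n)
    sex = rng.binomial(1, 0.65, n)
    parent_education = rng.choice([1, 2, 3, 4], size=n, p=[0.1, 0.25, 0.35, 0.3])
    movement = rng.lognormal(mean=np.log(0.5), sigma=0.5, size=n)

    def zscore(x):
        return (x - x.mean()) / x.std(ddof=0)

    covs = np.column_stack(
        [zscore(age), sex - sex.mean(), zscore(parent_education), zscore(movement)]
    )
    cov_eff = np.asarray(spec.covariate_effects, dtype=float)

    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
            "parent_education": parent_education,
            "movement": movement,
            "bmi": bmi,
            "body_fat": bodyfat,
            "waist": waist,
        }
    )
    df["obesity"] = (
        bmi >= np.percentile(bmi, spec.obesity_cutoff_percentile)
    ).astype(int)

    zbmi = zscore(bmi)
    linear_base = covs @ cov_eff
    for metric in spec.metrics:
        for roi in spec.rois:
            col = f"{metric}_{roi}"
            beta = spec.brain_effect_beta
            if spec.effect_columns is not None and col not in spec.effect_columns:
                beta = 0.0
            lin = beta * zbmi + spec.interaction_beta * zbmi * group + linear_base
            noise_var = max(1.0 - beta**2 - spec.interaction_beta**2
                            - float(cov_eff @ cov_eff), 0.05)
            df[col] = lin + rng.normal(0, np.sqrt(noise_var), n)

    # MAR deletion: logistic in group and standardized age
    eta = 0.5 * group + 0.5 * zscore(age)
    for colname, rate in (
        ("waist", spec.missing_rate_waist),
        ("body_fat", spec.missing_rate_bodyfat),
    ):
        if rate > 0:
            a = _calibrated_intercept(eta, rate)
            miss = rng.random(n) < expit(a + eta)
            df.loc[miss, colname] = np.nan
    return df


def replicate_spec(spec: CohortSpec, seed: int) -> CohortSpec:
    """A copy of ``spec`` with a new seed (for replicate studies)."""
    return replace(spec, seed=seed)
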