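"""Analytic small-angle scattering models and profile fitting.

Two form factors cover the morphologies of interest: an orientationally
averaged core-shell cylinder (fibrils; low-q intensity ~ q^-1) and a
symmetric three-slab bilayer of effectively infinite lateral extent
(nanotapes; low-q intensity ~ q^-2).  A seeded synthetic-profile
generator provides noisy test data for the least-squares fitter.

Units: q in 1/A, lengths in A, intensities arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import least_squares
from scipy.special import j1

__all__ = [
    "SaxsError",
    "ScatteringProfile",
    "CoreShellCylinderParams",
    "BilayerParams",
    "cylinder_intensity",
    "bilayer_intensity",
    "synth_profile",
    "fit_profile",
    "lowq_exponent",
    "read_profile",
    "write_profile",
]


class SaxsError(RuntimeError):
    pass


@dataclass
class ScatteringProfile:
    """(q, I, sigma) triple with a provenance tag."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    provenance: str = "computed"  # measured | synthetic | computed

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise SaxsError("q grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise SaxsError("intensities must be finite")
        if self.sigma is not None and np.any(self.sigma <= 0):
            raise SaxsError("sigma values must be positive")


@dataclass
class CoreShellCylinderParams:
    """Core-shell cylinder: radius R, shell s, length L (A), contrasts
    relative to solvent, overall scale and flat background."""

    radius: float = 16.5
    shell: float = 10.0
    length: float = 4000.0
    rho_core: float = -0.5
    rho_shell: float = 1.0
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self):
        if min(self.radius, self.shell, self.length) <= 0:
            raise SaxsError("cylinder dimensions must be positive")


@dataclass
class BilayerParams:
    """Symmetric three-slab bilayer: hydrophobic core of thickness
    t*core_fraction flanked by two head slabs; total thickness t (A).
    The lateral extent is treated as infinite (Porod q^-2 prefactor)."""

    thickness: float = 24.0
    core_fraction: float = 0.6
    rho_core: float = -1.0
    rho_head: float = 0.8
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self):
        if self.thickness <= 0:
            raise SaxsError("bilayer thickness must be positive")
        if not (0.0 < self.core_fraction < 1.0):
            raise SaxsError("core_fraction must be in (0, 1)")


# --------------------------------------------------------------------------
# form factors
# --------------------------------------------------------------------------


def _j1_over_x(x: np.ndarray) -> np.ndarray:
    out = np.full_like(x, 0.5)
    nz = np.abs(x) > 1e-8
    out[nz] = j1(x[nz]) / x[nz]
    return out


def _sinc(x: np.ndarray) -> np.ndarray:
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-8
    out[nz] = np.sin(x[nz]) / x[nz]
    return out


def cylinder_intensity(params: CoreShellCylinderParams, q_grid,
                       quadrature_order: int = 256) -> ScatteringProfile:
    """Orientationally averaged core-shell cylinder form factor.

    The amplitude for a cylinder at angle alpha to q is the standard
    Bessel-function expression; the orientation average is evaluated by
    fixed-order Gauss-Legendre quadrature over cos(alpha).  q = 0 points
    are computed by limit.
    """
    from scipy.integrate import simpson

    q = np.asarray(q_grid, dtype=float)
    r_out = params.radius + params.shell
    v_core = np.pi * params.radius**2 * params.length
    v_out = np.pi * r_out**2 * params.length
    drho_core = params.rho_core - params.rho_shell
    amp0 = drho_core * v_core + params.rho_shell * v_out

    intensity = np.empty_like(q)
    for i, qi in enumerate(q):
        if qi <= 1e-12:
            intensity[i] = amp0**2
            continue
        # sample the axial sinc oscillations (period pi / qz_half in u)
        # with a node count proportional to the quadrature order
        qz_half = qi * params.length / 2.0
        n = max(quadrature_order,
                min(100_000, int(quadrature_order / 21.0 * qz_half / np.pi)))
        n += (n + 1) % 2  # odd count for Simpson
        u = np.linspace(0.0, 1.0, n)
        sin_a = np.sqrt(np.maximum(1.0 - u**2, 0.0))
        amp = (drho_core * v_core * 2.0 * _j1_over_x(qi * sin_a * params.radius)
               + params.rho_shell * v_out * 2.0 * _j1_over_x(qi * sin_a * r_out)
               ) * _sinc(qz_half * u)
        intensity[i] = simpson(amp**2, x=u)
    intensity = params.scale * intensity + params.background
    return ScatteringProfile(q=q, intensity=intensity, provenance="computed")


def bilayer_intensity(params: BilayerParams, q_grid) -> ScatteringProfile:
    """Infinite-slab bilayer: I(q) = scale * P_cs(q) / q^2 + background.

    P_cs is the squared cross-section amplitude of a symmetric slab
    stack: a core slab of contrast rho_core and two flanking head slabs
    of contrast rho_head.  A uniform slab (rho_head = rho_core) has its
    first P_cs zero at q = 2 pi / thickness.
    """
    q = np.asarray(q_grid, dtype=float)
    half_core = 0.5 * params.thickness * params.core_fraction
    half_total = 0.5 * params.thickness
    # A(q) = 2 integral_0^t/2 rho(z) cos(qz) dz
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = np.where(
            q > 1e-12,
            2.0 * (params.rho_core * np.sin(q * half_core)
                   + params.rho_head * (np.sin(q * half_total)
                                        - np.sin(q * half_core))) / q,
            2.0 * (params.rho_core * half_core
                   + params.rho_head * (half_total - half_core)))
    p_cs = amp**2
    with np.errstate(divide="ignore"):
        intensity = np.where(q > 1e-12, params.scale * p_cs / q**2, np.inf)
    if np.any(q <= 1e-12):
        raise SaxsError("bilayer intensity diverges at q = 0; omit q = 0")
    return ScatteringProfile(q=q, intensity=intensity + params.background,
                             provenance="computed")


# --------------------------------------------------------------------------
# synthetic data
# --------------------------------------------------------------------------


def synth_profile(model: str, params, noise_fraction: float, seed: int,
                  q_grid) -> ScatteringProfile:
    """Model curve with seeded multiplicative Gaussian noise.

    I_synth = I_model * (1 + noise_fraction * N(0,1)) per point, with
    sigma = noise_fraction * I_model.  Points that would come out
    non-positive are resampled (deterministically, from the same
    generator).
    """
    if noise_fraction < 0:
        raise SaxsError("noise_fraction must be >= 0")
    clean = evaluate_model(model, params, q_grid)
    rng = np.random.default_rng(seed)
    intensity = clean.intensity.copy()
    if noise_fraction > 0:
        noisy = intensity * (1.0 + noise_fraction * rng.standard_normal(len(intensity)))
        for i in range(len(noisy)):
            attempts = 0
            while noisy[i] <= 0 and attempts < 100:
                noisy[i] = intensity[i] * (1.0 + noise_fraction * rng.standard_normal())
                attempts += 1
        intensity = noisy
        sigma = noise_fraction * clean.intensity
    else:
        sigma = None
    return ScatteringProfile(q=np.asarray(q_grid, dtype=float),
                             intensity=intensity, sigma=sigma,
                             provenance="synthetic")


def evaluate_model(model: str, params, q_grid) -> ScatteringProfile:
    if model == "cylinder":
        return cylinder_intensity(params, q_grid)
    if model == "bilayer":
        return bilayer_intensity(params, q_grid)
    raise SaxsError(f"unknown model {model!r}")


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

#: free parameters per model (name order defines the fit vector)
_FIT_FIELDS = {
    "cylinder": ("radius", "shell", "length", "scale", "background"),
    "bilayer": ("thickness", "core_fraction", "scale", "background"),
}
_DEFAULT_BOUNDS = {
    "radius": (1.0, 200.0), "shell": (1.0, 100.0), "length": (50.0, 1e5),
    "scale": (1e-12, 1e12), "background": (0.0, 1e12),
    "thickness": (2.0, 200.0), "core_fraction": (0.05, 0.95),
}


@dataclass
class FitResult:
    params: object
    uncertainties: dict
    chi2_reduced: float
    converged: bool
    at_bounds: list[str]
    residuals: np.ndarray


#: deterministic multiplicative jitters applied to the start point; the
#: best chi^2 wins (guards against local minima of oscillatory form factors)
_START_JITTERS = (1.0, 0.85, 1.18, 0.7, 1.4)


def fit_profile(profile: ScatteringProfile, model: str, init,
                bounds: dict | None = None,
                fit_fields: tuple[str, ...] | None = None,
                multi_start: bool = True) -> FitResult:
    """Weighted least-squares fit of a form-factor model to a profile.

    Weights use sigma when present, else are proportional to I (constant
    relative error).  A small deterministic multi-start (scaling the
    geometric start values) guards against the local minima of the
    oscillatory form factors; the lowest-chi^2 solution is returned with
    covariance-derived 1-sigma uncertainties, and parameters that ended
    on a bound are flagged.  ``init`` is a params dataclass of the model
    type; non-fitted fields are held fixed.
    """
    fields = fit_fields or _FIT_FIELDS[model]
    if len(profile.q) < 5 * len(fields):
        raise SaxsError(
            f"need >= {5 * len(fields)} points to fit {len(fields)} parameters")
    weights = (1.0 / profile.sigma if profile.sigma is not None
               else 1.0 / np.maximum(profile.intensity, 1e-300))
    x0 = np.array([getattr(init, f) for f in fields], dtype=float)
    user_bounds = bounds or {}
    lo = np.array([user_bounds.get(f, _DEFAULT_BOUNDS[f])[0] for f in fields])
    hi = np.array([user_bounds.get(f, _DEFAULT_BOUNDS[f])[1] for f in fields])
    x0 = np.clip(x0, lo, hi)

    def residual(x):
        p = replace(init, **dict(zip(fields, x)))
        curve = evaluate_model(model, p, profile.q)
        return (curve.intensity - profile.intensity) * weights

    geometric = [f for f in fields if f not in ("scale", "background")]
    jitters = _START_JITTERS if multi_start else (1.0,)
    dof_early = max(len(profile.q) - len(fields), 1)
    result = None
    for jit in jitters:
        start = x0.copy()
        for k, f in enumerate(fields):
            if f in geometric:
                start[k] = np.clip(x0[k] * jit, lo[k], hi[k])
        trial = least_squares(residual, start, bounds=(lo, hi), method="trf",
                              xtol=1e-10, ftol=1e-10, gtol=1e-10,
                              x_scale="jac")
        if result is None or np.sum(trial.fun**2) < np.sum(result.fun**2):
            result = trial
        # a reduced chi^2 near 1 (sigma weights) or tiny relative
        # residuals (I weights) means the global minimum was found
        if np.sum(result.fun**2) / dof_early < (2.0 if profile.sigma is not None
                                                else 1e-6):
            break
    fitted = replace(init, **dict(zip(fields, result.x)))
    dof = max(len(profile.q) - len(fields), 1)
    chi2 = float(np.sum(result.fun**2) / dof)
    # covariance from J^T J (Gauss-Newton approximation)
    uncertainties = {}
    try:
        jtj = result.jac.T @ result.jac
        cov = np.linalg.inv(jtj) * chi2
        for k, f in enumerate(fields):
            uncertainties[f] = float(np.sqrt(max(cov[k, k], 0.0)))
    except np.linalg.LinAlgError:
        uncertainties = {f: float("nan") for f in fields}
    at_bounds = [f for k, f in enumerate(fields)
                 if np.isclose(result.x[k], lo[k]) or np.isclose(result.x[k], hi[k])]
    return FitResult(params=fitted, uncertainties=uncertainties,
                     chi2_reduced=chi2, converged=result.success,
                     at_bounds=at_bounds, residuals=result.fun)


def lowq_exponent(profile: ScatteringProfile,
                  q_window: tuple[float, float]) -> float:
    """Slope of log I vs log q by ordinary least squares in a q window."""
    mask = (profile.q >= q_window[0]) & (profile.q <= q_window[1])
    if mask.sum() < 5:
        raise SaxsError("need >= 5 points in the q window")
    intensity = profile.intensity[mask]
    if np.any(intensity <= 0):
        raise SaxsError("non-positive intensities in the window; subtract "
                        "the background first")
    slope, _intercept = np.polyfit(np.log(profile.q[mask]), np.log(intensity), 1)
    return float(slope)


# --------------------------------------------------------------------------
# profile I/O
# --------------------------------------------------------------------------


def write_profile(profile: ScatteringProfile, path: str,
                  header_extra: str = "") -> None:
    """Two/three-column whitespace text with a comment header."""
    cols = [profile.q, profile.intensity]
    names = "q(1/A) I(a.u.)"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        names += " sigma(a.u.)"
    header = f"provenance: {profile.provenance}\n{names}"
    if header_extra:
        header = header_extra + "\n" + header
    np.savetxt(path, np.column_stack(cols), header=header)


def read_profile(path: str, provenance: str = "measured") -> ScatteringProfile:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise SaxsError("profile file needs at least two columns (q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringProfile(q=data[:, 0], intensity=data[:, 1],
                             sigma=sigma, provenance=provenance)
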