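"""Cole tissue-impedance model: evaluation, circle-based initialisation and fit.

Biological tissue over the 10 kHz-1 MHz band behaves like an extracellular
resistance ``R0`` in parallel with an intracellular branch (resistance
``R_I`` in series with the cell-membrane capacitance ``C_m``).  The
impedance locus across frequency is a depressed circular arc in the
resistance-reactance plane (a Cole-Cole plot), described by

    Z(f) = R_inf + (R0 - R_inf) / (1 + (j f / f_c)^alpha)

with ``R_inf = R0 R_I / (R0 + R_I)`` the infinite-frequency resistance,
``f_c`` the characteristic (apex) frequency and ``alpha`` in (0, 1] the
tissue-heterogeneity exponent (alpha = 1 is an undepressed semicircle).

Fitting proceeds in two stages, mirroring standard practice in
bioimpedance spectroscopy: a Taubin algebraic circle fit supplies the arc
geometry (real-axis intercepts give R0 and R_inf, the arc depression gives
alpha), and Nelder-Mead simplex refinement of all four parameters
minimises the summed squared complex residual.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import CircleFit, ColeParameters, ImpedanceSpectrum, InvalidInputError

__all__ = [
    "cole_impedance",
    "parallel_resistance",
    "intracellular_resistance",
    "membrane_capacitance",
    "characteristic_frequency",
    "taubin_circle_fit",
    "initial_cole_estimates",
    "fit_cole",
    "ColeModel",
    "ColeResults",
    "DegenerateGeometryError",
    "ConvergenceError",
]


class DegenerateGeometryError(ValueError):
    """Input geometry admits no circle / no real-axis intercepts."""


class ConvergenceError(RuntimeError):
    """Simplex refinement exhausted its iteration budget.

    Carries the best parameters seen (``params``) and the final simplex
    spread (``simplex_size``) for post-mortem inspection.
    """

    def __init__(self, message: str, params: np.ndarray, simplex_size: float):
        super().__init__(message)
        self.params = params
        self.simplex_size = simplex_size


def _check_cole_params(r0: float, r_inf: float, alpha: float, fc: float) -> None:
    if not (0 < r_inf < r0):
        raise InvalidInputError("requires 0 < r_inf < r0")
    if not (0 < alpha <= 1):
        raise InvalidInputError("alpha must lie in (0, 1]")
    if not fc > 0:
        raise InvalidInputError("fc must be > 0")


def cole_impedance(r0: float, r_inf: float, alpha: float, fc: float, f):
    """Model impedance Z(f) = R_inf + (R0-R_inf)/(1 + (j f/f_c)^alpha).

    ``f`` may be a scalar or array of frequencies in Hz.  The real part
    decreases monotonically from R0 (f -> 0) to R_inf (f -> inf); the
    imaginary part is <= 0 (capacitive arc in the fourth quadrant).
    """
    _check_cole_params(r0, r_inf, alpha, fc)
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise InvalidInputError("frequency must be >= 0")
    with np.errstate(divide="ignore"):
        jw = (1j * f / fc) ** alpha
    z = r_inf + (r0 - r_inf) / (1.0 + jw)
    return z if z.ndim else complex(z)


def parallel_resistance(r0: float, r_i: float) -> float:
    """Parallel combination r0*r_i/(r0+r_i): tissue resistance as f -> inf."""
    if r0 <= 0 or r_i <= 0:
        raise InvalidInputError("resistances must be > 0")
    return r0 * r_i / (r0 + r_i)


def intracellular_resistance(r0: float, r_inf: float) -> float:
    """Invert the parallel relation: R_I = r0*r_inf/(r0 - r_inf)."""
    if not (r0 > r_inf > 0):
        raise InvalidInputError("requires r0 > r_inf > 0 (non-degenerate arc)")
    return r0 * r_inf / (r0 - r_inf)


def membrane_capacitance(r0: float, r_inf: float, fc: float) -> float:
    """Cell-membrane capacitance C_m = 1/(2*pi*f_c*(R0 + R_I))."""
    if not fc > 0:
        raise InvalidInputError("fc must be > 0")
    r_i = intracellular_resistance(r0, r_inf)
    return 1.0 / (2.0 * np.pi * fc * (r0 + r_i))


def characteristic_frequency(r0: float, r_inf: float, cm: float) -> float:
    """Inverse of :func:`membrane_capacitance`: f_c = 1/(2*pi*C_m*(R0+R_I))."""
    if not cm > 0:
        raise InvalidInputError("cm must be > 0")
    r_i = intracellular_resistance(r0, r_inf)
    return 1.0 / (2.0 * np.pi * cm * (r0 + r_i))


def taubin_circle_fit(points) -> CircleFit:
    """Taubin algebraic circle fit (gradient-weighted algebraic distance).

    Uses the Newton iteration on the Taubin characteristic polynomial in
    centred moments; for points lying exactly on a circle the fit is exact
    to machine precision, and the fit is equivariant under translation.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 3:
        raise InvalidInputError("need >= 3 points to fit a circle")

    centroid = pts.mean(axis=0)
    x = pts[:, 0] - centroid[0]
    y = pts[:, 1] - centroid[1]
    # collinearity check on centred coordinates
    sv = np.linalg.svd(np.column_stack([x, y]), compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < 1e-9:
        raise DegenerateGeometryError("points are (near-)collinear; no circle fit")

    z = x * x + y * y
    mxx, myy, mxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    mxz, myz, mzz = (x * z).mean(), (y * z).mean(), (z * z).mean()

    mz = mxx + myy
    cov_xy = mxx * myy - mxy * mxy
    a3 = 4.0 * mz
    a2 = -3.0 * mz * mz - mzz
    a1 = mzz * mz + 4.0 * cov_xy * mz - mxz * mxz - myz * myz - mz**3
    a0 = (
        mxz * mxz * myy
        + myz * myz * mxx
        - mzz * cov_xy
        - 2.0 * mxz * myz * mxy
        + mz * mz * cov_xy
    )
    a22, a33 = 2.0 * a2, 3.0 * a3

    # Newton iteration from eta = 0 toward the smallest positive root
    eta = 0.0
    yval = a0
    for _ in range(50):
        dy = a1 + eta * (a22 + eta * a33)
        if dy == 0:
            break
        eta_new = eta - yval / dy
        if eta_new == eta or not np.isfinite(eta_new):
            break
        y_new = a0 + eta_new * (a1 + eta_new * (a2 + eta_new * (a3 + eta_new)))
        if abs(y_new) > abs(yval):
            break
        eta, yval = eta_new, y_new

    det = eta * eta - eta * mz + cov_xy
    if det == 0 or not np.isfinite(det):
        raise DegenerateGeometryError("degenerate moment matrix in circle fit")
    cx = (mxz * (myy - eta) - myz * mxy) / det / 2.0
    cy = (myz * (mxx - eta) - mxz * mxy) / det / 2.0
    radius = float(np.sqrt(cx * cx + cy * cy + mz - 2.0 * eta))
    if not np.isfinite(radius) or radius <= 0:
        raise DegenerateGeometryError("circle fit produced a non-finite radius")
    return CircleFit(
        center_x=float(cx + centroid[0]),
        center_y=float(cy + centroid[1]),
        radius=radius,
    )


def initial_cole_estimates(circle: CircleFit) -> tuple[float, float, float]:
    """Arc geometry -> (r0, r_inf, alpha) starting values.

    The circle's real-axis intercepts are the zero- and infinite-frequency
    resistances; the depression of the centre below the axis encodes
    alpha: alpha = (2/pi) * arccos(|cy| / radius).
    """
    if not circle.crosses_real_axis:
        raise DegenerateGeometryError(
            "fitted circle does not cross the real axis; no R0/R_inf intercepts"
        )
    half_chord = float(np.sqrt(circle.radius**2 - circle.center_y**2))
    r_inf = circle.center_x - half_chord
    r0 = circle.center_x + half_chord
    alpha = float((2.0 / np.pi) * np.arccos(abs(circle.center_y) / circle.radius))
    return r0, r_inf, alpha


# ---------------------------------------------------------------------------
# Model / Results


_ALPHA_CAP = 1.0 - 1e-9


def _pack(r0: float, r_inf: float, alpha: float, fc: float) -> np.ndarray:
    """Map (r0, r_inf, alpha, fc) to an unconstrained simplex vector."""
    alpha = min(max(alpha, 1e-9), _ALPHA_CAP)
    return np.array(
        [
            np.log(r_inf),
            np.log(r0 - r_inf),
            np.log(alpha / (1.0 - alpha)),
            np.log(fc),
        ]
    )


def _unpack(theta: np.ndarray) -> tuple[float, float, float, float]:
    r_inf = np.exp(theta[0])
    r0 = r_inf + np.exp(theta[1])
    alpha = 1.0 / (1.0 + np.exp(-theta[2]))
    fc = np.exp(theta[3])
    return r0, r_inf, alpha, fc


class ColeModel:
    """Cole arc model bound to one measured impedance spectrum.

    Parameters
    ----------
    spectrum : ImpedanceSpectrum
        Complex impedance at >= 5 strictly increasing frequencies.
    ftol_rel : float
        Relative objective tolerance: each simplex run terminates when the
        vertex spread falls below ``max(fatol, ftol_rel * |f|)``.
    fatol, xatol : float
        Absolute floors for the objective / parameter-spread tolerances.
    maxiter : int
        Iteration budget per simplex run; one restart from the incumbent
        optimum is always performed, so the total budget is twice this.
    """

    def __init__(
        self,
        spectrum: ImpedanceSpectrum,
        *,
        ftol_rel: float = 1e-10,
        fatol: float = 1e-15,
        xatol: float = 1e-9,
        maxiter: int = 2000,
    ):
        self.spectrum = spectrum
        self.ftol_rel = ftol_rel
        self.fatol = fatol
        self.xatol = xatol
        self.maxiter = maxiter

    def _objective(self, theta: np.ndarray) -> float:
        r0, r_inf, alpha, fc = _unpack(theta)
        if not np.isfinite([r0, r_inf, fc]).all():
            return np.inf
        z = cole_impedance(r0, r_inf, min(alpha, _ALPHA_CAP), fc, self.spectrum.frequencies)
        resid = self.spectrum.impedance - z
        return float(np.sum(resid.real**2 + resid.imag**2))

    def initial_parameters(self) -> np.ndarray:
        """Taubin circle geometry plus the apex frequency, packed."""
        pts = np.column_stack([self.spectrum.resistance, self.spectrum.reactance])
        circle = taubin_circle_fit(pts)
        span = max(self.spectrum.resistance.max() - self.spectrum.resistance.min(), 1e-6)
        try:
            r0, r_inf, alpha = initial_cole_estimates(circle)
        except DegenerateGeometryError:
            # noisy partial arc whose circle misses the real axis: start
            # from the resistance extremes instead
            r0 = self.spectrum.resistance.max() + 0.1 * span
            r_inf = self.spectrum.resistance.min() - 0.1 * span
            alpha = 0.8
        if r_inf <= 0:
            r_inf = max(0.05 * span, 1e-3)
        if r0 <= r_inf:
            r0 = r_inf + span
        fc0 = float(self.spectrum.frequencies[np.argmax(np.abs(self.spectrum.reactance))])
        return _pack(r0, r_inf, alpha, fc0)

    def fit(self) -> "ColeResults":
        theta0 = self.initial_parameters()
        f_prev = self._objective(theta0)
        best = None
        for stage in range(2):  # one refinement restart from the incumbent
            res = optimize.minimize(
                self._objective,
                theta0,
                method="Nelder-Mead",
                options={
                    "fatol": max(self.fatol, self.ftol_rel * abs(f_prev)),
                    "xatol": self.xatol,
                    "maxiter": self.maxiter,
                    "maxfev": 4 * self.maxiter,
                },
            )
            best = res
            theta0, f_prev = res.x, res.fun
        if not best.success:
            simplex = best.final_simplex[0]
            size = float(np.max(np.abs(simplex - simplex[0])))
            raise ConvergenceError(
                f"Nelder-Mead exhausted {self.maxiter} iterations (f={best.fun:.3e})",
                params=np.array(_unpack(best.x)),
                simplex_size=size,
            )
        r0, r_inf, alpha, fc = _unpack(best.x)
        if alpha >= _ALPHA_CAP:
            alpha = 1.0
        params = ColeParameters(
            r0=float(r0),
            r_i=float(intracellular_resistance(r0, r_inf)),
            r_inf=float(r_inf),
            r0_minus_rinf=float(r0 - r_inf),
            alpha=float(alpha),
            fc=float(fc),
            cm=float(membrane_capacitance(r0, r_inf, fc)),
            fitting_error=float(best.fun),
        )
        return ColeResults(self, params, n_iterations=int(best.nit))


@dataclass(frozen=True)
class ColeResults:
    """Fitted Cole parameters with Gauss-Newton uncertainty estimates."""

    model: ColeModel
    params: ColeParameters
    n_iterations: int

    _PARAM_NAMES = ("r0", "r_inf", "alpha", "fc")

    def _jacobian(self) -> np.ndarray:
        """Numerical Jacobian of stacked (Re, Im) residuals w.r.t. params."""
        p = self.params
        theta = np.array([p.r0, p.r_inf, p.alpha, p.fc])
        f = self.model.spectrum.frequencies

        def stacked(t):
            z = cole_impedance(t[0], t[1], min(t[2], 1.0), t[3], f)
            return np.concatenate([z.real, z.imag])

        base = stacked(theta)
        jac = np.empty((base.size, 4))
        for k in range(4):
            h = 1e-6 * max(abs(theta[k]), 1e-12)
            tp = theta.copy()
            tp[k] += h
            jac[:, k] = (stacked(tp) - base) / h
        return jac

    def bse(self) -> pd.Series:
        """Approximate standard errors from the Gauss-Newton curvature."""
        jac = self._jacobian()
        n_resid = jac.shape[0]
        dof = max(n_resid - 4, 1)
        sigma2 = self.params.fitting_error / dof
        jtj = jac.T @ jac
        try:
            cov = sigma2 * np.linalg.inv(jtj)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(4, np.nan)
        return pd.Series(se, index=self._PARAM_NAMES)

    def summary(self) -> str:
        p = self.params
        se = self.bse()
        lines = [
            "Cole tissue-impedance model fit",
            "=" * 46,
            f"{'n frequencies':<22}{self.model.spectrum.frequencies.size:>24}",
            f"{'iterations':<22}{self.n_iterations:>24}",
            f"{'fitting error (Ohm^2)':<22}{p.fitting_error:>24.6e}",
            "-" * 46,
            f"{'param':<10}{'estimate':>18}{'std err':>18}",
        ]
        values = {"r0": p.r0, "r_inf": p.r_inf, "alpha": p.alpha, "fc": p.fc}
        for name in self._PARAM_NAMES:
            lines.append(f"{name:<10}{values[name]:>18.6g}{se[name]:>18.3g}")
        lines += [
            "-" * 46,
            f"{'r_i (Ohm)':<22}{p.r_i:>24.6g}",
            f"{'r0 - r_inf (Ohm)':<22}{p.r0_minus_rinf:>24.6g}",
            f"{'C_m (F)':<22}{p.cm:>24.6g}",
        ]
        return "\n".join(lines)

    def predict(self, frequencies=None) -> np.ndarray:
        f = self.model.spectrum.frequencies if frequencies is None else frequencies
        p = self.params
        return cole_impedance(p.r0, p.r_inf, p.alpha, p.fc, f)

    def plot(self, ax=None):
        """Cole-Cole plot: measured points and fitted arc, -Im(Z) upward."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        spec = self.model.spectrum
        ax.plot(spec.resistance, -spec.reactance, "o", label="measured")
        f_dense = np.geomspace(spec.frequencies[0] / 10, spec.frequencies[-1] * 10, 400)
        z = self.predict(f_dense)
        ax.plot(z.real, -z.imag, "-", label="Cole fit")
        ax.set_xlabel("Resistance (Ω)")
        ax.set_ylabel("−Reactance (Ω)")
        ax.legend()
        return ax


def fit_cole(spectrum: ImpedanceSpectrum, **options) -> ColeParameters:
    """Fit the Cole model to a spectrum; convenience wrapper over ColeModel."""
    return ColeModel(spectrum, **options).fit().params
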