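"""Recovery of the nine viscoelastic markers from raw creep records.

Two extraction paths feed the marker table, mirroring the measurement
pipeline: the double power-law characterization supplies the short- and
long-time exponents ``alphaL`` and ``alphaR`` directly from log-log
regressions, while the hierarchical-model fit supplies the branch moduli
``E1, E2, E3`` and viscosity ``eta`` (and hence the derived markers
``Esum``, ``tau`` and ``fT``).

The hierarchical fit is a penalized (MAP-style) least-squares problem.  At
realistic measurement noise the six-parameter inverse problem is sloppy:
many parameter combinations reproduce a creep curve equally well, so an
unpenalized fit returns marker values dominated by noise along the flat
directions of the likelihood.  The fit therefore minimizes

    sum_i [ (ln J_model(t_i) - ln J_obs(t_i)) / sigma_hat ]^2
    + sum_k [ (theta_k - theta0_k) / prior_sd_k ]^2

where ``theta = (ln E1, ln s_x, ln E3, ln eta, alphaL, alphaR)`` — with
``s_x = 2 pi fT`` the branch-crossover rate carried as a coordinate so the
curve's visible kink constrains the transition frequency directly —
``theta0`` are robust per-curve descriptors (window slopes, compliance
level at the reference rate, branch-line crossover) and ``sigma_hat`` is a
per-curve noise estimate from fourth differences.  On noiseless curves
``sigma_hat`` collapses and the data term dominates, so exact parameter
recovery is preserved; on noisy curves the penalty pins the sloppy
directions to the descriptor values while the likelihood refines the
identifiable combinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import gamma as _gamma_fn

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cohort import MARKER_COLUMNS, CohortDataset
from .rheology import (
    OMEGA0,
    PAPER_UNIT_PA,
    CreepCurve,
    DerivedMarkers,
    ViscoParams,
    _stehfest_weights,
    derived_markers,
    hertz_compliance,
)

__all__ = [
    "FitResult",
    "FitReport",
    "DEFAULT_SHORT_WINDOW",
    "DEFAULT_LONG_WINDOW",
    "fit_hierarchical_model",
    "fit_double_power_law",
    "build_feature_table",
    "extract_features",
    "MARKERS",
]

MARKERS = list(MARKER_COLUMNS)

#: default regression windows (seconds).  The short window reads the fast
#: power-law branch; the long window sits between the fast-branch crossover
#: and the network-plateau onset, where the slow branch (exponent ~0.2)
#: dominates the response.
DEFAULT_SHORT_WINDOW = (0.0, 0.1)
DEFAULT_LONG_WINDOW = (1.5, 6.0)

#: parameter bounds used by the fit: moduli/viscosity (U), exponents
_LN_AMP_BOUNDS = (np.log(1e-3), np.log(1e7))
_ALPHA_L_BOUNDS = (0.5, 1.0)
_ALPHA_R_BOUNDS = (0.10, 0.35)

#: prior widths for (lnE1, ln s_x, lnE3, ln eta, alphaL, alphaR); s_x is the
#: branch-crossover rate (2 pi fT), carried as a fit coordinate so that the
#: transition frequency is constrained directly by the visible kink of the
#: curve instead of through the noise-amplifying ratio (E2/E1)^{1/(aL-aR)}
_PRIOR_SD = np.array([0.6, 0.6, 1.0, 1.0, 0.08, 0.04])
_LN_SX_BOUNDS = (-5.0, 7.0)

_SIGMA_FLOOR = 1.0e-7


class ExtractionError(ValueError):
    pass


@dataclass(frozen=True)
class FitResult:
    params: ViscoParams
    derived: DerivedMarkers
    r_squared: float
    converged: bool
    n_iter: int
    sigma_hat: float = float("nan")
    message: str = ""


@dataclass(frozen=True)
class FitReport:
    """Cohort-level accounting of the extraction step."""

    n_total: int
    n_kept: int
    n_dropped_r2: int
    n_dropped_diverged: int
    r2_min: float
    median_r2: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (times >= lo) & (times <= hi)


def _regress(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    xm = x.mean()
    xc = x - xm
    slope = float(xc @ y / (xc @ xc))
    return slope, float(y.mean() - slope * xm)


def fit_double_power_law(
    curve: CreepCurve,
    short_window: tuple[float, float] | None = None,
    long_window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Short- and long-time power-law exponents by log-log regression.

    Windows default to ``[t_min, 0.1]`` s and ``[1.5, 6]`` s; each must
    contain at least 6 samples and they must not overlap.
    """
    if curve.kind != "compliance":
        raise ExtractionError("fit_double_power_law expects a compliance curve")
    t = curve.times
    short_window = short_window or (t[0], DEFAULT_SHORT_WINDOW[1])
    long_window = long_window or DEFAULT_LONG_WINDOW
    if short_window[1] > long_window[0]:
        raise ExtractionError("short and long windows must be disjoint")
    out = []
    for window in (short_window, long_window):
        m = _window_mask(t, window)
        if m.sum() < 6:
            raise ExtractionError(
                f"window {window} covers only {int(m.sum())} samples (need >= 6)"
            )
        slope, _ = _regress(np.log(t[m]), np.log(curve.values[m]))
        out.append(slope)
    return out[0], out[1]


def _estimate_noise(log_values: np.ndarray) -> float:
    """Noise level of ln J from fourth differences (log-spaced grid).

    High-order differencing cancels the smooth power-law trend (so a
    noiseless curve yields ~0) while white noise survives with variance
    70 sigma^2 per difference.
    """
    d4 = np.diff(log_values, n=4)
    return float(np.sqrt(np.mean(d4**2) / 70.0))


def _heuristic_theta0(curve: CreepCurve) -> np.ndarray:
    """Robust descriptor-based starting point / prior centre.

    alphaL, alphaR from the window regressions; the total level from the
    compliance around t = 1/w0 corrected by the local power-law factor
    Gamma(1 + slope); the fast/slow amplitude split from the crossover of
    the two regression lines (the operational transition frequency).
    """
    t, j = curve.times, curve.values
    ln_t, ln_j = np.log(t), np.log(j)

    a_l, b_s = _regress(*_clip_window(ln_t, ln_j, t, (t[0], DEFAULT_SHORT_WINDOW[1])))
    a_r, b_l = _regress(*_clip_window(ln_t, ln_j, t, DEFAULT_LONG_WINDOW))
    a_l = float(np.clip(a_l, 0.505, 0.995))
    a_r = float(np.clip(a_r, 0.105, 0.345))
    if a_l - a_r < 0.12:
        a_l = min(a_r + 0.12, 0.995)

    c1, b1 = _regress(*_clip_window(ln_t, ln_j, t, (0.6, 1.6)))
    c1 = float(np.clip(c1, 0.01, 0.99))
    g1 = 1.0 / (np.exp(b1) * _gamma_fn(1.0 + c1))  # ~ Ghat(w0), all branches

    # crossover of the two branch lines: E1 (w/w0)^aL = E2 (w/w0)^aR
    ln_tx = float(np.clip((b_l - b_s) / (a_l - a_r), np.log(5e-3), np.log(50.0)))
    r12 = float(np.exp(-(a_l - a_r) * ln_tx))  # E2/E1 at the reference rate

    eta0 = 0.10 * g1  # Newtonian share of the total level at w0
    e_sum0 = max(g1 - eta0, 1e-3)
    # split: fast branch e1, slow branch e2, remainder network plateau
    e1_0 = e_sum0 / (1.0 + r12 + 0.5)
    e3_0 = max(e_sum0 - e1_0 * (1.0 + r12), 0.02 * e_sum0)
    return np.array([np.log(e1_0), -ln_tx, np.log(e3_0), np.log(eta0), a_l, a_r])


def _clip_window(ln_t, ln_j, t, window):
    m = _window_mask(t, window)
    if m.sum() < 4:
        m = slice(0, max(4, int(t.size * 0.1)))
    return ln_t[m], ln_j[m]


def _theta_to_params(theta: np.ndarray) -> ViscoParams:
    e1, e3, eta = np.exp(theta[[0, 2, 3]])
    a_l, a_r = theta[4], theta[5]
    e2 = e1 * np.exp((a_l - a_r) * theta[1])  # E2 = E1 * s_x^(aL - aR)
    return ViscoParams(float(e1), float(e2), float(e3), float(eta), float(a_l), float(a_r))


def _model_log_compliance(theta: np.ndarray, s: np.ndarray, ln_s: np.ndarray,
                          pref: np.ndarray, w: np.ndarray):
    e1, e3, eta = np.exp(theta[[0, 2, 3]])
    a_l, a_r = theta[4], theta[5]
    ln_sx = theta[1]
    branch_l = e1 * np.exp(a_l * ln_s)
    branch_r = e1 * np.exp((a_l - a_r) * ln_sx + a_r * ln_s)
    g = e3 + branch_r + branch_l + eta * s
    j = pref * ((1.0 / (s * g)) @ w)
    return j, g, branch_l, branch_r


def fit_hierarchical_model(
    curve: CreepCurve,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    init: ViscoParams | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Penalized weighted least-squares fit of the hierarchical surrogate.

    Multi-start strategy: one descriptor-based heuristic start plus up to
    ``n_starts - 1`` perturbed restarts; restarts stop early once the data
    term reaches the per-curve noise floor (reduced chi-square ~ 1).
    Never raises on failure: ``converged`` is False with a diagnostic
    message instead.
    """
    if curve.kind != "compliance":
        raise ExtractionError("fit_hierarchical_model expects a compliance curve")
    t = curve.times
    ln_j_obs = np.log(curve.values)
    sigma = max(_estimate_noise(ln_j_obs), _SIGMA_FLOOR)

    w, k = _stehfest_weights()
    ln2 = np.log(2.0)
    s = np.outer(ln2 / t, k)
    ln_s = np.log(s / OMEGA0)
    pref = ln2 / t

    theta0 = _heuristic_theta0(curve)
    if init is not None:
        x = init.as_array()
        ln_sx = np.log(x[1] / x[0]) / (x[4] - x[5])
        theta0 = np.array([np.log(x[0]), ln_sx, np.log(max(x[2], 1e-6)),
                           np.log(max(x[3], 1e-6)), x[4], x[5]])
    if bounds is None:
        lo = np.array([_LN_AMP_BOUNDS[0], _LN_SX_BOUNDS[0], _LN_AMP_BOUNDS[0],
                       _LN_AMP_BOUNDS[0], _ALPHA_L_BOUNDS[0], _ALPHA_R_BOUNDS[0]])
        hi = np.array([_LN_AMP_BOUNDS[1], _LN_SX_BOUNDS[1], _LN_AMP_BOUNDS[1],
                       _LN_AMP_BOUNDS[1], _ALPHA_L_BOUNDS[1], _ALPHA_R_BOUNDS[1]])
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    theta0 = np.clip(theta0, lo, hi)

    prior_sd = _PRIOR_SD

    def residuals(theta):
        j, *_ = _model_log_compliance(theta, s, ln_s, pref, w)
        data = (np.log(j) - ln_j_obs) / sigma
        return np.concatenate([data, (theta - theta0) / prior_sd])

    def jacobian(theta):
        j, g, branch_l, branch_r = _model_log_compliance(theta, s, ln_s, pref, w)
        e3, eta = np.exp(theta[[2, 3]])
        ln_sx = theta[1]
        gap = theta[4] - theta[5]
        grads = (
            branch_l + branch_r,               # d/d lnE1
            gap * branch_r,                    # d/d ln s_x
            np.full_like(s, e3),               # d/d lnE3
            eta * s,                           # d/d ln eta
            branch_l * ln_s + branch_r * ln_sx,  # d/d alphaL
            branch_r * (ln_s - ln_sx),         # d/d alphaR
        )
        out = np.empty((t.size + 6, 6))
        inv = -1.0 / (s * g * g)
        for col, grad in enumerate(grads):
            out[: t.size, col] = pref * ((inv * grad) @ w) / j / sigma
        out[t.size:, :] = np.diag(1.0 / prior_sd)
        return out

    j_obs = curve.values
    ss_tot = float(np.sum((j_obs - j_obs.mean()) ** 2))
    rng = np.random.default_rng(seed)
    best = None
    best_r2 = -np.inf
    n_iter = 0
    message = ""
    n_data = t.size
    for start in range(max(1, n_starts)):
        x0 = theta0
        if start > 0:
            jitter = rng.normal(0.0, 1.0, 6) * np.array([0.4, 0.4, 0.6, 0.6, 0.05, 0.03])
            x0 = np.clip(theta0 + jitter, lo, hi)
        try:
            # near-noiseless curves demand much deeper convergence to pin
            # the sloppy directions, so grant them a larger budget
            max_nfev = 3000 if sigma < 1e-5 else 600
            res = least_squares(
                residuals, x0, jac=jacobian, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-14, max_nfev=max_nfev,
            )
        except Exception as exc:  # Stehfest overflow or solver failure
            message = f"start {start}: {exc}"
            continue
        n_iter += res.nfev
        if best is None or res.cost < best.cost:
            best = res
            j_fit, *_ = _model_log_compliance(res.x, s, ln_s, pref, w)
            best_r2 = 1.0 - float(np.sum((j_fit - j_obs) ** 2)) / ss_tot
        # stop restarting once the data term is at the noise floor
        data_chi2 = float(np.sum(best.fun[:n_data] ** 2))
        if data_chi2 <= 1.3 * n_data:
            break

    if best is None:
        dummy = ViscoParams(1.0, 1.0, 1.0, 1.0, 0.75, 0.2)
        return FitResult(dummy, derived_markers(dummy), float("-inf"), False,
                         n_iter, sigma, message or "all starts failed")
    params = _theta_to_params(best.x)
    converged = bool(best.status > 0 and np.isfinite(best_r2))
    return FitResult(
        params=params,
        derived=derived_markers(params),
        r_squared=best_r2,
        converged=converged,
        n_iter=n_iter,
        sigma_hat=sigma,
        message=message,
    )


def build_feature_table(
    fits: list[FitResult],
    power_laws: list[tuple[float, float]],
    statuses: list[int],
    r2_min: float = 0.9,
    measurement_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, FitReport]:
    """Assemble the nine-marker table, dropping unreliable fits.

    Rows with ``converged == False`` or ``r_squared < r2_min`` are removed
    and counted in the report.  A loud warning (not an error) is emitted if
    more than half of the rows are dropped.
    """
    if not (len(fits) == len(power_laws) == len(statuses)):
        raise ExtractionError("fits, power_laws and statuses must have equal length")
    ids = measurement_ids or [f"m{i:05d}" for i in range(len(fits))]
    rows = []
    n_bad_r2 = n_div = 0
    for mid, fit, (a_l_hat, a_r_hat), status in zip(ids, fits, power_laws, statuses):
        if not fit.converged:
            n_div += 1
            continue
        if fit.r_squared < r2_min:
            n_bad_r2 += 1
            continue
        p, d = fit.params, fit.derived
        rows.append({
            "measurement_id": mid, "E1": p.e1, "E2": p.e2, "E3": p.e3,
            "Esum": d.e_sum, "eta": p.eta, "tau": d.tau, "fT": d.f_t,
            "alphaL": a_l_hat, "alphaR": a_r_hat, "status": int(status),
        })
    table = pd.DataFrame(rows, columns=["measurement_id", *MARKERS, "status"])
    report = FitReport(
        n_total=len(fits),
        n_kept=len(table),
        n_dropped_r2=n_bad_r2,
        n_dropped_diverged=n_div,
        r2_min=r2_min,
        median_r2=float(np.median([f.r_squared for f in fits])) if fits else float("nan"),
    )
    if fits and report.n_kept < 0.5 * report.n_total:
        warnings.warn(
            f"extraction dropped {report.n_total - report.n_kept} of "
            f"{report.n_total} measurements (R2 < {r2_min} or diverged)",
            stacklevel=2,
        )
    return table, report


def compliance_in_paper_units(curve: CreepCurve, protocol) -> CreepCurve:
    """Hertz-convert an SI indentation record and rescale to 1/U."""
    j_si = hertz_compliance(curve, protocol)
    return j_si.with_values(j_si.values * PAPER_UNIT_PA)


def extract_features(
    dataset: CohortDataset,
    r2_min: float = 0.9,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, FitReport]:
    """Full extraction pipeline for a simulated cohort.

    Converts each indentation record to creep compliance in paper units,
    runs the hierarchical fit and the double power-law regressions, and
    assembles the filtered marker table.
    """
    fits, plaws, statuses, ids = [], [], [], []
    for i, (mid, curve) in enumerate(dataset.measurements.items()):
        comp = compliance_in_paper_units(curve, dataset.config.protocol)
        fits.append(fit_hierarchical_model(comp, n_starts=n_starts, seed=seed + i))
        plaws.append(fit_double_power_law(comp))
        statuses.append(int(curve.meta.get("status", -1)))
        ids.append(mid)
    return build_feature_table(fits, plaws, statuses, r2_min=r2_min, measurement_ids=ids)
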