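"""Forward viscoelastic model, Hertz contact conversion and slope analysis.

The tissue is described by a four-branch Laplace-domain relaxation modulus

    Ghat(s) = E3 + E2 (s/w0)^aR + E1 (s/w0)^aL + eta * s,      w0 = 1 rad/s

a compact surrogate for self-similar hierarchical rheology that reproduces
the phenomenology seen in AFM creep of soft tissue: a fast power-law branch
with exponent ``alpha_l`` in (0.5, 1) at short times, a slow branch with
exponent ``alpha_r`` near 0.2 at longer times, a network plateau ``E3`` and
a Newtonian cytoplasmic flow term ``eta``.  Creep compliance follows by
numerical inversion of ``Jhat(s) = 1 / (s Ghat(s))`` with the Gaver-Stehfest
algorithm.

Moduli are carried in "paper units" U; the cohort simulator maps 1 U = 1 kPa
when producing SI indentation records (see :mod:`viscoclass.cohort`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from math import factorial
from typing import NamedTuple

import numpy as np

__all__ = [
    "OMEGA0",
    "STEHFEST_N",
    "PAPER_UNIT_PA",
    "ViscoParams",
    "CreepCurve",
    "IndentationProtocol",
    "DerivedMarkers",
    "laplace_modulus",
    "creep_compliance",
    "hertz_compliance",
    "hertz_indentation",
    "derived_markers",
    "local_loglog_slope",
]

#: reference rate fixing the unit of the power-law branches (rad/s)
OMEGA0 = 1.0
#: number of Gaver-Stehfest terms (even; validated against closed forms)
STEHFEST_N = 14
#: SI pressure represented by one paper unit U (1 U = 1 kPa)
PAPER_UNIT_PA = 1.0e3


class RheologyError(ValueError):
    """Domain error in rheological inputs."""


class StehfestError(ArithmeticError):
    """Numerical failure of the Gaver-Stehfest inversion."""


@dataclass(frozen=True)
class ViscoParams:
    """Parameters of the hierarchical surrogate model (paper units U).

    ``e1``: cytoplasm modulus, ``e2``: cytoskeleton-fiber modulus,
    ``e3``: whole-network modulus, ``eta``: cytoplasm viscosity (U s),
    ``alpha_l``/``alpha_r``: short-/long-time power-law exponents.

    Moduli and viscosity must be non-negative; zero values are degenerate
    single-element limits used for validation against closed forms.  A
    physical tissue draw has all of them strictly positive.
    """

    e1: float
    e2: float
    e3: float
    eta: float
    alpha_l: float
    alpha_r: float

    def __post_init__(self) -> None:
        for name in ("e1", "e2", "e3", "eta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise RheologyError(f"{name} must be finite and >= 0, got {v!r}")
        if not (0.0 < self.alpha_r < self.alpha_l < 1.0):
            raise RheologyError(
                "exponents must satisfy 0 < alpha_r < alpha_l < 1, got "
                f"alpha_l={self.alpha_l!r}, alpha_r={self.alpha_r!r}"
            )

    @property
    def e_sum(self) -> float:
        """Total modulus E1 + E2 + E3 (U)."""
        return self.e1 + self.e2 + self.e3

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.e1, self.e2, self.e3, self.eta, self.alpha_l, self.alpha_r]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ViscoParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class CreepCurve:
    """One measurement record: creep compliance or indentation versus time.

    ``times`` are in seconds, strictly increasing and positive.  ``values``
    are creep compliance (1/U, or 1/Pa for SI records) when
    ``kind == "compliance"`` and metres when ``kind == "indentation"``.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "compliance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.kind not in ("compliance", "indentation"):
            raise RheologyError(f"unknown curve kind {self.kind!r}")
        if t.ndim != 1 or v.shape != t.shape:
            raise RheologyError("times and values must be 1-D arrays of equal length")
        if t.size < 8:
            raise RheologyError("a creep record needs at least 8 samples")
        if not (t > 0).all() or not (np.diff(t) > 0).all():
            raise RheologyError("times must be positive and strictly increasing")
        if not np.isfinite(v).all() or not (v > 0).all():
            raise RheologyError("values must be finite and strictly positive")

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "CreepCurve":
        return replace(self, values=values, kind=kind or self.kind)


@dataclass(frozen=True)
class IndentationProtocol:
    """AFM step-force indentation protocol.

    Defaults follow the measurement description: spherical probe of 20 um
    diameter, incompressible tissue (nu = 0.5), 10 s hold, and a log-spaced
    grid of 60 samples from 0.02 s.
    """

    force: float = 1.0e-8  # N
    probe_radius: float = 10.0e-6  # m
    poisson: float = 0.5
    hold_time: float = 10.0  # s
    n_points: int = 60
    t_min: float = 0.02  # s

    def __post_init__(self) -> None:
        if self.force <= 0:
            raise RheologyError("step force must be positive")
        if self.probe_radius <= 0:
            raise RheologyError("probe radius must be positive")
        if not (0.0 <= self.poisson < 1.0):
            raise RheologyError("Poisson ratio must lie in [0, 1)")
        if not (0 < self.t_min < self.hold_time):
            raise RheologyError("need 0 < t_min < hold_time")
        if self.n_points < 8:
            raise RheologyError("n_points must be at least 8")

    def time_grid(self) -> np.ndarray:
        """Log-spaced sampling times in seconds."""
        return np.geomspace(self.t_min, self.hold_time, self.n_points)


class DerivedMarkers(NamedTuple):
    e_sum: float  # U
    tau: float  # s
    f_t: float  # Hz


@lru_cache(maxsize=None)
def _stehfest_weights(n: int = STEHFEST_N) -> tuple[np.ndarray, np.ndarray]:
    if n % 2:
        raise ValueError("Stehfest term count must be even")
    half = n // 2
    w = np.zeros(n)
    for k in range(1, n + 1):
        acc = 0.0
        for j in range((k + 1) // 2, min(k, half) + 1):
            acc += (
                j**half
                * factorial(2 * j)
                / (
                    factorial(half - j)
                    * factorial(j)
                    * factorial(j - 1)
                    * factorial(k - j)
                    * factorial(2 * j - k)
                )
            )
        w[k - 1] = (-1) ** (k + half) * acc
    return w, np.arange(1, n + 1, dtype=float)


def laplace_modulus(params: ViscoParams, s) -> np.ndarray | float:
    """Relaxation modulus Ghat(s) of the surrogate model (U).

    Strictly increasing in ``s``; tends to the network plateau ``e3`` as
    ``s -> 0`` and to the Newtonian branch as ``s -> inf``.
    """
    s_arr = np.asarray(s, dtype=float)
    if not (s_arr > 0).all():
        raise RheologyError("Laplace rate s must be positive")
    sn = s_arr / OMEGA0
    out = (
        params.e3
        + params.e2 * sn**params.alpha_r
        + params.e1 * sn**params.alpha_l
        + params.eta * s_arr
    )
    return out if np.ndim(s) else float(out)


def creep_compliance(params: ViscoParams, times) -> CreepCurve:
    """Creep compliance J(t) by Gaver-Stehfest inversion of 1/(s Ghat(s)).

    Valid for times in [1e-3, 1e3] s; the result is strictly positive and
    non-decreasing for every physical parameter set.
    """
    t = np.asarray(times, dtype=float)
    if not ((t >= 1.0e-3) & (t <= 1.0e3)).all():
        raise RheologyError("times must lie in [1e-3, 1e3] s")
    w, k = _stehfest_weights()
    ln2 = np.log(2.0)
    s = np.outer(ln2 / t, k)  # (nt, N)
    jhat = 1.0 / (s * laplace_modulus(params, s))
    j = (ln2 / t) * (jhat @ w)
    if not np.isfinite(j).all() or (j <= 0).any():
        raise StehfestError(
            "Gaver-Stehfest inversion produced non-finite or non-positive "
            f"compliance for params {params!r}"
        )
    return CreepCurve(times=t, values=j, kind="compliance")


def _hertz_factor(protocol: IndentationProtocol) -> float:
    return (
        4.0
        * np.sqrt(protocol.probe_radius)
        / (3.0 * protocol.force * (1.0 - protocol.poisson**2))
    )


def hertz_compliance(indentation: CreepCurve, protocol: IndentationProtocol) -> CreepCurve:
    """Convert an indentation record to creep compliance via Hertz contact.

    For a spherical probe under step force F:
    ``J(t) = 4 sqrt(R) d(t)^{3/2} / (3 F (1 - nu^2))`` with d the depth.
    Units are 1/Pa when the inputs are SI.
    """
    if indentation.kind != "indentation":
        raise RheologyError("hertz_compliance expects an indentation curve")
    j = _hertz_factor(protocol) * indentation.values**1.5
    return indentation.with_values(j, kind="compliance")


def hertz_indentation(compliance: CreepCurve, protocol: IndentationProtocol) -> CreepCurve:
    """Inverse Hertz map: depth d(t) = [J(t) / hertz_factor]^{2/3} (metres)."""
    if compliance.kind != "compliance":
        raise RheologyError("hertz_indentation expects a compliance curve")
    d = (compliance.values / _hertz_factor(protocol)) ** (2.0 / 3.0)
    return compliance.with_values(d, kind="indentation")


def derived_markers(params: ViscoParams) -> DerivedMarkers:
    """Total modulus, relaxation time and transition frequency.

    ``e_sum = E1 + E2 + E3``;  ``tau = eta / E1``;  ``f_t`` is the frequency
    at which the fast and slow power-law branches of Ghat are equal:
    ``E1 (w/w0)^aL = E2 (w/w0)^aR``  =>
    ``f_t = (w0 / 2 pi) (E2/E1)^{1/(aL - aR)}``.
    """
    gap = params.alpha_l - params.alpha_r
    if gap <= 1.0e-9:
        raise RheologyError("degenerate exponents: alpha_l must exceed alpha_r")
    if params.e1 <= 0 or params.e2 <= 0:
        raise RheologyError("transition frequency needs positive e1 and e2")
    f_t = (OMEGA0 / (2.0 * np.pi)) * (params.e2 / params.e1) ** (1.0 / gap)
    return DerivedMarkers(e_sum=params.e_sum, tau=params.eta / params.e1, f_t=float(f_t))


def local_loglog_slope(curve: CreepCurve, window: int = 9) -> np.ndarray:
    """Sliding-window slope of log(value) against log(time).

    Centred linear regressions of width ``window`` (odd, >= 3); edge points
    use truncated windows so the short-time exponent is readable at t_min.
    Output has the same length as the curve.
    """
    if window < 3 or window % 2 == 0:
        raise RheologyError("window must be odd and >= 3")
    x = np.log(curve.times)
    y = np.log(curve.values)
    half = window // 2
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        xs = x[lo:hi] - x[lo:hi].mean()
        out[i] = xs @ y[lo:hi] / (xs @ xs)
    return out
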