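"""Synthetic cohorts of simulated AFM creep measurements.

The generator stands in for a mouse liver AFM study that is not publicly
deposited.  Three groups — healthy (status 0), drug-treated fibrotic
(status 1) and diseased fibrotic (status 2) — each contribute 800
measurements by default.  Group calibration reproduces the reported
statistics: mean total modulus Esum of 456.1 U (healthy) and 681.4 U
(treated), a diseased mean of five times healthy, short-time exponents
inside (0.5, 1.0) and long-time exponents near 0.2.  Spreads (log-normal
moduli with a common cytoplasm factor, truncated-normal exponents) and the
3% multiplicative measurement noise are calibration choices documented in
docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .rheology import (
    PAPER_UNIT_PA,
    CreepCurve,
    IndentationProtocol,
    ViscoParams,
    creep_compliance,
    derived_markers,
    hertz_indentation,
)

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "CohortDataset",
    "STATUS_NAMES",
    "default_group_specs",
    "sample_group_params",
    "simulate_measurement",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

STATUS_NAMES = {0: "healthy", 1: "treated", 2: "diseased"}

#: ground-truth marker columns carried by every cohort
MARKER_COLUMNS = [
    "E1",
    "E2",
    "E3",
    "Esum",
    "eta",
    "tau",
    "fT",
    "alphaL",
    "alphaR",
]


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distribution of one tissue group.

    Moduli are log-normal: ``E1 ~ LogNormal`` with arithmetic mean
    ``mean_e1`` and coefficient of variation ``cov_e1``; E2 and E3 are E1
    times log-normal ratios (so the within-group moduli are strongly
    positively correlated, as in fibrotic stiffening where all structural
    levels stiffen together).  Exponents are truncated normal with per-draw
    rejection until ``alpha_l > alpha_r + 0.1``.
    """

    status: int
    mean_e1: float
    mean_e2_ratio: float
    mean_e3_ratio: float
    cov_e1: float
    cov_ratios: float
    mean_eta: float
    cov_eta: float
    mean_alpha_l: float
    sd_alpha_l: float
    mean_alpha_r: float
    sd_alpha_r: float
    n: int = 800

    ALPHA_L_BOUNDS = (0.5, 1.0)
    ALPHA_R_BOUNDS = (0.10, 0.35)

    def __post_init__(self) -> None:
        if self.status not in STATUS_NAMES:
            raise CohortConfigError(f"status must be one of {sorted(STATUS_NAMES)}")
        if min(self.mean_e1, self.mean_e2_ratio, self.mean_e3_ratio, self.mean_eta) <= 0:
            raise CohortConfigError("moduli means and ratios must be positive")
        if self.n < 0:
            raise CohortConfigError("n must be non-negative")
        lo, hi = self.ALPHA_L_BOUNDS
        if not (lo < self.mean_alpha_l < hi):
            raise CohortConfigError(f"mean_alpha_l must lie inside {self.ALPHA_L_BOUNDS}")
        lo, hi = self.ALPHA_R_BOUNDS
        if not (lo < self.mean_alpha_r < hi):
            raise CohortConfigError(f"mean_alpha_r must lie inside {self.ALPHA_R_BOUNDS}")

    @property
    def mean_e_sum(self) -> float:
        return self.mean_e1 * (1.0 + self.mean_e2_ratio + self.mean_e3_ratio)


def default_group_specs() -> tuple[GroupSpec, GroupSpec, GroupSpec]:
    """Default three-group calibration (paper units U).

    Healthy Esum mean 456.1 U; treated moduli scaled by 1.494 (681.4 U);
    diseased scaled by 5.0 (2280.5 U).  Exponent means 0.85 / 0.72 / 0.55
    (alphaL) and 0.20 / 0.21 / 0.22 (alphaR, weakly informative).
    """
    common = dict(
        mean_e2_ratio=2.0,
        mean_e3_ratio=1.561,
        cov_e1=0.39,
        cov_ratios=0.10,
        cov_eta=0.40,
        sd_alpha_l=0.05,
        sd_alpha_r=0.025,
    )
    healthy = GroupSpec(
        status=0, mean_e1=100.0, mean_eta=50.0,
        mean_alpha_l=0.85, mean_alpha_r=0.20, **common,
    )
    treated = GroupSpec(
        status=1, mean_e1=149.4, mean_eta=70.0,
        mean_alpha_l=0.72, mean_alpha_r=0.21, **common,
    )
    diseased = GroupSpec(
        status=2, mean_e1=500.0, mean_eta=250.0,
        mean_alpha_l=0.55, mean_alpha_r=0.22, **common,
    )
    return healthy, treated, diseased


@dataclass(frozen=True)
class CohortConfig:
    group_specs: tuple[GroupSpec, ...] = field(default_factory=default_group_specs)
    protocol: IndentationProtocol = field(default_factory=IndentationProtocol)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        statuses = [g.status for g in self.group_specs]
        if len(set(statuses)) != len(statuses):
            raise CohortConfigError("duplicate status codes in group specs")
        if not (0.0 <= self.noise_sd <= 0.2):
            raise CohortConfigError("noise_sd must lie in [0, 0.2]")


@dataclass(frozen=True)
class CohortDataset:
    """Labelled simulated measurements plus their ground-truth markers.

    ``measurements`` maps measurement_id -> indentation CreepCurve (SI);
    ``ground_truth`` is one row per measurement with the nine markers and
    the status code.
    """

    config: CohortConfig
    measurements: dict[str, CreepCurve]
    ground_truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.measurements)


def _lognormal(rng: np.random.Generator, mean: float, cov: float, n: int) -> np.ndarray:
    """Log-normal draws with given arithmetic mean and coefficient of variation."""
    if cov == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cov**2)
    return rng.lognormal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2), n)


def sample_group_params(spec: GroupSpec, rng: np.random.Generator) -> list[ViscoParams]:
    """Draw ``spec.n`` ground-truth parameter sets for one group."""
    lo_l, hi_l = GroupSpec.ALPHA_L_BOUNDS
    lo_r, hi_r = GroupSpec.ALPHA_R_BOUNDS
    if spec.mean_alpha_l <= spec.mean_alpha_r + 0.1:
        raise CohortConfigError(
            "mean exponents leave no room for the alpha_l > alpha_r + 0.1 constraint"
        )
    n = spec.n
    e1 = _lognormal(rng, spec.mean_e1, spec.cov_e1, n)
    e2 = e1 * _lognormal(rng, spec.mean_e2_ratio, spec.cov_ratios, n)
    e3 = e1 * _lognormal(rng, spec.mean_e3_ratio, spec.cov_ratios, n)
    eta = _lognormal(rng, spec.mean_eta, spec.cov_eta, n)
    alpha_l = np.empty(n)
    alpha_r = np.empty(n)
    for i in range(n):
        for _ in range(10_000):
            a = rng.normal(spec.mean_alpha_l, spec.sd_alpha_l)
            b = rng.normal(spec.mean_alpha_r, spec.sd_alpha_r)
            if lo_l < a < hi_l and lo_r < b < hi_r and a > b + 0.1:
                alpha_l[i], alpha_r[i] = a, b
                break
        else:  # pragma: no cover - unreachable with valid specs
            raise CohortConfigError("exponent truncation failed to converge")
    return [
        ViscoParams(e1[i], e2[i], e3[i], eta[i], alpha_l[i], alpha_r[i])
        for i in range(n)
    ]


def simulate_measurement(
    params: ViscoParams,
    protocol: IndentationProtocol,
    noise_sd: float,
    rng: np.random.Generator,
) -> CreepCurve:
    """One noisy AFM indentation record (SI units).

    The noiseless depth is the Hertz inverse of the model compliance; the
    observation is multiplied pointwise by ``exp(eps)``,
    ``eps ~ N(0, noise_sd)``.  No monotone enforcement: downstream fitting
    must tolerate local dips.
    """
    if not (0.0 <= noise_sd <= 0.2):
        raise CohortConfigError("noise_sd must lie in [0, 0.2]")
    j_u = creep_compliance(params, protocol.time_grid())
    j_si = j_u.with_values(j_u.values / PAPER_UNIT_PA)
    depth = hertz_indentation(j_si, protocol)
    if noise_sd > 0:
        noisy = depth.values * np.exp(rng.normal(0.0, noise_sd, depth.values.size))
        depth = depth.with_values(noisy)
    return depth


def _truth_row(params: ViscoParams) -> dict[str, float]:
    d = derived_markers(params)
    return dict(
        E1=params.e1, E2=params.e2, E3=params.e3, Esum=d.e_sum,
        eta=params.eta, tau=d.tau, fT=d.f_t,
        alphaL=params.alpha_l, alphaR=params.alpha_r,
    )


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Simulate the full labelled cohort; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    measurements: dict[str, CreepCurve] = {}
    rows = []
    for spec in config.group_specs:
        params_list = sample_group_params(spec, rng)
        for i, params in enumerate(params_list):
            mid = f"{STATUS_NAMES[spec.status]}_{i:04d}"
            curve = simulate_measurement(params, config.protocol, config.noise_sd, rng)
            measurements[mid] = replace(curve, meta={"measurement_id": mid, "status": spec.status})
            rows.append({"measurement_id": mid, "status": spec.status, **_truth_row(params)})
    ground_truth = pd.DataFrame(rows, columns=["measurement_id", "status", *MARKER_COLUMNS])
    return CohortDataset(config=config, measurements=measurements, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# on-disk layout: measurements/<id>.csv + ground_truth.csv + cohort_manifest.json


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    mdir = out / "measurements"
    mdir.mkdir(parents=True, exist_ok=True)
    proto = dataset.config.protocol
    for mid, curve in dataset.measurements.items():
        with open(mdir / f"{mid}.csv", "w") as fh:
            fh.write(f"# measurement_id: {mid}\n")
            fh.write(f"# status: {curve.meta.get('status')}\n")
            fh.write(f"# force_N: {proto.force!r}\n")
            fh.write(f"# probe_radius_m: {proto.probe_radius!r}\n")
            fh.write(f"# poisson: {proto.poisson!r}\n")
            fh.write("time_s,indentation_m\n")
            for t, v in zip(curve.times, curve.values):
                fh.write(f"{float(t)!r},{float(v)!r}\n")
    dataset.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    manifest = {
        "n_measurements": len(dataset),
        "noise_sd": dataset.config.noise_sd,
        "seed": dataset.config.seed,
        "protocol": {
            "force": proto.force,
            "probe_radius": proto.probe_radius,
            "poisson": proto.poisson,
            "hold_time": proto.hold_time,
            "n_points": proto.n_points,
            "t_min": proto.t_min,
        },
        "groups": [
            {"status": g.status, "name": STATUS_NAMES[g.status], "n": g.n}
            for g in dataset.config.group_specs
        ],
    }
    (out / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_cohort(in_dir: str | Path) -> tuple[dict[str, CreepCurve], pd.DataFrame, IndentationProtocol]:
    """Load measurements, ground truth and protocol written by write_cohort."""
    src = Path(in_dir)
    manifest = json.loads((src / "cohort_manifest.json").read_text())
    protocol = IndentationProtocol(**manifest["protocol"])
    ground_truth = pd.read_csv(src / "ground_truth.csv")
    measurements: dict[str, CreepCurve] = {}
    for path in sorted((src / "measurements").glob("*.csv")):
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for k, line in enumerate(lines):
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                body_start = k
                break
        data = np.loadtxt(lines[body_start + 1:], delimiter=",")
        mid = meta.get("measurement_id", path.stem)
        meta["status"] = int(meta.get("status", -1))
        measurements[mid] = CreepCurve(
            times=data[:, 0], values=data[:, 1], kind="indentation", meta=meta
        )
    return measurements, ground_truth, protocol
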