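"""Cohort simulation and the Monte Carlo evaluation of ML vs MAP.

Lifespans are drawn by inverse-transform sampling from the marginal
gamma-Gompertz (or Gompertz) distribution, starting at model age 0 and
following the cohort to extinction.  Each simulated cohort is aggregated
into a life table of death counts and exact person-years, fitted by ML
and/or MAP, and the replicate estimates summarised into per-parameter
bias and standard deviation plus pooled deceleration-detection error
rates:

* type I  - share of replicates with Gompertz truth (sigma2 = 0) in which
  a method detects deceleration;
* type II - share of replicates with gamma-Gompertz truth (sigma2 > 0) in
  which it does not.

Reproducibility: the master seed is split into one independent
``numpy.random.SeedSequence`` child per (scenario, replicate), and each
child is split again into streams for lifespan sampling and for the two
optimiser runs, so the whole study is bit-reproducible and insensitive to
the order in which scenarios are run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import PARAM_NAMES, detect_deceleration, fit
from .likelihood import LifeTable, PenaltyConfig
from .models import ThetaGG, gg_quantile

__all__ = [
    "Scenario",
    "MCStudyResult",
    "sample_lifespans",
    "build_life_table",
    "run_mc_study",
    "error_rates",
    "heterogeneity_design",
    "no_heterogeneity_design",
    "default_design",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scenario:
    """One Monte Carlo condition: true parameters and cohort size."""

    theta_true: ThetaGG
    n: int = 10_000
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("cohort size must be at least 10")
        if not self.label:
            t = self.theta_true
            object.__setattr__(
                self, "label", f"a={t.a:g},b={t.b:g},s2={t.sigma2:g}"
            )


def heterogeneity_design(n: int = 10_000) -> list:
    """The 2x2x2 crossing of levels, aging rates and frailty variances."""
    return [
        Scenario(ThetaGG(a, b, s2), n=n)
        for a in (0.0001, 0.00001)
        for b in (0.1, 0.15)
        for s2 in (0.2, 0.8)
    ]


def no_heterogeneity_design(n: int = 10_000) -> list:
    """The 3x3 Gompertz (sigma2 = 0) crossing of levels and aging rates."""
    return [
        Scenario(ThetaGG(a, b, 0.0), n=n)
        for a in (0.0001, 0.0003, 0.0005)
        for b in (0.09, 0.10, 0.11)
    ]


def default_design(n: int = 10_000) -> list:
    """All 17 scenarios: 8 with heterogeneity, 9 without."""
    return heterogeneity_design(n) + no_heterogeneity_design(n)


def sample_lifespans(n: int, theta_true: ThetaGG, rng_seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. ages at death by inverse-transform sampling.

    ``rng_seed`` may be an int, a ``SeedSequence`` or a ``Generator``.
    The uniforms are mapped through the analytic survival quantile, so the
    draws follow the marginal gamma-Gompertz distribution exactly (the
    Gompertz branch applies when sigma2 = 0).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(rng_seed)
    u = 1.0 - rng.random(n)  # in (0, 1]; u = 1 maps to age 0
    u = np.minimum(u, 1.0 - 1e-16)
    return gg_quantile(u, theta_true)


def build_life_table(lifespans, start_age: int = 0) -> LifeTable:
    """Aggregate exact ages at death into a one-year life table.

    ``D_x`` counts deaths in [x, x+1); ``E_x`` is the exact person-years
    lived in the interval (an individual dying at age T contributes
    ``min(T, x+1) - x`` for every x < T).  The cohort is followed to
    extinction, so sum(D) equals the cohort size and sum(E) equals total
    lifespan.  ``start_age`` only labels the table's first interval.
    """
    T = np.asarray(lifespans, dtype=float)
    if T.size == 0:
        raise ValueError("no lifespans given")
    if np.any(T < 0) or not np.all(np.isfinite(T)):
        raise ValueError("lifespans must be finite and non-negative")
    k = np.floor(T).astype(np.int64)
    m = int(k.max())
    n_ages = max(m + 1, 2)
    D = np.bincount(k, minlength=n_ages).astype(float)
    frac = np.bincount(k, weights=T - k, minlength=n_ages)
    # survivors past the end of each interval: those dying in later intervals
    alive_past = np.concatenate([np.cumsum(D[::-1])[::-1][1:], [0.0]])
    E = alive_past + frac
    return LifeTable(D=D, E=E, start_age=start_age)


@dataclass
class MCStudyResult:
    """Replicate-level estimates and their summaries for one MC study.

    ``estimates`` holds one row per (scenario, method, replicate) with the
    fitted parameters and the detection decision; ``summary`` one row per
    (scenario, method, parameter) with bias and standard deviation.
    """

    estimates: pd.DataFrame
    summary: pd.DataFrame
    reps: int
    seed: int | None
    n_failed: int = 0

    def scenario_labels(self) -> list:
        return list(self.estimates["scenario"].unique())


def run_mc_study(
    scenarios,
    reps: int,
    methods=("ML", "MAP"),
    cfg: PenaltyConfig | None = None,
    seed=None,
    age_offset: float = 0.0,
    compute_se: str | bool = "auto",
    progress: bool = False,
) -> MCStudyResult:
    """Monte Carlo study: simulate, fit, and summarise bias/SD and errors.

    For every scenario and replicate a cohort is sampled, aggregated into
    a life table and fitted by each requested method.  Standard errors are
    needed only for the ML detection rule; ``compute_se='auto'`` computes
    them for ML fits and skips them for MAP fits to save time.

    Replicates whose fit raises are dropped from the summaries and counted
    in ``n_failed``.
    """
    cfg = cfg if cfg is not None else PenaltyConfig()
    scenarios = list(scenarios)
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(scenarios) * reps)

    rows = []
    n_failed = 0
    for i, sc in enumerate(scenarios):
        for j in range(reps):
            child = children[i * reps + j]
            sim_ss, *fit_ss = child.spawn(1 + len(methods))
            lifespans = sample_lifespans(sc.n, sc.theta_true, sim_ss)
            lt = build_life_table(lifespans)
            for method, fss in zip(methods, fit_ss):
                want_se = (
                    compute_se if isinstance(compute_se, bool)
                    else method.upper() == "ML"
                )
                try:
                    fr = fit(
                        lt,
                        method=method,
                        cfg=cfg,
                        seed=np.random.default_rng(fss),
                        age_offset=age_offset,
                        compute_se=want_se,
                    )
                except Exception:  # noqa: BLE001 - replicate-level robustness
                    logger.warning(
                        "fit failed: scenario %s, method %s, rep %d",
                        sc.label, method, j,
                    )
                    n_failed += 1
                    continue
                rows.append(
                    {
                        "scenario": sc.label,
                        "sigma2_true": sc.theta_true.sigma2,
                        "n": sc.n,
                        "method": fr.method,
                        "rep": j,
                        "a": fr.theta_hat.a,
                        "b": fr.theta_hat.b,
                        "sigma2": fr.theta_hat.sigma2,
                        "sigma2_raw": fr.sigma2_raw,
                        "detected": detect_deceleration(fr) == "deceleration",
                        "converged": fr.converged,
                        "a_true": sc.theta_true.a,
                        "b_true": sc.theta_true.b,
                    }
                )
        if progress:
            logger.info("scenario %s done (%d/%d)", sc.label, i + 1, len(scenarios))

    estimates = pd.DataFrame(rows)
    summary = _summarise(estimates, reps, seed)
    return MCStudyResult(
        estimates=estimates, summary=summary, reps=reps,
        seed=None if seed is None else int(seed), n_failed=n_failed,
    )


def _summarise(estimates: pd.DataFrame, reps: int, seed) -> pd.DataFrame:
    rows = []
    truth = {"a": "a_true", "b": "b_true", "sigma2": "sigma2_true"}
    for (scenario, method), grp in estimates.groupby(["scenario", "method"], sort=False):
        for p in PARAM_NAMES:
            err = grp[p] - grp[truth[p]]
            rows.append(
                {
                    "scenario": scenario,
                    "method": method,
                    "parameter": p,
                    "truth": float(grp[truth[p]].iloc[0]),
                    "bias": float(err.mean()),
                    "sd": float(grp[p].std(ddof=1)),
                    "reps": int(len(grp)),
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def error_rates(study: MCStudyResult, method: str = "MAP") -> dict:
    """Pooled detection error rates for one method.

    type_I pools all replicates with sigma2 = 0 truth; type_II all with
    sigma2 > 0 truth.  A missing truth class yields ``None`` for the
    corresponding rate (undefined, not zero).
    """
    est = study.estimates
    est = est[est["method"] == method.upper()]
    null = est[est["sigma2_true"] == 0]
    alt = est[est["sigma2_true"] > 0]
    return {
        "type_I": None if null.empty else float(null["detected"].mean()),
        "type_II": None if alt.empty else float((~alt["detected"]).mean()),
    }


def study_report(study: MCStudyResult) -> str:
    """Plain-text bias/SD table in the layout of the simulation summaries."""
    lines = []
    for (scenario, method), grp in study.summary.groupby(
        ["scenario", "method"], sort=False
    ):
        cells = "  ".join(
            f"{row.parameter}: bias={row.bias:+.6f} sd={row.sd:.6f}"
            for row in grp.itertuples()
        )
        lines.append(f"{scenario:<28s} {method:<4s} {cells}")
    for method in study.estimates["method"].unique():
        er = error_rates(study, method)
        lines.append(
            f"{method}: type I = {er['type_I']}, type II = {er['type_II']}"
        )
    lines.append(f"reps = {study.reps}, seed = {study.seed}, failed = {study.n_failed}")
    return "\n".join(lines)
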