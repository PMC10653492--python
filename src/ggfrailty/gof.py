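"""Goodness of fit on the log-rate scale and ML-vs-MAP comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import FitResult, fit
from .likelihood import LifeTable, PenaltyConfig
from .models import ThetaGG, gg_marginal_hazard

__all__ = ["mse", "FitComparison", "compare"]


def mse(lt: LifeTable, theta: ThetaGG, age_offset: float = 0.0) -> float:
    """Mean squared error between log observed and log fitted death rates.

    MSE = (1/n) sum_x (ln m_x - ln mubar(x; theta))^2 over the n ages with
    both deaths and exposure; ``age_offset`` must match the one used when
    fitting so the model is evaluated at the same age points.
    """
    keep = (lt.D > 0) & (lt.E > 0)
    if not np.any(keep):
        raise ValueError("no age has both deaths and exposure")
    x = (lt.ages + age_offset)[keep]
    m_x = lt.D[keep] / lt.E[keep]
    mu = np.asarray(gg_marginal_hazard(x, theta))
    resid = np.log(m_x) - np.log(mu)
    return float(np.mean(resid**2))


@dataclass
class FitComparison:
    """ML vs MAP on one dataset, ranked by goodness of fit."""

    dataset: str
    ml: FitResult
    map: FitResult
    mse_ml: float
    mse_map: float

    @property
    def winner(self) -> str:
        return "MAP" if self.mse_map < self.mse_ml else "ML"


def compare(
    lt: LifeTable,
    cfg: PenaltyConfig | None = None,
    seed=None,
    age_offset: float = 0.0,
    dataset: str = "",
    **fit_kwargs,
) -> FitComparison:
    """Fit a life table by both ML and MAP and compare their MSEs."""
    cfg = cfg if cfg is not None else PenaltyConfig()
    ml = fit(lt, "ML", cfg=cfg, seed=seed, age_offset=age_offset, **fit_kwargs)
    mp = fit(lt, "MAP", cfg=cfg, seed=seed, age_offset=age_offset, **fit_kwargs)
    return FitComparison(
        dataset=dataset,
        ml=ml,
        map=mp,
        mse_ml=mse(lt, ml.theta_hat, age_offset),
        mse_map=mse(lt, mp.theta_hat, age_offset),
    )
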