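"""Posterior/estimate summaries, density conversions and model ranking.

Pack density (packs per 100 km²) converts to total density by multiplying
with mean pack size; the detection scale sigma converts to a home-range
summary via the radius enclosing a given probability mass of the
activity-centre-relative space use implied by the detection kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2


@dataclass
class DensityEstimate:
    """A pack-density estimate with uncertainty and provenance."""

    packs_per_100km2: float
    sd: float
    ci95: tuple
    estimator: str  # "bayes" | "ml"
    model: str  # e.g. "HN_NULL"
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.packs_per_100km2 <= 0:
            raise ValueError("density must be positive")
        lo, hi = self.ci95
        if not (lo <= self.packs_per_100km2 <= hi):
            raise ValueError("interval must contain the estimate")


def hpd_interval(samples: np.ndarray, level: float = 0.95) -> tuple:
    """Highest-posterior-density interval: the shortest window containing
    the requested mass (sorted-window method)."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples for an HPD interval")
    m = max(int(math.ceil(level * n)), 2)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def wolves_per_100km2(pack_density: float, mean_pack_size: float) -> float:
    """Total density = pack density x mean pack size (point conversion)."""
    if pack_density <= 0 or mean_pack_size <= 0:
        raise ValueError("pack density and mean pack size must be positive")
    return pack_density * mean_pack_size


def range_radius(sigma: float, detfn: str = "HN", mass: float = 0.95) -> float:
    """Radius (metres) enclosing ``mass`` of the space-use distribution
    implied by the detection kernel around the activity centre.

    HN: the radial displacement is bivariate normal, so
    r = sigma * sqrt(chi2_2 quantile) (2.4477 sigma at 95%).  NE: r solves
    the bivariate-exponential mass equation 1-exp(-r/s)(1+r/s) = mass.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (0 <= mass < 1):
        raise ValueError("mass must be in [0, 1)")
    if mass == 0:
        return 0.0
    if detfn == "HN":
        return sigma * math.sqrt(chi2.ppf(mass, df=2))
    if detfn == "NE":
        f = lambda r: 1.0 - math.exp(-r / sigma) * (1.0 + r / sigma) - mass
        return brentq(f, 0.0, 1000.0 * sigma)
    raise ValueError("detfn must be 'HN' or 'NE'")


def use_area(radius_m: float) -> float:
    """Area (km²) of the circle with the given radius in metres."""
    if radius_m < 0:
        raise ValueError("radius must be non-negative")
    return math.pi * radius_m**2 / 1e6


@dataclass
class FitRecord:
    """One fitted model's entry in a cross-model comparison."""

    session_id: str
    model: str  # e.g. "HN_NULL"
    estimator: str  # "bayes" | "ml"
    density: float
    density_sd: float
    ci95: tuple
    k_params: int
    bayes_p: Optional[float] = None
    aicc: Optional[float] = None
    trap_decision: Optional[object] = None


def record_from_ml(fit, session_id: Optional[str] = None) -> FitRecord:
    """Build a comparison record from an :class:`~packscr.scr_likelihood.MLFit`."""
    return FitRecord(
        session_id=session_id if session_id is not None else fit.session_id,
        model=fit.spec.name,
        estimator="ml",
        density=fit.D_hat,
        density_sd=fit.se["D"],
        ci95=fit.ci95["D"],
        k_params=1 + fit.spec.n_detection_params,
        aicc=fit.aicc,
    )


def record_from_chain(chain, bayes_p: float,
                      session_id: Optional[str] = None,
                      trap_decision=None) -> FitRecord:
    """Build a comparison record from a posterior chain and its Bayes p."""
    return FitRecord(
        session_id=session_id if session_id is not None else chain.session_id,
        model=chain.spec.name,
        estimator="bayes",
        density=float(np.mean(chain.D)),
        density_sd=float(np.std(chain.D, ddof=1)),
        ci95=hpd_interval(chain.D, 0.95),
        k_params=1 + chain.spec.n_detection_params,
        bayes_p=bayes_p,
        trap_decision=trap_decision,
    )


def model_report(fits: Sequence[FitRecord]) -> pd.DataFrame:
    """Rank fitted models: Bayesian fits by |Bayes p - 0.5|, ML fits by
    AICc (ties broken by fewer parameters); one session per report."""
    if len(fits) == 0:
        raise ValueError("no fits to rank")
    sessions = {f.session_id for f in fits}
    if len(sessions) > 1:
        raise ValueError(f"mixed sessions in one ranking: {sorted(sessions)}")
    rows = []
    for f in fits:
        if f.estimator == "bayes":
            if f.bayes_p is None:
                raise ValueError(f"bayes fit {f.model} lacks a Bayes p-value")
            key = abs(f.bayes_p - 0.5)
        else:
            if f.aicc is None:
                raise ValueError(f"ml fit {f.model} lacks an AICc")
            key = f.aicc
        rows.append(
            {
                "session": f.session_id,
                "estimator": f.estimator,
                "model": f.model,
                "density": f.density,
                "sd": f.density_sd,
                "ci95_low": f.ci95[0],
                "ci95_high": f.ci95[1],
                "bayes_p": f.bayes_p,
                "aicc": f.aicc,
                "rank_key": key,
                "k_params": f.k_params,
                "trap_response_recommended": (
                    getattr(f.trap_decision, "recommended", None)
                ),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["estimator", "rank_key", "k_params"],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = df.groupby("estimator")["rank_key"].rank(method="first").astype(int)
    return df
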