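"""Synthetic patient cohorts with prescribed group-conditional moments.

Each continuous feature is drawn from a zero-truncated normal whose
underlying parameters are moment-matched so that the *truncated*
distribution reproduces the requested group mean and SD exactly.  By
default the per-group moments are the published cohort summary
statistics (events-positive n=34 vs events-negative n=262, prevalence
34/296); features are independent unless a correlation matrix is
supplied, in which case a Gaussian copula is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CohortSpec",
    "TABLE_DEFAULTS",
    "FEATURE_COLUMNS",
    "CONTINUOUS_COLUMNS",
    "simulate_cohort",
]

# Column labels follow the published summary table (scaled units).
CONTINUOUS_COLUMNS = [
    "Age (year)",
    "MPA inlet CSA (100 mm2)",
    "MPA outlet CSA (100 mm2)",
    "RPA inlet CSA (100 mm2)",
    "LPA inlet CSA (100 mm2)",
    "MPA inlet hydraulic diameter (10 mm)",
    "MPA outlet hydraulic diameter (10 mm)",
    "RPA inlet hydraulic diameter (10 mm)",
    "LPA inlet hydraulic diameter (10 mm)",
    "MPA inlet maximal diameter (10 mm)",
    "MPA outlet maximal diameter (10 mm)",
    "RPA inlet maximal diameter (10 mm)",
    "LPA inlet maximal diameter (10 mm)",
    "MPA bifurcation area (100 mm2)",
    "MPA bifurcation angle (deg)",
    "MPA bifurcation volume (1000 mm3)",
]

FEATURE_COLUMNS = CONTINUOUS_COLUMNS + ["Sex", "MPA dilation"]

#: (mean+, sd+, mean-, sd-) per continuous feature — events (+) vs (-)
TABLE_DEFAULTS: Dict[str, Tuple[float, float, float, float]] = {
    "Age (year)": (59.32, 13.71, 60.71, 14.57),
    "MPA inlet CSA (100 mm2)": (10.43, 2.66, 7.67, 2.15),
    "MPA outlet CSA (100 mm2)": (11.98, 3.00, 8.39, 2.22),
    "RPA inlet CSA (100 mm2)": (6.95, 2.89, 4.98, 1.56),
    "LPA inlet CSA (100 mm2)": (6.71, 3.28, 4.71, 1.41),
    "MPA inlet hydraulic diameter (10 mm)": (3.28, 0.42, 2.81, 0.39),
    "MPA outlet hydraulic diameter (10 mm)": (3.50, 0.41, 2.92, 0.42),
    "RPA inlet hydraulic diameter (10 mm)": (2.60, 0.38, 2.26, 0.35),
    "LPA inlet hydraulic diameter (10 mm)": (2.39, 0.38, 2.19, 0.32),
    "MPA inlet maximal diameter (10 mm)": (2.90, 0.41, 2.78, 0.37),
    "MPA outlet maximal diameter (10 mm)": (3.24, 0.53, 3.06, 0.44),
    "RPA inlet maximal diameter (10 mm)": (2.23, 0.38, 2.15, 0.37),
    "LPA inlet maximal diameter (10 mm)": (2.15, 0.43, 2.07, 0.38),
    "MPA bifurcation area (100 mm2)": (1.32, 0.95, 0.57, 0.31),
    "MPA bifurcation angle (deg)": (133.23, 37.04, 152.12, 22.15),
    "MPA bifurcation volume (1000 mm3)": (19.78, 8.43, 12.90, 5.58),
}

#: fraction of males per group (+, -)
MALE_RATE_BY_GROUP = (14 / 34, 118 / 262)
#: fraction with trunk dilation per group (+, -)
DILATION_RATE_BY_GROUP = (13 / 34, 31 / 262)

DEFAULT_PREVALENCE = 34 / 296


class CorrelationError(ValueError):
    """Supplied correlation matrix is not usable."""


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one simulated cohort draw."""

    n_total: int = 296
    prevalence: float = DEFAULT_PREVALENCE
    moments: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(TABLE_DEFAULTS)
    )
    correlation: Optional[np.ndarray] = None
    male_rate_by_group: Tuple[float, float] = MALE_RATE_BY_GROUP
    dilation_rate_by_group: Tuple[float, float] = DILATION_RATE_BY_GROUP
    split_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.prevalence < 1.0):
            raise ValueError("prevalence must lie in [0, 1)")
        if self.prevalence == 0.0:
            warnings.warn(
                "prevalence 0: all labels negative; group-difference "
                "tests are undefined for this cohort"
            )
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        for name, (m1, s1, m0, s0) in self.moments.items():
            if s1 < 0 or s0 < 0:
                raise ValueError(f"negative SD for {name!r}")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            p = len(self.moments)
            if corr.shape != (p, p):
                raise CorrelationError(
                    f"correlation matrix shape {corr.shape} does not match "
                    f"{p} features"
                )
            if not np.allclose(corr, corr.T, atol=1e-10):
                raise CorrelationError("correlation matrix is not symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
                raise CorrelationError("correlation matrix diagonal must be 1")
            if np.linalg.eigvalsh(corr).min() < -1e-8:
                raise CorrelationError(
                    "correlation matrix is not positive semi-definite"
                )


# ------------------------------------------------- truncated-normal match


@lru_cache(maxsize=4096)
def _match_truncated_moments(mean: float, sd: float) -> Tuple[float, float]:
    """Underlying (mu, sigma) whose zero-truncated normal has (mean, sd)."""
    if sd == 0.0:
        return mean, 0.0
    if mean / sd > 8.0:  # truncation numerically irrelevant
        return mean, sd

    def residual(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        alpha = -mu / sigma
        z = stats.norm.sf(alpha)
        lam = stats.norm.pdf(alpha) / z
        m = mu + sigma * lam
        var = sigma ** 2 * (1.0 + alpha * lam - lam ** 2)
        return [m - mean, np.sqrt(max(var, 1e-300)) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment match failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def _truncated_draw(rng, mu, sigma, size):
    if sigma == 0.0:
        return np.full(size, mu)
    alpha = -mu / sigma
    u = rng.uniform(stats.norm.cdf(alpha), 1.0, size=size)
    return mu + sigma * stats.norm.ppf(u)


# -------------------------------------------------------------- simulation


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table; deterministic given ``spec.seed``.

    Columns: the continuous features of :data:`CONTINUOUS_COLUMNS`,
    ``Sex`` ("male"/"female"), ``MPA dilation`` (0/1), ``event`` (0/1)
    and ``set`` ("training"/"validation").
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total

    n_pos = int(round(spec.prevalence * n))
    event = np.zeros(n, dtype=int)
    event[rng.permutation(n)[:n_pos]] = 1

    feat_names = list(spec.moments)
    data = {}

    if spec.correlation is not None:
        corr = np.asarray(spec.correlation, dtype=float)
        # Gaussian copula: correlated normal scores, truncnorm marginals
        try:
            chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr)))
        except np.linalg.LinAlgError as exc:
            raise CorrelationError(f"correlation matrix not factorisable: {exc}")
        zmat = rng.standard_normal((n, len(corr))) @ chol.T
        umat = stats.norm.cdf(zmat)
    else:
        umat = rng.uniform(size=(n, len(feat_names)))

    for j, name in enumerate(feat_names):
        m1, s1, m0, s0 = spec.moments[name]
        col = np.empty(n)
        for grp, (m, s) in ((1, (m1, s1)), (0, (m0, s0))):
            mask = event == grp
            if not mask.any():
                continue
            mu, sigma = _match_truncated_moments(m, s)
            if sigma == 0.0:
                col[mask] = mu
                continue
            alpha = -mu / sigma
            lo = stats.norm.cdf(alpha)
            u = lo + (1.0 - lo) * umat[mask, j]
            col[mask] = mu + sigma * stats.norm.ppf(u)
        data[name] = col

    male = np.empty(n, dtype=int)
    dilated = np.empty(n, dtype=int)
    for grp, pm, pd_ in (
        (1, spec.male_rate_by_group[0], spec.dilation_rate_by_group[0]),
        (0, spec.male_rate_by_group[1], spec.dilation_rate_by_group[1]),
    ):
        mask = event == grp
        k = int(mask.sum())
        male[mask] = rng.uniform(size=k) < pm
        dilated[mask] = rng.uniform(size=k) < pd_

    n_train = int(round(spec.split_fraction * n))
    assign = np.array(["validation"] * n, dtype=object)
    assign[rng.permutation(n)[:n_train]] = "training"

    frame = pd.DataFrame(data)
    frame["Sex"] = np.where(male == 1, "male", "female")
    frame["MPA dilation"] = dilated
    frame["event"] = event
    frame["set"] = assign
    return frame
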