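"""Critical-age detection and cross-species pooling.

Within a stage, the age profile of the selection gradient on mortality
may first rise with age (a *contra-senescent* phase, impossible in
purely age-classified demography) before declining (*pro-senescent*).
The critical age of a stage is the age class at which the gradient
magnitude peaks, separating the two phases. The final, open age class
(ages >= omega) is excluded from the search, and ties are broken toward
the earliest age, which is conservative against overstating
contra-senescence.

For comparison across species, critical ages are rescaled by the life
expectancy ``eta`` of the first non-seed stage; pooling stages across
species and smoothing ``log10`` of the scaled critical age with a
Gaussian kernel gives the cross-species distribution of how long
contra-senescent selection persists, in units of life expectancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gradients import GradientField
from .lifecourse import FundamentalMatrix

__all__ = ["critical_ages", "pool_critical_ages", "PooledCriticalAges"]

#: Gradient rows whose largest magnitude falls below this are reported
#: undefined rather than assigned a spurious critical age.
DEFINED_FLOOR = 1e-14


def critical_ages(
    field: GradientField,
    fund: FundamentalMatrix,
    stage_labels: tuple | None = None,
) -> pd.DataFrame:
    """Per-stage critical ages of the mortality gradient.

    Returns a DataFrame with one row per stage and columns:

    ``stage``
        1-based stage number.
    ``critical_age``
        Age class (1-based, in years for annual matrices) at which the
        mortality-gradient magnitude peaks, over age classes
        ``1..omega-1`` (open class excluded); NaN when undefined.
    ``critical_age_scaled``
        ``critical_age / eta_fnss``.
    ``has_contra_phase``
        True iff the peak occurs after the first age class.
    ``contra_duration``
        ``critical_age - 1``: years of increasing-gradient phase.
    ``critical_age_phi``
        Same statistic on the fertility gradient (supplementary).
    ``defined``
        False when the gradient row is identically ~0 (e.g. a stage
        with no survival), in which case the age columns are NaN.
    """
    if field.omega < 3:
        raise ValueError(
            f"omega = {field.omega} leaves no interior age classes to search; "
            "choose omega >= 3"
        )
    s = field.s
    eta_fnss = fund.eta_fnss
    interior = slice(0, field.omega - 1)  # exclude the open final class

    rows = []
    for j in range(s):
        row = {}
        for name, arr in (("", field.grad_mu), ("_phi", field.grad_phi)):
            prof = np.abs(arr[j, interior])
            if prof.max() < DEFINED_FLOOR:
                row[f"critical_age{name}"] = np.nan
            else:
                # np.argmax returns the first maximum: earliest age on ties
                row[f"critical_age{name}"] = int(np.argmax(prof)) + 1
        ca = row["critical_age"]
        rows.append({
            "stage": j + 1,
            "stage_label": stage_labels[j] if stage_labels else f"stage_{j + 1}",
            "critical_age": ca,
            "critical_age_scaled": ca / eta_fnss if np.isfinite(ca) else np.nan,
            "has_contra_phase": bool(np.isfinite(ca) and ca > 1),
            "contra_duration": ca - 1 if np.isfinite(ca) else np.nan,
            "critical_age_phi": row["critical_age_phi"],
            "eta_fnss": eta_fnss,
            "defined": bool(np.isfinite(ca)),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PooledCriticalAges:
    """Pooled scaled critical ages and their kernel density on log10 scale."""

    scaled_ages: np.ndarray  # pooled critical_age_scaled, all defined stages
    log10_sample: np.ndarray
    bandwidth: float  # KDE bandwidth on the log10 scale
    median: float  # of the unlogged scaled ages
    mean: float
    sd: float

    def density(self, x: np.ndarray) -> np.ndarray:
        """Gaussian KDE of ``log10(critical_age_scaled)`` evaluated at ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        diffs = (x[:, None] - self.log10_sample[None, :]) / self.bandwidth
        dens = np.exp(-0.5 * diffs**2).sum(axis=1)
        return dens / (self.log10_sample.size * self.bandwidth * np.sqrt(2 * np.pi))

    def density_table(self, n_grid: int = 200, pad: float = 1.0) -> pd.DataFrame:
        lo = self.log10_sample.min() - pad
        hi = self.log10_sample.max() + pad
        x = np.linspace(lo, hi, n_grid)
        return pd.DataFrame({"log10_scaled_age": x, "density": self.density(x)})


def pool_critical_ages(
    tables: list[pd.DataFrame], bandwidth: float | None = None
) -> PooledCriticalAges:
    """Pool critical-age tables (one per species, every defined stage).

    The density estimate is a Gaussian kernel smoother of the pooled
    ``log10(critical_age_scaled)`` sample with Silverman's rule-of-thumb
    bandwidth by default (a fixed fallback of 0.1 dex when the sample is
    a single point or has zero spread). Summary statistics (median,
    mean, sd) are reported on the unlogged scaled ages.
    """
    if not tables:
        raise ValueError("no critical-age tables to pool")
    vals = np.concatenate([
        t.loc[t["defined"], "critical_age_scaled"].to_numpy(dtype=float) for t in tables
    ])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("pooled critical-age sample is empty")
    if np.any(vals <= 0):
        raise ValueError("scaled critical ages must be positive")
    logs = np.log10(vals)
    spread = logs.std(ddof=1) if logs.size > 1 else 0.0
    if logs.size > 1 and spread > 0:
        bw_default = stats.gaussian_kde(logs, bw_method="silverman").factor * spread
    else:
        bw_default = 0.1
    bw = float(bandwidth) if bandwidth is not None else float(bw_default)
    return PooledCriticalAges(
        scaled_ages=vals,
        log10_sample=logs,
        bandwidth=bw,
        median=float(np.median(vals)),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
    )
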