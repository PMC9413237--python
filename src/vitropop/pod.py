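"""Points of departure (EC10) and the toxicodynamic variability factor.

The POD is the EC10 — the concentration producing a 10% drop from
baseline on the fitted downward Hill curve — obtained in closed form from
each MCMC draw of (EC50, n):

    EC10 = EC50 * (0.1/0.9)^(1/n)

A substance is called inactive when the population median EC10 exceeds
3x the maximum tested concentration (strict inequality).  Inter-individual
toxicodynamic variability is quantified as TDVF_05 = EC10 of the median
individual / EC10 of the 5th-percentile (most sensitive) individual,
computed across individuals separately within every MCMC sample so the
result is a full uncertainty distribution.  The regulatory half-log
default (10^1/2 = 3.16) and the combined default of 10 serve as
comparison benchmarks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hill import PosteriorSamples

__all__ = [
    "DEFAULT_TD_BENCHMARK",
    "DEFAULT_TOTAL_BENCHMARK",
    "ec10_from_params",
    "pod_table",
    "classify_activity",
    "ActivityCall",
    "tdvf05",
    "TDVFDistribution",
    "summarize_variability",
]

DEFAULT_TD_BENCHMARK = float(10 ** 0.5)   # half-log toxicodynamic default
DEFAULT_TOTAL_BENCHMARK = 10.0            # combined TK+TD default


def ec10_from_params(ec50, n):
    """Closed-form EC10 of the downward Hill curve.

    Since (1/9)^(1/n) < 1 for every n >= 1, the EC10 always lies below the
    EC50.  Vectorized; raises if any n < 1 or ec50 <= 0.
    """
    ec50 = np.asarray(ec50, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(ec50 <= 0):
        raise ValueError("ec50 must be > 0")
    if np.any(n < 1):
        raise ValueError("Hill coefficient must be >= 1")
    return ec50 * (1.0 / 9.0) ** (1.0 / n)


def pod_table(post: PosteriorSamples) -> pd.DataFrame:
    """Per-individual EC10 posterior summaries for one substance."""
    draws = ec10_draws(post)
    q = np.quantile(draws, [0.5, 0.025, 0.975], axis=0)
    return pd.DataFrame({
        "substance": post.substance,
        "cell_line_id": post.individuals,
        "ec10_median": q[0],
        "ec10_lo2p5": q[1],
        "ec10_hi97p5": q[2],
    })


def ec10_draws(post: PosteriorSamples) -> np.ndarray:
    """EC10 per MCMC draw, shape (n_total_draws, n_individuals)."""
    return ec10_from_params(post.individual_draws("ec50"),
                            post.individual_draws("n"))


def population_median_ec10(post: PosteriorSamples,
                           method: str = "posterior_median") -> float:
    """Population median EC10 for the activity rule.

    ``posterior_median`` (default): median across individuals of each
    individual's posterior-median EC10.  ``per_draw``: median across
    individuals within each draw, then the median over draws.
    """
    draws = ec10_draws(post)
    if method == "posterior_median":
        return float(np.median(np.median(draws, axis=0)))
    if method == "per_draw":
        return float(np.median(np.median(draws, axis=1)))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class ActivityCall:
    substance: str
    active: bool
    population_median_ec10: float
    max_concentration: float
    rule_factor: float = 3.0


def classify_activity(
    pod: PosteriorSamples | float,
    max_concentration: float,
    rule_factor: float = 3.0,
    method: str = "posterior_median",
    substance: str = "substance",
) -> ActivityCall:
    """Inactive iff population median EC10 > rule_factor x max tested
    concentration (strict inequality; at exactly the threshold the
    substance is still called active)."""
    if isinstance(pod, PosteriorSamples):
        med = population_median_ec10(pod, method=method)
        substance = pod.substance
    else:
        med = float(pod)
        if np.isnan(med):
            raise ValueError("empty POD table: no median EC10 available")
    return ActivityCall(
        substance=substance,
        active=not (med > rule_factor * max_concentration),
        population_median_ec10=med,
        max_concentration=float(max_concentration),
        rule_factor=rule_factor,
    )


@dataclass
class TDVFDistribution:
    substance: str
    samples: np.ndarray          # TDVF_05 per MCMC sample
    median: float
    ci05: float
    ci95: float
    exceeds_default_td: bool     # median > 10^(1/2)
    exceeds_default_total: bool  # median > 10
    n_individuals: int
    stability_warning: str = ""


def tdvf05(
    ec10: np.ndarray | PosteriorSamples,
    substance: str = "substance",
    sensitive_quantile: float = 0.05,
) -> TDVFDistribution:
    """TDVF_05 uncertainty distribution from aligned EC10 draws.

    ``ec10`` is (n_samples, n_individuals) — or a :class:`PosteriorSamples`
    from which EC10 draws are derived.  Within each MCMC sample the median
    and the ``sensitive_quantile`` (default 5th percentile, linear
    interpolation between order statistics) are taken across individuals;
    their ratio is that sample's TDVF_05.
    """
    if isinstance(ec10, PosteriorSamples):
        substance = ec10.substance
        ec10 = ec10_draws(ec10)
    ec10 = np.asarray(ec10, dtype=float)
    if ec10.ndim != 2:
        raise ValueError("ec10 draws must be 2-D (samples x individuals)")
    n_ind = ec10.shape[1]
    if n_ind < 2:
        raise ValueError("TDVF_05 needs >= 2 individuals")
    warn = ""
    if n_ind < 20:
        warn = (f"only {n_ind} individuals: the 5th-percentile individual "
                "is an extrapolation below the smallest order statistic")
        warnings.warn(warn, stacklevel=2)
    med = np.median(ec10, axis=1)
    p05 = np.quantile(ec10, sensitive_quantile, axis=1)
    tdvf = med / p05
    q = np.quantile(tdvf, [0.5, 0.05, 0.95])
    return TDVFDistribution(
        substance=substance, samples=tdvf,
        median=float(q[0]), ci05=float(q[1]), ci95=float(q[2]),
        exceeds_default_td=bool(q[0] > DEFAULT_TD_BENCHMARK),
        exceeds_default_total=bool(q[0] > DEFAULT_TOTAL_BENCHMARK),
        n_individuals=n_ind, stability_warning=warn)


def summarize_variability(
    pods: dict[str, float],
    tdvfs: dict[str, TDVFDistribution],
) -> dict:
    """Cross-substance summary: potency vs variability.

    ``pods`` maps substance -> population median EC10.  Returns summary
    stats and the Pearson correlation between log10 median EC10 and log10
    median TDVF_05 across substances (flagged invalid when degenerate).
    """
    common = sorted(set(pods) & set(tdvfs))
    if len(common) < 2:
        raise ValueError("need >= 2 substances with both POD and TDVF")
    ec10 = np.array([pods[s] for s in common])
    td = np.array([tdvfs[s].median for s in common])
    x, y = np.log10(ec10), np.log10(td)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        corr, pval, valid = np.nan, np.nan, False
    else:
        corr, pval = stats.pearsonr(x, y)
        valid = True
    table = pd.DataFrame({
        "substance": common,
        "median_ec10_uM": ec10,
        "tdvf05_median": td,
        "tdvf05_ci05": [tdvfs[s].ci05 for s in common],
        "tdvf05_ci95": [tdvfs[s].ci95 for s in common],
        "exceeds_3p16": [tdvfs[s].exceeds_default_td for s in common],
        "exceeds_10": [tdvfs[s].exceeds_default_total for s in common],
    })
    return dict(
        table=table,
        ec10_tdvf_correlation=float(corr) if valid else np.nan,
        correlation_p=float(pval) if valid else np.nan,
        correlation_valid=valid,
        median_tdvf=float(np.median(td)),
        tdvf_range=(float(td.min()), float(td.max())),
        ec10_range=(float(ec10.min()), float(ec10.max())),
    )
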