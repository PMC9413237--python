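"""Plate normalization, quality-control gates and reproducibility checks.

Raw luminescence in every experimental well is normalized to the mean of
the same plate's vehicle (0.5% DMSO) wells, so 1.0 is the vehicle level
and 0 is complete cytotoxicity.  A plate passes QC when the vehicle wells'
coefficient of variability is strictly below 20% and the 100 uM TAB
positive-control wells show complete kill (mean normalized response at or
below a small tolerance).  QC failure excludes the whole plate.
Reproducibility is summarized by Pearson correlations between replicate
response profiles (intra-plate duplicate chemicals, and a seeded random
pair of the replicate plates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCError",
    "CorrelationResult",
    "normalize_plates",
    "qc_plates",
    "filter_qc",
    "to_dose_response",
    "replicate_correlation",
    "interplate_correlations",
]


class QCError(ValueError):
    """Plate cannot be normalized or gated (e.g. no usable vehicle wells)."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    valid: bool
    reason: str = ""


def normalize_plates(plates: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_response`` = raw / same-plate vehicle mean.

    Stimulation above vehicle level (> 1) is allowed, not clipped.
    """
    out = plates.copy()
    veh = plates[plates["well_role"] == "vehicle"]
    if veh.empty:
        raise QCError("no vehicle wells present")
    means = veh.groupby("plate_id")["raw_luminescence"].mean()
    missing = set(plates["plate_id"]) - set(means.index)
    if missing:
        raise QCError(f"plates without vehicle wells: {sorted(missing)[:5]}")
    if (means <= 0).any():
        bad = means[means <= 0].index.tolist()
        raise QCError(f"non-positive vehicle mean on plates: {bad[:5]}")
    out["normalized_response"] = (
        out["raw_luminescence"].to_numpy()
        / means.reindex(out["plate_id"]).to_numpy())
    return out


def qc_plates(
    plates: pd.DataFrame,
    vehicle_cv_max: float = 20.0,
    positive_control_max: float = 0.05,
) -> pd.DataFrame:
    """Per-plate QC report: vehicle CV gate (strict < 20%) and
    positive-control complete-kill gate.

    The CV uses the sample (n-1) standard deviation of the raw vehicle
    counts; the positive-control criterion is the mean normalized response
    of the TAB wells <= ``positive_control_max``.
    """
    if "normalized_response" not in plates.columns:
        plates = normalize_plates(plates)
    rows = []
    for plate_id, grp in plates.groupby("plate_id", sort=True):
        veh = grp.loc[grp["well_role"] == "vehicle", "raw_luminescence"]
        pos = grp.loc[grp["well_role"] == "positive", "normalized_response"]
        reasons = []
        if len(veh) < 2:
            cv = np.nan
            reasons.append("vehicle CV undefined (<2 vehicle wells)")
        else:
            cv = 100.0 * veh.std(ddof=1) / veh.mean()
            if not cv < vehicle_cv_max:
                reasons.append(
                    f"vehicle CV {cv:.3g}% not < {vehicle_cv_max:g}%")
        if pos.empty:
            pos_mean = np.nan
            reasons.append("no positive-control wells")
        else:
            pos_mean = float(pos.mean())
            if pos_mean > positive_control_max:
                reasons.append("positive control incomplete kill "
                               f"(mean {pos_mean:.3g} > {positive_control_max:g})")
        rows.append(dict(plate_id=plate_id, vehicle_cv=cv,
                         positive_control_mean_response=pos_mean,
                         qc_pass=not reasons,
                         failure_reasons="; ".join(reasons)))
    return pd.DataFrame(rows)


def filter_qc(normalized: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    """Drop all wells of plates that failed QC (plate-level exclusion)."""
    passing = set(report.loc[report["qc_pass"], "plate_id"])
    return normalized[normalized["plate_id"].isin(passing)].copy()


def to_dose_response(normalized: pd.DataFrame) -> pd.DataFrame:
    """Long-format dose-response dataset consumed by the Bayesian fit.

    Treatment wells only; ``replicate`` numbers the plates within each
    (cell line, chemical) group in plate-id order.
    """
    t = normalized[normalized["well_role"] == "treatment"].copy()
    t["replicate"] = (
        t.groupby(["cell_line_id", "chemical_id"])["plate_id"]
        .transform(lambda s: pd.factorize(s, sort=True)[0] + 1))
    cols = ["cell_line_id", "chemical_id", "concentration_uM",
            "replicate", "normalized_response"]
    return t[cols].reset_index(drop=True)


def replicate_correlation(responses_a, responses_b) -> CorrelationResult:
    """Pearson r with two-sided p between paired response profiles.

    Zero variance in either vector makes r undefined; the result is
    flagged invalid rather than returned as a silent NaN.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(np.nan, np.nan, False,
                                 "zero variance in one of the vectors")
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(float(r), float(p), True)


def interplate_correlations(
    normalized: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Inter-plate reproducibility per (cell line, chemical).

    For each cell line and chemical with >= 2 replicate plates, two plates
    are chosen at random (seeded) and their treatment-well profiles,
    matched by concentration, are correlated.
    """
    rng = np.random.default_rng(seed)
    t = normalized[normalized["well_role"] == "treatment"]
    rows = []
    for (cid, chem), grp in t.groupby(["cell_line_id", "chemical_id"]):
        plate_ids = sorted(grp["plate_id"].unique())
        if len(plate_ids) < 2:
            continue
        pick = rng.choice(len(plate_ids), size=2, replace=False)
        pa, pb = plate_ids[pick[0]], plate_ids[pick[1]]
        a = (grp[grp["plate_id"] == pa]
             .sort_values("concentration_uM")["normalized_response"].to_numpy())
        b = (grp[grp["plate_id"] == pb]
             .sort_values("concentration_uM")["normalized_response"].to_numpy())
        k = min(a.size, b.size)
        res = replicate_correlation(a[:k], b[:k])
        rows.append(dict(cell_line_id=cid, chemical_id=chem,
                         plate_a=pa, plate_b=pb, pearson_r=res.r,
                         p_value=res.p_value, valid=res.valid,
                         reason=res.reason))
    return pd.DataFrame(rows)
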