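"""LPS calibration from TLR-biosensor fluorescence kinetics.

Reporter cells carrying a fluorescent ATP biosensor brighten as TLR ligands
activate them; stronger stimuli act sooner.  The kinetics of each well are
summarised by the *onset time*: the moment the cumulative area under the
fluorescence curve reaches 30% of its final (saturation) value.  Across a
standard series the log of the LPS concentration is linear in the inverse
onset time,

    log(conc) = a * (1 / onset) + b,

so an ordinary least-squares fit of that line calibrates the assay and
inverts to LPS-equivalent concentrations for unknown samples.  Natural log
is used throughout (the inverse transform is self-consistent for any base).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "FluorescenceCurve",
    "OnsetModel",
    "LpsEstimate",
    "cumulative_auc",
    "onset_time",
    "fit_onset_model",
    "estimate_lps",
    "calibration_report",
]

#: standard-series handling range of the assay, ug/mL
ASSAY_RANGE = (0.01, 3.0)


@dataclass(frozen=True)
class FluorescenceCurve:
    """One well's kinetics: strictly increasing times, non-negative signal."""

    times: np.ndarray
    values: np.ndarray
    known_conc: float | None = None
    well_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or len(t) < 3 or len(t) != len(v):
            raise ValueError("a curve needs >= 3 aligned time points")
        if (np.diff(t) <= 0).any():
            raise ValueError("time points must be strictly increasing")
        if (v < 0).any():
            raise ValueError("fluorescence must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass
class OnsetModel:
    """Fitted onset-time calibration line log(conc) = a/onset + b."""

    a: float
    b: float
    r_squared: float
    onsets: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    assay_range: tuple[float, float] = ASSAY_RANGE
    degenerate: bool = False  # exactly two concentrations: R^2 = 1 by construction


@dataclass(frozen=True)
class LpsEstimate:
    value: float  # ug/mL
    onset: float
    extrapolated: bool  # outside the standard range (reported, not clipped)


def cumulative_auc(curve: FluorescenceCurve) -> np.ndarray:
    """Per-timepoint cumulative trapezoid area; last entry is the saturation value."""
    if len(curve.times) < 2:
        raise ValueError("AUC requires at least two points")
    return cumulative_trapezoid(curve.values, curve.times, initial=0.0)


def onset_time(curve: FluorescenceCurve, fraction: float = 0.30) -> float:
    """Linearly interpolated time at which cumulative AUC reaches ``fraction`` of total.

    Invariant to scaling the fluorescence by any positive constant.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    cum = cumulative_auc(curve)
    total = cum[-1]
    if total <= 0:
        raise ValueError("onset undefined: cumulative AUC is zero")
    target = fraction * total
    i = int(np.searchsorted(cum, target))
    if i == 0:
        return float(curve.times[0])
    # linear interpolation between the bracketing scans
    t0, t1 = curve.times[i - 1], curve.times[i]
    c0, c1 = cum[i - 1], cum[i]
    if c1 == c0:
        return float(t1)
    return float(t0 + (target - c0) / (c1 - c0) * (t1 - t0))


def fit_onset_model(
    curves: list[FluorescenceCurve], fraction: float = 0.30
) -> OnsetModel:
    """OLS of ln(concentration) on inverse onset time across a standard series."""
    import warnings

    onsets, concs, wells = [], [], []
    for i, curve in enumerate(curves):
        if curve.known_conc is None or curve.known_conc <= 0:
            raise ValueError("every standard curve needs a positive known concentration")
        try:
            tau = onset_time(curve, fraction)
        except ValueError as exc:
            warnings.warn(f"curve {curve.well_id or i}: onset failed ({exc}); excluded")
            continue
        onsets.append(tau)
        concs.append(curve.known_conc)
        wells.append(curve.well_id or f"well_{i}")
    distinct = np.unique(np.round(concs, 12))
    if len(distinct) < 2:
        raise ValueError("calibration requires >= 2 distinct known concentrations")
    x = 1.0 / np.asarray(onsets)
    y = np.log(np.asarray(concs))
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return OnsetModel(
        a=float(a),
        b=float(b),
        r_squared=r2,
        onsets=pd.Series(onsets, index=wells, name="onset"),
        degenerate=len(distinct) == 2,
    )


def estimate_lps(
    model: OnsetModel, curve: FluorescenceCurve, fraction: float = 0.30
) -> LpsEstimate:
    """LPS-equivalent concentration exp(a/onset + b) for an unknown sample.

    Estimates outside the standard range are reported but flagged as
    extrapolated rather than clipped: the range is the span of the standard
    series, not a physical bound.
    """
    tau = onset_time(curve, fraction)
    value = float(np.exp(model.a / tau + model.b))
    lo, hi = model.assay_range
    return LpsEstimate(value=value, onset=tau, extrapolated=not (lo <= value <= hi))


def curves_from_long(df: pd.DataFrame) -> list[FluorescenceCurve]:
    """Build curves from a long table with columns well_id, known_conc, time, value."""
    out = []
    for well, grp in df.groupby("well_id", sort=True):
        grp = grp.sort_values("time")
        conc = grp["known_conc"].iloc[0]
        out.append(
            FluorescenceCurve(
                times=grp["time"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                known_conc=None if pd.isna(conc) else float(conc),
                well_id=str(well),
            )
        )
    return out


def calibration_report(
    model: OnsetModel, estimates: dict[str, LpsEstimate] | None = None
) -> dict:
    """JSON-ready calibration summary (a, b, R^2, per-well onsets/estimates)."""
    report = {
        "a": model.a,
        "b": model.b,
        "r_squared": model.r_squared,
        "assay_range_ug_per_ml": list(model.assay_range),
        "degenerate": model.degenerate,
        "onsets": {k: float(v) for k, v in model.onsets.items()},
    }
    if estimates:
        report["estimates"] = {
            k: {"lps_ug_per_ml": e.value, "onset": e.onset, "extrapolated": e.extrapolated}
            for k, e in estimates.items()
        }
    return report
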