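"""Calibration curves over dilution series and LOQ determination.

The limit of quantification follows the back-calculation rule used in
targeted assays: the lowest dilution level whose back-calculated amount
deviates from nominal by less than 20% — by default requiring every higher
level to pass as well (contiguity), so a noisy mid-curve level cannot be
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, SingularFitError

LOQ_MAX_DEVIATION_PCT = 20.0


@dataclass
class CalibrationCurve:
    """Weighted linear fit of response on nominal amount for one peptide."""

    peptide: str
    levels: list[tuple[float, float]]          # (nominal amol, response), ascending
    slope: float
    intercept: float
    weighting: str                             # "none" | "1/x" | "1/x2"
    r2: float
    per_level_deviation: list[float] = field(default_factory=list)  # %, per level
    loq: float | None = None                   # amol, None = not determined


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if weighting == "1/x":
        return 1.0 / x
    if weighting in ("1/x2", "1/x²"):
        return 1.0 / x**2
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_calibration(levels: list[tuple[float, float]], weighting: str = "1/x",
                    peptide: str = "") -> CalibrationCurve:
    """Weighted least-squares line through (nominal, response) levels.

    Requires at least 3 distinct nonzero nominal levels. The default 1/x
    weighting is the targeted-MS convention for series spanning a wide
    dynamic range. Deviations and LOQ are filled in by the caller via
    back_calc_deviation / determine_loq (or use calibrate_series).
    """
    lv = sorted((float(x), float(y)) for x, y in levels)
    xs = np.array([x for x, _ in lv])
    ys = np.array([y for _, y in lv])
    nonzero = xs > 0
    if len(np.unique(xs[nonzero])) < 3:
        raise InsufficientDataError("need >= 3 distinct nonzero levels")
    xs, ys = xs[nonzero], ys[nonzero]
    lv = [p for p in lv if p[0] > 0]
    if np.ptp(xs) == 0:
        raise SingularFitError("zero variance in nominal amounts")
    w = _weights(xs, weighting)
    slope, intercept = np.polyfit(xs, ys, 1, w=np.sqrt(w))
    yhat = slope * xs + intercept
    ybar = np.average(ys, weights=w)
    ss_res = float(np.sum(w * (ys - yhat) ** 2))
    ss_tot = float(np.sum(w * (ys - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CalibrationCurve(peptide=peptide, levels=lv, slope=float(slope),
                            intercept=float(intercept), weighting=weighting,
                            r2=float(r2))


def back_calc_deviation(curve: CalibrationCurve, nominal: float) -> float:
    """Percent deviation of the back-calculated amount at one level.

    100 * |x_hat - nominal| / nominal with x_hat = (response - b) / m.
    """
    if curve.slope == 0:
        raise SingularFitError("slope is zero; back-calculation undefined")
    for x, y in curve.levels:
        if x == nominal:
            x_hat = (y - curve.intercept) / curve.slope
            return 100.0 * abs(x_hat - nominal) / nominal
    raise KeyError(f"nominal level {nominal} not on the curve")


def determine_loq(curve: CalibrationCurve,
                  max_deviation_pct: float = LOQ_MAX_DEVIATION_PCT,
                  contiguous: bool = True) -> float | None:
    """Lowest level quantified within the deviation bound.

    With contiguity (default) the returned level and every level above it
    must pass; without, the lowest passing level is returned regardless of
    failures above. Returns None when no level qualifies. Also fills
    curve.per_level_deviation and curve.loq.
    """
    devs = [back_calc_deviation(curve, x) for x, _ in curve.levels]
    curve.per_level_deviation = devs
    passing = [d < max_deviation_pct for d in devs]
    loq = None
    if contiguous:
        for i in range(len(passing)):
            if all(passing[i:]):
                loq = curve.levels[i][0]
                break
    else:
        for i, ok in enumerate(passing):
            if ok:
                loq = curve.levels[i][0]
                break
    curve.loq = loq
    if loq is not None:
        i = [x for x, _ in curve.levels].index(loq)
        assert devs[i] < max_deviation_pct
    return loq


def calibrate_series(series, weighting: str = "1/x",
                     contiguous: bool = True) -> CalibrationCurve:
    """Full calibration from a simulated dilution series.

    ``series`` is the output of simulate_dilution_series: (nominal amol,
    acquisition) tuples. The response is the light/heavy summed-area ratio of
    the QC-accepted peak pair; levels whose pair fails QC are dropped (they
    cannot be quantified, so they cannot define the LOQ either).
    """
    from .signal import evaluate_acquisition

    levels = []
    peptide = ""
    for nominal, acq in series:
        table = evaluate_acquisition(acq)
        if table.empty:
            continue
        row = table.iloc[0]
        peptide = row["peptide"]
        if row["accepted"] and row["heavy_area"] > 0:
            levels.append((nominal, row["light_area"] / row["heavy_area"]))
    curve = fit_calibration(levels, weighting=weighting, peptide=peptide)
    determine_loq(curve, contiguous=contiguous)
    return curve
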