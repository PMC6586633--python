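"""Chromatogram extraction, peak integration and the acceptance QC.

The QC operationalizes the identification rules of isotope-dilution PRM:
an analyte/standard pair counts as detected only if the mass deviation of
its transitions stays under 5 ppm, at least two transitions are seen, the
peak is Gaussian in shape, the light and heavy partners co-elute, their
transition ratios agree, and the measured fragment pattern matches the
library spectrum (normalized dot product).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import UndefinedSimilarityError
from .simulator import AcquisitionSettings, PeptideSpec, RawAcquisition, SimulationTruth

#: Extraction tolerance (ppm). Deliberately wider than the 5 ppm
#: identification filter: extraction must tolerate the error it measures.
XIC_TOL_PPM = 10.0


@dataclass
class ChromatogramTrace:
    """Time/intensity/measured-m/z series for one transition."""

    peptide: str
    label: str
    fragment: str
    rts: np.ndarray          # min, strictly increasing
    intensities: np.ndarray  # arbitrary units >= 0
    measured_mzs: np.ndarray  # m/z per point, 0 where no centroid matched
    theoretical_mz: float = 0.0

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.measured_mzs = np.asarray(self.measured_mzs, dtype=float)
        if not (len(self.rts) == len(self.intensities) == len(self.measured_mzs)):
            raise ValueError("trace arrays must have equal length")
        if len(self.rts) > 1 and np.any(np.diff(self.rts) <= 0):
            raise ValueError("retention times must be strictly increasing")


@dataclass
class PeakEvaluation:
    """Integrated peak plus QC verdicts for one (or one pair of) precursor(s)."""

    peptide: str = ""
    label: str = ""
    apex_rt: float = float("nan")
    boundaries: tuple[float, float] = (float("nan"), float("nan"))
    areas: dict[str, float] = field(default_factory=dict)
    mass_errors_ppm: dict[str, float] = field(default_factory=dict)
    fragment_detected: dict[str, bool] = field(default_factory=dict)
    n_detected_transitions: int = 0
    shape_r2: float | None = None
    dotp: float | None = None
    rt_delta_heavy_light: float | None = None
    ratio_dotp_heavy_light: float | None = None
    detected: bool = False
    accepted: bool = False
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def mean_abs_ppm(self) -> float:
        vals = [v for v in self.mass_errors_ppm.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass(frozen=True)
class QcThresholds:
    """Acceptance thresholds for evaluate_pair (all configurable)."""

    ppm_max: float = 5.0
    min_transitions: int = 2
    shape_min: float = 0.8
    rt_tol_min: float = 0.05
    ratio_dotp_min: float = 0.85
    library_dotp_min: float = 0.85


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_xic(acquisition: RawAcquisition, peptide: str, label: str,
                fragment: str, theoretical_mz: float,
                tol_ppm: float = XIC_TOL_PPM) -> ChromatogramTrace:
    """Extract one transition's ion chromatogram at a ppm tolerance.

    Per scan the intensity is the sum of all centroids within ``tol_ppm`` of
    the theoretical m/z; the measured m/z is their intensity-weighted mean
    (0 when no centroid matched).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    scans = acquisition.scans_for(peptide, label)
    if not scans:
        raise KeyError(f"no scans for ({peptide!r}, {label!r})")
    tol = theoretical_mz * tol_ppm * 1e-6
    rts = np.empty(len(scans))
    inten = np.zeros(len(scans))
    mzs = np.zeros(len(scans))
    for i, s in enumerate(scans):
        rts[i] = s.rt
        if s.mz.size:
            m = np.abs(s.mz - theoretical_mz) <= tol
            if m.any():
                w = s.intensity[m]
                inten[i] = w.sum()
                mzs[i] = float(np.average(s.mz[m], weights=w)) if w.sum() > 0 else 0.0
    return ChromatogramTrace(peptide=peptide, label=label, fragment=fragment,
                             rts=rts, intensities=inten, measured_mzs=mzs,
                             theoretical_mz=theoretical_mz)


def extract_precursor_traces(acquisition: RawAcquisition, spec: PeptideSpec,
                             tol_ppm: float = XIC_TOL_PPM) -> list[ChromatogramTrace]:
    """XICs for every monitored fragment of one precursor."""
    return [extract_xic(acquisition, spec.sequence, spec.label, name, mz, tol_ppm)
            for name, mz in zip(spec.fragment_names, spec.fragment_mzs)]


# ---------------------------------------------------------------------------
# Peak detection and integration
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, k: int = 5) -> np.ndarray:
    if len(x) < k:
        return x.copy()
    kernel = np.ones(k) / k
    return np.convolve(x, kernel, mode="same")


def _boundary(smoothed: np.ndarray, apex: int, apex_h: float, step: int) -> int:
    """Walk outward from the apex to the nearer of the 1%-of-apex crossing
    or the valley before a rising neighboring peak (a sustained climb to
    twice the running minimum from below 20% of apex)."""
    i = min_i = apex
    n = len(smoothed)
    while 0 <= i + step < n:
        j = i + step
        if smoothed[j] <= smoothed[min_i]:
            min_i = j
        if smoothed[j] <= 0.01 * apex_h:
            return j
        if smoothed[j] > 2.0 * smoothed[min_i] and smoothed[min_i] < 0.2 * apex_h:
            return min_i
        i = j
    return min_i


def detect_and_integrate(traces: list[ChromatogramTrace], expected_rt: float,
                         window: float) -> PeakEvaluation:
    """Locate and integrate the peak nearest the expected elution time.

    The apex is the maximum of the 5-point-smoothed summed trace within
    expected_rt +/- window/2. Boundaries extend from the apex to the nearer
    of a local minimum or 1% of apex height. Per-fragment areas use the
    trapezoidal rule over the boundary interval; per-fragment mass errors are
    intensity-weighted mean absolute ppm deviations over in-boundary points.
    """
    if not traces:
        raise ValueError("at least one trace required")
    if window <= 0:
        raise ValueError("window must be positive")
    rts = traces[0].rts
    summed = np.sum([t.intensities for t in traces], axis=0)
    ev = PeakEvaluation(peptide=traces[0].peptide, label=traces[0].label)
    if summed.max() <= 0:
        ev.detected = False
        ev.rejection_reasons.append("not-detected")
        ev.areas = {t.fragment: 0.0 for t in traces}
        return ev

    smoothed = _moving_average(summed)
    mask = np.abs(rts - expected_rt) <= window / 2
    if not mask.any():
        mask = np.ones_like(rts, dtype=bool)
    idx = np.flatnonzero(mask)
    apex = idx[np.argmax(smoothed[idx])]
    apex_h = smoothed[apex]
    if apex_h <= 0:
        ev.detected = False
        ev.rejection_reasons.append("not-detected")
        ev.areas = {t.fragment: 0.0 for t in traces}
        return ev

    lo = _boundary(smoothed, apex, apex_h, -1)
    hi = _boundary(smoothed, apex, apex_h, +1)
    if hi - lo + 1 < 3:  # widen degenerate boundaries to at least 3 points
        lo, hi = max(0, apex - 1), min(len(rts) - 1, apex + 1)

    sl = slice(lo, hi + 1)
    ev.apex_rt = float(rts[apex])
    ev.boundaries = (float(rts[lo]), float(rts[hi]))
    n_det = 0
    for t in traces:
        area = float(np.trapezoid(t.intensities[sl], rts[sl]))
        ev.areas[t.fragment] = area
        seen = t.intensities[sl] > 0
        matched = seen & (t.measured_mzs[sl] > 0)
        if matched.any():
            ppm = np.abs(t.measured_mzs[sl][matched] - t.theoretical_mz) \
                / t.theoretical_mz * 1e6
            w = t.intensities[sl][matched]
            ev.mass_errors_ppm[t.fragment] = float(np.average(ppm, weights=w))
        else:
            ev.mass_errors_ppm[t.fragment] = float("nan")
        det = area > 0 and seen.sum() >= 3
        ev.fragment_detected[t.fragment] = det
        if det:
            n_det += 1
    ev.n_detected_transitions = n_det
    ev.detected = n_det > 0
    if not ev.detected:
        ev.rejection_reasons.append("not-detected")
    ev.shape_r2 = gaussian_shape_score(rts[sl], summed[sl])
    return ev


def gaussian_shape_score(rts: np.ndarray, intensities: np.ndarray) -> float | None:
    """Coefficient of determination of a least-squares Gaussian fit.

    Returns None (not evaluable) for fewer than 5 points; a flat trace has no
    explainable curvature and scores 0. Clipped to [0, 1].
    """
    rts = np.asarray(rts, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(rts) < 5:
        return None
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0 or y.max() <= 0:
        return 0.0

    def g(t, a, mu, s):
        return a * np.exp(-0.5 * ((t - mu) / s) ** 2)

    p0 = (float(y.max()), float(rts[np.argmax(y)]),
          max(float(rts[-1] - rts[0]) / 6, 1e-4))
    try:
        popt, _ = curve_fit(g, rts, y, p0=p0, maxfev=2000)
        resid = y - g(rts, *popt)
    except (RuntimeError, ValueError):
        return 0.0
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(np.clip(r2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Spectral similarity and pair-level QC
# ---------------------------------------------------------------------------

def dot_product(measured, library) -> float:
    """Normalized spectral dot product in [0, 1].

    1.00 means identical relative fragment patterns, 0.00 means orthogonal
    (no shared signal).
    """
    a = np.asarray(measured, dtype=float)
    b = np.asarray(library, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("vectors must be 1-D, equal length >= 2")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("intensities must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("dot product undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def _qualified_transitions(part: PeakEvaluation,
                           thresholds: QcThresholds) -> dict[str, float]:
    """Transitions counting as detected: signal present AND own mean |mass
    error| under the ppm bound (the identification filter is applied per
    transition, as in targeted-MS review practice)."""
    out = {}
    for frag, area in part.areas.items():
        detected = part.fragment_detected.get(frag, area > 0)
        ppm = part.mass_errors_ppm.get(frag, float("nan"))
        if detected and np.isfinite(ppm) and ppm < thresholds.ppm_max:
            out[frag] = ppm
    return out


def evaluate_pair(light: PeakEvaluation, heavy: PeakEvaluation,
                  library: dict[str, float],
                  thresholds: QcThresholds = QcThresholds()) -> PeakEvaluation:
    """Apply the pairwise acceptance criteria and return the pair verdict.

    A transition qualifies when it is detected with mean |mass error| under
    ppm_max. Accepted iff all of: >= min_transitions qualifying transitions
    for both partners; mean |mass error| of detected transitions < ppm_max
    for both; Gaussian shape score >= shape_min; |apex RT difference| <=
    rt_tol; light/heavy transition-ratio dot product >= ratio_dotp_min;
    light-vs-library dot product >= library_dotp_min. Every failed
    criterion is named in rejection_reasons. The verdict's mass_errors_ppm
    holds the qualifying transitions of both partners (label-prefixed).
    """
    ev = PeakEvaluation(
        peptide=light.peptide, label="pair", apex_rt=light.apex_rt,
        boundaries=light.boundaries, areas=dict(light.areas),
        shape_r2=light.shape_r2, detected=light.detected and heavy.detected)
    reasons = ev.rejection_reasons

    if not ev.detected:
        reasons.append("not-detected")

    for part in (light, heavy):
        qualified = _qualified_transitions(part, thresholds)
        prefix = "heavy" if part is heavy else "light"
        for frag, ppm in qualified.items():
            ev.mass_errors_ppm[f"{prefix}:{frag}"] = ppm
        if part is light:
            ev.n_detected_transitions = len(qualified)
        ppm = part.mean_abs_ppm
        if not np.isfinite(ppm) or ppm >= thresholds.ppm_max:
            if "mass-error" not in reasons:
                reasons.append("mass-error")
        if len(qualified) < thresholds.min_transitions:
            if "min-transitions" not in reasons:
                reasons.append("min-transitions")
        if part.shape_r2 is None or part.shape_r2 < thresholds.shape_min:
            if "shape" not in reasons:
                reasons.append("shape")

    if np.isfinite(light.apex_rt) and np.isfinite(heavy.apex_rt):
        ev.rt_delta_heavy_light = abs(light.apex_rt - heavy.apex_rt)
        if ev.rt_delta_heavy_light > thresholds.rt_tol_min:
            reasons.append("rt-coelution")
    else:
        reasons.append("rt-coelution")

    frags = sorted(set(light.areas) & set(heavy.areas) & set(library))
    if len(frags) >= 2:
        la = np.array([light.areas[f] for f in frags])
        ha = np.array([heavy.areas[f] for f in frags])
        lib = np.array([library[f] for f in frags])
        try:
            ev.ratio_dotp_heavy_light = dot_product(la, ha)
            ev.dotp = dot_product(la, lib)
        except UndefinedSimilarityError:
            ev.ratio_dotp_heavy_light = None
            ev.dotp = None
        if ev.ratio_dotp_heavy_light is None \
                or ev.ratio_dotp_heavy_light < thresholds.ratio_dotp_min:
            reasons.append("ratio-dotp")
        if ev.dotp is None or ev.dotp < thresholds.library_dotp_min:
            reasons.append("library-dotp")
    else:
        reasons.append("ratio-dotp")
        reasons.append("library-dotp")

    ev.accepted = not reasons
    return ev


def rt_tolerance_for(settings: AcquisitionSettings, n_concurrent: int) -> float:
    """Co-elution tolerance: one cycle time, floored at 0.05 min."""
    cycle_min = n_concurrent * settings.per_scan_ms / 60_000.0
    return max(0.05, cycle_min)


def signal_to_noise(traces: list[ChromatogramTrace],
                    evaluation: PeakEvaluation | None = None) -> float:
    """Apex height of the summed trace over the background floor.

    The floor is the median of the lowest quartile of the summed trace —
    robust to peak-boundary choices and to chemical background that spans
    the whole scheduling window.
    """
    summed = np.sum([t.intensities for t in traces], axis=0)
    if summed.max() <= 0:
        return 0.0
    k = max(1, summed.size // 4)
    floor = float(np.median(np.partition(summed, k - 1)[:k]))
    return float(summed.max() / max(floor, 1.0))


# ---------------------------------------------------------------------------
# Pair-level pipeline helpers and parameter sweep
# ---------------------------------------------------------------------------

def evaluate_acquisition(acquisition: RawAcquisition,
                         thresholds: QcThresholds | None = None,
                         tol_ppm: float = XIC_TOL_PPM) -> pd.DataFrame:
    """Extract, integrate and QC every light/heavy pair of an acquisition.

    Returns a tidy table with one row per pair: QC metrics, verdict, areas
    and the light/heavy area ratio inputs for quantification.
    """
    from .simulator import panel_pairs

    rows = []
    for light, heavy in panel_pairs(acquisition.panel):
        if not acquisition.scans_for(light.sequence, light.label):
            continue
        lt = extract_precursor_traces(acquisition, light, tol_ppm)
        ht = extract_precursor_traces(acquisition, heavy, tol_ppm)
        lev = detect_and_integrate(lt, light.rt_true, acquisition.settings.rt_window)
        hev = detect_and_integrate(ht, heavy.rt_true, acquisition.settings.rt_window)
        library = dict(zip(light.fragment_names, light.fragment_rel_intensities))
        thr = thresholds
        if thr is None:
            n_conc = _max_concurrency(acquisition.panel, acquisition.settings)
            thr = QcThresholds(rt_tol_min=rt_tolerance_for(acquisition.settings, n_conc))
        pair = evaluate_pair(lev, hev, library, thr)
        rows.append({
            "peptide": light.sequence, "protein": light.protein,
            "accepted": pair.accepted,
            "rejection_reasons": ";".join(pair.rejection_reasons),
            "mean_abs_ppm": pair.mean_abs_ppm,
            "dotp": pair.dotp, "ratio_dotp": pair.ratio_dotp_heavy_light,
            "shape_r2": pair.shape_r2,
            "n_transitions": pair.n_detected_transitions,
            "apex_rt": pair.apex_rt,
            "light_area": sum(lev.areas.values()),
            "heavy_area": sum(hev.areas.values()),
            "sn": signal_to_noise(lt, lev),
            "light_eval": lev, "heavy_eval": hev, "pair_eval": pair,
        })
    return pd.DataFrame(rows)


def _max_concurrency(panel: list[PeptideSpec], settings: AcquisitionSettings) -> int:
    events = []
    seen = set()
    for p in panel:
        if p.sequence in seen:
            continue
        seen.add(p.sequence)
        events.append((p.rt_true - settings.rt_window / 2, 1))
        events.append((p.rt_true + settings.rt_window / 2, -1))
    events.sort()
    cur = best = 0
    for _, d in events:
        cur += d
        best = max(best, cur)
    return max(1, best * 2)  # pairs -> precursors


def parameter_sweep(panel: list[PeptideSpec], truth: SimulationTruth,
                    settings_grid: list[AcquisitionSettings],
                    loq_pairs: list[tuple[PeptideSpec, PeptideSpec]] | None = None,
                    loq_start: float = 118.0, loq_seed: int = 0) -> pd.DataFrame:
    """Run simulate -> extract -> QC per settings and summarize the trade-offs.

    Per grid point reports the mean absolute mass deviation, mean library dot
    product and mean S/N over detected pairs; if loq_pairs is given, also the
    median limit of quantification over 2-fold dilution series for those
    pairs (see the calibrate module).
    """
    from . import calibrate as _cal
    from .simulator import simulate_acquisition, simulate_dilution_series

    if not settings_grid:
        raise ValueError("settings grid must be non-empty")
    rows = []
    for st in settings_grid:
        acq = simulate_acquisition(panel, st, truth)
        table = evaluate_acquisition(acq)
        det = table[table["n_transitions"] > 0]
        row = {
            "resolution": st.resolution,
            "injection_time": st.injection_time,
            "isolation_width": st.isolation_width,
            "mean_abs_ppm": float(det["mean_abs_ppm"].mean()) if len(det) else float("nan"),
            "mean_dotp": float(det["dotp"].dropna().mean()) if len(det) else float("nan"),
            "mean_sn": float(det["sn"].mean()) if len(det) else float("nan"),
            "n_accepted": int(table["accepted"].sum()),
        }
        if loq_pairs:
            loqs = []
            for pair in loq_pairs:
                series = simulate_dilution_series(pair, loq_start, 2.0, 7, st,
                                                  seed=loq_seed)
                curve = _cal.calibrate_series(series)
                loqs.append(curve.loq if curve.loq is not None else float("inf"))
            row["median_loq"] = float(np.median(loqs))
        rows.append(row)
    return pd.DataFrame(rows)
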