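"""Scripted reproductions of the workflow's headline behaviors on
synthetic acquisitions: instrument-parameter trends, LOQ ordering across
parameter sets, and induction time-course recovery.

Each experiment is deterministic given its seed and returns an
ExperimentReport with machine-readable metrics and pass/fail checks. Real-
instrument magnitudes (absolute LOQs, copy numbers, exact fold changes)
enter only as simulation parameters or ordering properties, never as
numeric assertions about external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import calibrate_series
from .signal import evaluate_acquisition
from .simulator import (AcquisitionSettings, build_upr_panel, default_truth,
                        panel_pairs, simulate_acquisition,
                        simulate_condition_experiment, simulate_dilution_series,
                        _derive_seed)

#: The three acquisition parameter sets compared throughout: the optimized
#: high-resolution/long-fill setup against its two ablations.
PARAMETER_SETS = {
    "240k-500ms": AcquisitionSettings(resolution=240_000, injection_time=500),
    "240k-60ms": AcquisitionSettings(resolution=240_000, injection_time=60),
    "30k-500ms": AcquisitionSettings(resolution=30_000, injection_time=500),
}


@dataclass
class ExperimentReport:
    experiment: str
    seed: int
    n_seeds: int
    metrics: dict = field(default_factory=dict)
    checks: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def _subpanel(panel, n_pairs: int):
    pairs = panel_pairs(panel)[:n_pairs]
    return [p for pair in pairs for p in pair]


def instrument_parameter_trends(seed: int = 0, n_seeds: int = 20,
                                n_pairs: int = 4,
                                with_interferent: bool = True) -> ExperimentReport:
    """Monotone instrument-physics trends over repeated simulations.

    Checks, averaged over seeds: mean |mass error| decreases 15k -> 60k ->
    240k; mean library dot product is non-decreasing over injection times
    30 -> 80 -> 500 ms; and with a co-eluting interferent present, S/N at
    isolation width 0.4 exceeds S/N at 1.6.
    """
    rep = ExperimentReport("instrument_parameter_trends", seed, n_seeds)
    if n_seeds < 2:
        rep.notes.append("insufficient replication: trends need >= 2 seeds")
        rep.checks["replication"] = False
        return rep

    panel = _subpanel(build_upr_panel(seed), n_pairs)

    def mean_metric(settings, column, with_itf):
        vals = []
        for k in range(n_seeds):
            truth = default_truth(panel, seed=_derive_seed(seed, f"trend:{k}"),
                                  with_interference=with_itf)
            table = evaluate_acquisition(simulate_acquisition(panel, settings, truth))
            col = table[table["n_transitions"] > 0][column].dropna()
            if len(col):
                vals.append(float(col.mean()))
        return float(np.mean(vals))

    ppm = {r: mean_metric(AcquisitionSettings(resolution=r), "mean_abs_ppm", False)
           for r in (15_000, 60_000, 240_000)}
    rep.metrics["mean_abs_ppm_by_resolution"] = ppm
    rep.checks["mass_error_monotone"] = ppm[240_000] < ppm[60_000] < ppm[15_000]

    dotp = {it: mean_metric(AcquisitionSettings(injection_time=it), "dotp", False)
            for it in (30, 80, 500)}
    rep.metrics["mean_dotp_by_injection_ms"] = dotp
    rep.checks["dotp_monotone"] = dotp[500] >= dotp[80] >= dotp[30]

    sn = {w: mean_metric(AcquisitionSettings(isolation_width=w), "sn", with_interferent)
          for w in (0.4, 1.6)}
    rep.metrics["mean_sn_by_isolation_width"] = sn
    if with_interferent:
        rep.checks["sn_narrow_isolation"] = sn[0.4] > sn[1.6]
    else:
        rep.metrics["sn_ratio_no_interferent"] = sn[0.4] / sn[1.6]
        rep.notes.append("interferent ablated: isolation-width effect expected small")
    return rep


def calibration_loq_comparison(seed: int = 0, n_seeds: int = 10,
                               n_pairs: int = 4, start_conc: float = 118.0,
                               min_fraction: float = 0.8) -> ExperimentReport:
    """LOQ ordering across the three parameter sets.

    Builds 7-step factor-2 dilution series per peptide and seed, fits
    calibration curves, determines per-peptide LOQs and checks that the
    optimized setup (240k, 500 ms) reaches an LOQ at least as low as both
    ablations for >= ``min_fraction`` of (peptide, seed) series.
    """
    rep = ExperimentReport("calibration_loq_comparison", seed, n_seeds)
    pairs = panel_pairs(build_upr_panel(seed))[:n_pairs]
    loqs: dict[str, list[float]] = {name: [] for name in PARAMETER_SETS}
    for k in range(n_seeds):
        s = _derive_seed(seed, f"loq:{k}")
        for pair in pairs:
            for name, st in PARAMETER_SETS.items():
                series = simulate_dilution_series(pair, start_conc, 2.0, 7, st, seed=s)
                try:
                    curve = calibrate_series(series)
                    loq = curve.loq
                except Exception:
                    loq = None
                loqs[name].append(loq if loq is not None else float("inf"))
    arr = {name: np.array(v) for name, v in loqs.items()}
    best = arr["240k-500ms"]
    frac = float(np.mean((best <= arr["240k-60ms"]) & (best <= arr["30k-500ms"])))
    rep.metrics["median_loq_amol"] = {
        name: float(np.median(v[np.isfinite(v)])) if np.isfinite(v).any() else None
        for name, v in arr.items()}
    rep.metrics["fraction_best_setting_loq_lowest"] = frac
    rep.checks["loq_ordering"] = frac >= min_fraction
    return rep


#: Programmed induction trajectories (fold change by time in hours) for the
#: two synthetic treatments: a strong sustained response with early
#: transcription-factor induction and delayed receptor induction, and a
#: weaker transient one.
EARLY_PROTEINS = ("XBP1", "ATF4", "ATF3")
DELAYED_PROTEINS = ("IRE1", "PERK", "ATF6")
TIMEPOINTS_HR = (6.0, 16.0, 24.0)


def _trajectory(protein: str, max_fold: float, sustained: bool) -> dict[float, float]:
    if protein == "ATF6":
        # consumed by proteolytic activation early, resynthesized later;
        # its induction is a modest recovery, not a multi-fold increase
        return {6.0: 0.6, 16.0: 0.9, 24.0: 1.2}
    early = protein in EARLY_PROTEINS
    ramp = {6.0: 1.0, 16.0: 0.6, 24.0: 1.0} if early else {6.0: 0.2, 16.0: 0.7, 24.0: 1.0}
    if not sustained:
        ramp = {tp: f * (0.5 if tp == 24.0 else 1.0) for tp, f in ramp.items()}
    return {tp: 1.0 + (max_fold - 1.0) * f for tp, f in ramp.items()}


def induction_timecourse(seed: int = 0, replicates: int = 3,
                         sustained_fold: float = 17.0,
                         transient_fold: float = 5.0,
                         n_pairs: int = 6, cv: float = 0.10) -> ExperimentReport:
    """Recovery of programmed induction trajectories from the full pipeline.

    Two synthetic treatments are simulated over 6/16/24 h: a sustained
    ~17-fold induction and a transient ~5-fold one, with early effectors
    and delayed receptors. Checks that recovered maximal fold changes land
    within 3 replicate-sd of truth and that the early-vs-delayed onset
    ordering is reproduced.
    """
    from .quantify import quantify_acquisition

    rep = ExperimentReport("induction_timecourse", seed, replicates)
    # one pair per protein, covering both early and delayed responders
    wanted = (EARLY_PROTEINS + DELAYED_PROTEINS)[:n_pairs]
    panel = []
    for protein in wanted:
        for light, heavy in panel_pairs(build_upr_panel(seed)):
            if light.protein == protein:
                panel.extend([light, heavy])
                break
    proteins = sorted({p.protein for p in panel})
    settings = PARAMETER_SETS["240k-500ms"]
    recovered: dict[str, dict[str, dict[float, float]]] = {}
    recovered_sd: dict[str, dict[str, dict[float, float]]] = {}
    truth_folds: dict[str, dict[str, dict[float, float]]] = {}

    for cond, max_fold, sustained in (("sustained", sustained_fold, True),
                                      ("transient", transient_fold, False)):
        recovered[cond] = {p: {} for p in proteins}
        recovered_sd[cond] = {p: {} for p in proteins}
        truth_folds[cond] = {p: _trajectory(p, max_fold, sustained) for p in proteins}
        for tp in TIMEPOINTS_HR:
            folds = {p: truth_folds[cond][p][tp] for p in proteins}
            runs = simulate_condition_experiment(
                panel, folds, replicates, settings,
                seed=_derive_seed(seed, f"{cond}:{tp}"), cv=cv)
            per_protein: dict[str, dict[str, list[float]]] = {"control": {}, "treated": {}}
            for arm in ("control", "treated"):
                for acq in runs[arm]:
                    for q in quantify_acquisition(acq):
                        per_protein[arm].setdefault(q.protein, []).append(q.amount_amol)
            for p in proteins:
                c = per_protein["control"].get(p)
                t = per_protein["treated"].get(p)
                if c and t:
                    fold = float(np.mean(t) / np.mean(c))
                    recovered[cond][p][tp] = fold
                    emp = (np.std(t, ddof=1) / np.mean(t) / np.sqrt(len(t))
                           if len(t) > 1 else 0.0)
                    # analytic sd of a ratio of replicate means at the
                    # programmed CV, floored by the empirical estimate
                    rel = max(float(emp), cv / np.sqrt(len(t)))
                    recovered_sd[cond][p][tp] = fold * rel * np.sqrt(2)

    rep.metrics["recovered_folds"] = recovered
    rep.metrics["truth_folds"] = truth_folds

    within = []
    for cond in recovered:
        for p in proteins:
            if not recovered[cond][p]:
                continue
            tp_max = max(truth_folds[cond][p], key=truth_folds[cond][p].get)
            if tp_max in recovered[cond][p]:
                err = abs(recovered[cond][p][tp_max] - truth_folds[cond][p][tp_max])
                sd = max(recovered_sd[cond][p][tp_max], 1e-6)
                within.append(err <= 3 * sd)
    rep.metrics["n_fold_recoveries"] = len(within)
    rep.checks["max_fold_within_3sd"] = bool(within) and all(within)

    onset_ok = []
    for cond in recovered:
        for pe in [p for p in proteins if p in EARLY_PROTEINS]:
            for pd_ in [p for p in proteins if p in DELAYED_PROTEINS]:
                re6 = recovered[cond].get(pe, {}).get(6.0)
                rd6 = recovered[cond].get(pd_, {}).get(6.0)
                te6 = truth_folds[cond][pe][6.0]
                td6 = truth_folds[cond][pd_][6.0]
                if re6 is not None and rd6 is not None and te6 > td6:
                    # early protein's relative 6-h induction exceeds delayed one's
                    onset_ok.append(re6 / truth_folds[cond][pe][24.0]
                                    > rd6 / truth_folds[cond][pd_][24.0])
    rep.metrics["n_onset_comparisons"] = len(onset_ok)
    rep.checks["onset_ordering"] = bool(onset_ok) and np.mean(onset_ok) >= 0.9
    return rep
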