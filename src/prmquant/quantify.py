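"""Absolute quantification: amounts, copy numbers, fold changes.

Isotope dilution: the endogenous (light) peptide is quantified against a
stable-isotope-labeled internal standard spiked at a known amount. Either a
single-point ratio (amount = L/H ratio x spiked amount) or a calibration
curve maps the MS response to amol on column; Avogadro's number and the
measured per-cell protein mass convert amol to protein copies per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibrate import CalibrationCurve
from .errors import UndefinedRatioError

AVOGADRO = 6.022e23
#: Total protein mass per cell (ng) measured for the glioblastoma line used
#: as the default matrix, and peptide mass loaded on column (ug).
PROTEIN_PER_CELL_NG = 0.20
LOADED_PEPTIDE_UG = 1.0


@dataclass
class QuantResult:
    peptide: str
    protein: str
    lh_ratio: float
    amount_amol: float
    is_amount_amol: float | None = None
    copies_per_cell: float | None = None
    n_cells_on_column: float | None = None
    mode: str = "single-point"  # or "curve"
    clamped: bool = False
    replicate_mean: float | None = None
    replicate_sd: float | None = None


@dataclass
class ConditionComparison:
    protein: str
    condition: str
    timepoint_hr: float
    fold_change: float | None
    control_copies: float | None = None
    treated_copies: float | None = None
    treated_sd: float | None = None
    flags: list[str] = field(default_factory=list)


def light_heavy_ratio(light_areas: dict[str, float],
                      heavy_areas: dict[str, float]) -> float:
    """Summed light area over summed heavy area across shared fragments."""
    shared = sorted(set(light_areas) & set(heavy_areas))
    if not shared:
        raise UndefinedRatioError("no shared fragments")
    h = sum(heavy_areas[f] for f in shared)
    if h <= 0:
        raise UndefinedRatioError("all heavy areas are zero")
    return float(sum(light_areas[f] for f in shared) / h)


def absolute_amount(value: float, curve: CalibrationCurve | None = None,
                    is_amount: float | None = None) -> tuple[float, str, bool]:
    """Map a response to amol on column.

    Single-point mode (``is_amount`` given): amount = L/H ratio x spiked
    standard amount. Curve mode: amount = (response - intercept) / slope.
    Negative back-calculated amounts clamp to 0 with a warning flag —
    legitimate near blank levels. Returns (amount, mode, clamped).
    """
    if curve is not None:
        if curve.slope == 0:
            raise ValueError("calibration slope is zero")
        amount = (value - curve.intercept) / curve.slope
        mode = "curve"
    elif is_amount is not None:
        if is_amount <= 0:
            raise ValueError("is_amount must be positive")
        amount = value * is_amount
        mode = "single-point"
    else:
        raise ValueError("provide a calibration curve or an internal-standard amount")
    clamped = amount < 0
    if clamped:
        warnings.warn("negative back-calculated amount clamped to 0", stacklevel=2)
        amount = 0.0
    return float(amount), mode, clamped


def copies_per_cell(amount_amol: float,
                    loaded_peptide_ug: float = LOADED_PEPTIDE_UG,
                    protein_per_cell_ng: float = PROTEIN_PER_CELL_NG,
                    ) -> tuple[float, float]:
    """Convert amol on column to protein copies per cell.

    cells on column = loaded peptide mass / protein mass per cell;
    copies = amount[mol] x Avogadro / cells. Returns (copies, n_cells).
    """
    if amount_amol < 0:
        raise ValueError("amount must be non-negative")
    if loaded_peptide_ug <= 0 or protein_per_cell_ng <= 0:
        raise ValueError("loaded mass and per-cell protein mass must be positive")
    n_cells = loaded_peptide_ug * 1e3 / protein_per_cell_ng  # ug -> ng
    copies = amount_amol * 1e-18 * AVOGADRO / n_cells
    return float(copies), float(n_cells)


def aggregate_protein(results: list[QuantResult],
                      method: str = "mean") -> tuple[float, float, int]:
    """Protein-level copy number from its peptides.

    Unweighted mean (default; ``method='median'`` available) across peptide
    copy numbers; sd across peptides. Raises if no peptide was quantified.
    Returns (center, sd, n_peptides).
    """
    vals = np.array([r.copies_per_cell for r in results
                     if r.copies_per_cell is not None])
    if vals.size == 0:
        raise UndefinedRatioError("no quantified peptides for this protein")
    center = float(np.median(vals)) if method == "median" else float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return center, sd, int(vals.size)


def quantify_acquisition(acquisition, curve_by_peptide=None,
                         is_amounts: dict[str, float] | None = None,
                         loaded_peptide_ug: float = LOADED_PEPTIDE_UG,
                         protein_per_cell_ng: float = PROTEIN_PER_CELL_NG,
                         accepted_only: bool = True) -> list[QuantResult]:
    """QC an acquisition and quantify every accepted pair.

    Uses curve mode where a calibration curve is supplied for the peptide,
    otherwise single-point mode with the spiked standard amount (from
    ``is_amounts`` or the simulation truth).
    """
    from .signal import evaluate_acquisition

    table = evaluate_acquisition(acquisition)
    out: list[QuantResult] = []
    for _, row in table.iterrows():
        if accepted_only and not row["accepted"]:
            continue
        lev, hev = row["light_eval"], row["heavy_eval"]
        try:
            ratio = light_heavy_ratio(lev.areas, hev.areas)
        except UndefinedRatioError:
            continue
        curve = (curve_by_peptide or {}).get(row["peptide"])
        if curve is not None:
            amount, mode, clamped = absolute_amount(ratio, curve=curve)
        else:
            isa = None
            if is_amounts and row["peptide"] in is_amounts:
                isa = is_amounts[row["peptide"]]
            elif acquisition.truth is not None:
                isa = acquisition.truth.amounts.get((row["peptide"], "heavy"))
            if isa is None:
                raise ValueError(
                    f"no calibration curve or IS amount for {row['peptide']}")
            amount, mode, clamped = absolute_amount(ratio, is_amount=isa)
        cpc, n_cells = copies_per_cell(amount, loaded_peptide_ug, protein_per_cell_ng)
        out.append(QuantResult(peptide=row["peptide"], protein=row["protein"],
                               lh_ratio=ratio, amount_amol=amount,
                               is_amount_amol=None if curve else isa,
                               copies_per_cell=cpc, n_cells_on_column=n_cells,
                               mode=mode, clamped=clamped))
    return out


def fold_change_timecourse(copies_by_condition: dict[tuple[str, float],
                                                     dict[str, list[float]]],
                           control_label: str = "control",
                           ) -> list[ConditionComparison]:
    """Per-protein, per-timepoint fold changes versus the matched control.

    ``copies_by_condition`` maps (condition, timepoint_hr) to per-protein
    replicate copy numbers. Missing control pairs are flagged, not dropped;
    a zero control copy number flags an undefined fold change.
    """
    out: list[ConditionComparison] = []
    controls = {tp: prot for (cond, tp), prot in copies_by_condition.items()
                if cond == control_label}
    for (cond, tp), proteins in sorted(copies_by_condition.items()):
        if cond == control_label:
            continue
        for protein, reps in sorted(proteins.items()):
            treated = float(np.mean(reps))
            sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
            cc = ConditionComparison(protein=protein, condition=cond,
                                     timepoint_hr=tp, fold_change=None,
                                     treated_copies=treated, treated_sd=sd)
            ctrl = controls.get(tp, {}).get(protein)
            if ctrl is None:
                cc.flags.append("missing-control")
            else:
                c = float(np.mean(ctrl))
                cc.control_copies = c
                if c == 0:
                    cc.flags.append("undefined-fold-change")
                else:
                    cc.fold_change = treated / c
            out.append(cc)
    return out
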