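"""Target selection and scheduled-method design for PRM.

Long fills and long transients make the PRM duty cycle slow, so the number
of precursors monitored at any elution time must be capped to keep enough
points across each chromatographic peak. This module digests protein
sequences in silico, filters candidates to proteotypic peptides (unique in
the supplied proteome, fully cleaved, no ragged ends), and greedily builds a
scheduled method whose concurrency never exceeds the cap — by default 3
heavy/light precursor pairs within 2-minute retention-time windows.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from pyteomics import parser as _pparser

from .simulator import AcquisitionSettings, transient_ms

TRYPSIN_SITE = re.compile(r"[KR](?!P)")

# Kyte-Doolittle hydropathy, used as a retention-time surrogate when no
# measured/predicted RT is supplied.
_KD = {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
       "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
       "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
       "Y": -1.3, "V": 4.2}


@dataclass(frozen=True)
class CandidatePeptide:
    sequence: str
    protein: str
    rt_predicted: float
    unique_in_proteome: bool
    missed_cleavages: int
    ragged_end: bool


@dataclass
class ScheduledMethod:
    """Per-pair RT windows plus the concurrency/cycle bookkeeping."""

    targets: list[tuple[CandidatePeptide, float, float]]  # (pair, start, end)
    rt_window: float
    max_concurrency_observed: int = 0
    cycle_time_at_peak_concurrency_ms: float = 0.0
    est_points_per_peak: float = 0.0
    uncovered_proteins: list[str] = field(default_factory=list)
    rejected: list[CandidatePeptide] = field(default_factory=list)


def predict_rt(sequence: str, gradient_min: float = 75.0) -> float:
    """Hydrophobicity-sum surrogate mapped onto the gradient (min)."""
    h = sum(_KD.get(a, 0.0) for a in sequence)
    return 5.0 + (gradient_min - 10.0) / (1.0 + np.exp(-0.12 * h))


def _count_missed(peptide: str) -> int:
    return len(TRYPSIN_SITE.findall(peptide[:-1]))


def tryptic_digest(entries: list[tuple[str, str]], max_missed: int = 2,
                   min_length: int = 6, max_length: int = 30,
                   rt_by_sequence: dict[str, float] | None = None,
                   ) -> list[CandidatePeptide]:
    """In-silico tryptic digest with uniqueness, missed-cleavage and
    ragged-end annotation.

    Cleaves C-terminal to K/R except before P (pyteomics trypsin rule).
    A peptide is ragged when a K/R run makes its cleavage register
    ambiguous: the residue after its C-terminus, or the residue preceding
    its N-terminal cleavage site, is itself K/R. Uniqueness is exact
    substring containment in exactly one supplied entry. Empty sequences
    are skipped with a warning.
    """
    if not entries:
        raise ValueError("at least one sequence required")
    clean: list[tuple[str, str]] = []
    for name, seq in entries:
        if not seq:
            warnings.warn(f"empty sequence for {name!r}; skipped")
            continue
        clean.append((name, seq.upper()))
    out: list[CandidatePeptide] = []
    for name, seq in clean:
        for start, pep in _pparser.icleave(seq, _pparser.expasy_rules["trypsin"],
                                           missed_cleavages=max_missed,
                                           min_length=1):
            if not (min_length <= len(pep) <= max_length):
                continue
            end = start + len(pep)
            ragged = (end < len(seq) and seq[end] in "KR") or \
                     (start >= 2 and seq[start - 2] in "KR")
            n_owners = sum(1 for _, s in clean if pep in s)
            rt = (rt_by_sequence or {}).get(pep, predict_rt(pep))
            out.append(CandidatePeptide(
                sequence=pep, protein=name, rt_predicted=float(rt),
                unique_in_proteome=n_owners == 1,
                missed_cleavages=_count_missed(pep), ragged_end=ragged))
    return out


def concurrency_profile(method: ScheduledMethod,
                        ) -> tuple[int, list[tuple[float, int]]]:
    """Sweep-line count of concurrently scheduled PAIRS over retention time.

    Each target contributes one pair (two precursors). Returns the maximum
    and the full (rt, count) step profile.
    """
    if not method.targets:
        raise ValueError("method has no targets")
    events: list[tuple[float, int]] = []
    for _, start, end in method.targets:
        events.append((start, 1))
        events.append((end, -1))
    events.sort(key=lambda e: (e[0], e[1]))  # close before open at ties
    profile: list[tuple[float, int]] = []
    cur = best = 0
    for rt, d in events:
        cur += d
        profile.append((rt, cur))
        best = max(best, cur)
    return best, profile


def _fits_under_cap(windows: list[tuple[float, float]],
                    new: tuple[float, float], cap: int) -> bool:
    events = []
    for a, b in windows + [new]:
        events.append((a, 1))
        events.append((b, -1))
    events.sort(key=lambda e: (e[0], e[1]))
    cur = 0
    for _, d in events:
        cur += d
        if cur > cap:
            return False
    return True


def select_targets(candidates: list[CandidatePeptide], rt_window: float = 2.0,
                   max_concurrent: int = 3, per_protein_min: int = 1,
                   settings: AcquisitionSettings | None = None,
                   require_proteotypic: bool = True) -> ScheduledMethod:
    """Greedy scheduled-method construction under the concurrency cap.

    Candidates failing the proteotypic filters (non-unique, missed
    cleavages, ragged ends) are rejected up front. Proteins are served in
    rounds, neediest first; within a protein the candidate farthest in RT
    from already-selected targets wins (well-separated elution). A candidate
    is only admitted if the resulting window set stays within
    ``max_concurrent`` pairs at every RT; the method never silently violates
    the cap — infeasible proteins are reported as uncovered.
    """
    if rt_window <= 0:
        raise ValueError("rt_window must be positive")
    eligible, rejected = [], []
    for c in candidates:
        ok = (not require_proteotypic) or (
            c.unique_in_proteome and c.missed_cleavages == 0 and not c.ragged_end)
        (eligible if ok else rejected).append(c)

    by_protein: dict[str, list[CandidatePeptide]] = {}
    for c in eligible:
        by_protein.setdefault(c.protein, []).append(c)
    selected: list[tuple[CandidatePeptide, float, float]] = []
    windows: list[tuple[float, float]] = []
    chosen: set[str] = set()
    uncovered: list[str] = []

    def isolation_score(c: CandidatePeptide) -> float:
        if not selected:
            return float("inf")
        return min(abs(c.rt_predicted - t.rt_predicted) for t, _, _ in selected)

    for round_i in range(per_protein_min):
        order = sorted(by_protein, key=lambda p: (len(by_protein[p]), p))
        for protein in order:
            pool = [c for c in by_protein[protein] if c.sequence not in chosen]
            pool.sort(key=lambda c: (-isolation_score(c), c.rt_predicted, c.sequence))
            placed = False
            for c in pool:
                win = (c.rt_predicted - rt_window / 2, c.rt_predicted + rt_window / 2)
                if _fits_under_cap(windows, win, max_concurrent):
                    selected.append((c, win[0], win[1]))
                    windows.append(win)
                    chosen.add(c.sequence)
                    placed = True
                    break
            if not placed and round_i == 0:
                uncovered.append(protein)

    method = ScheduledMethod(targets=selected, rt_window=rt_window,
                             uncovered_proteins=sorted(set(uncovered)),
                             rejected=rejected)
    if selected:
        max_pairs, _ = concurrency_profile(method)
        method.max_concurrency_observed = max_pairs
        assert max_pairs <= max_concurrent
        if settings is not None:
            cycle, ppp = estimate_cycle(settings, 2 * max_pairs)
            method.cycle_time_at_peak_concurrency_ms = cycle
            method.est_points_per_peak = ppp
    return method


def estimate_cycle(settings: AcquisitionSettings, n_concurrent_precursors: int,
                   peak_base_width_min: float = 0.5) -> tuple[float, float]:
    """Duty-cycle model: cycle time and chromatographic points per peak.

    Per-scan time = max(injection time, orbitrap transient) + overhead;
    the cycle serves every concurrent precursor once. Unknown resolutions
    fall back to the nearest tabulated transient with a warning.
    """
    if n_concurrent_precursors < 1:
        raise ValueError("need at least one concurrent precursor")
    from .simulator import TRANSIENT_MS
    if settings.resolution not in TRANSIENT_MS:
        warnings.warn(f"resolution {settings.resolution:g} not tabulated; "
                      f"using nearest transient ({transient_ms(settings.resolution)} ms)")
    cycle = n_concurrent_precursors * settings.per_scan_ms
    points = peak_base_width_min * 60_000.0 / cycle
    return float(cycle), float(points)
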