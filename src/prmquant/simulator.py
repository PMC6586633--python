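"""Synthetic orbitrap PRM acquisition simulator.

Generates centroided MS/MS scans for scheduled PRM targets under a physical
model that reproduces the instrument-parameter trade-offs of a quadrupole
orbitrap operated in parallel-reaction-monitoring mode:

* mass accuracy improves with resolving power and with ion statistics,
* fragment-ratio stability (spectral dot product) improves with injection
  time because per-scan ion counts are multinomial over the fragment pattern,
* signal-to-noise degrades with isolation width because wider quadrupole
  windows co-isolate interfering precursors,
* adjacent centroids closer than the analyzer peak width merge, so low
  resolving power integrates false fragment signal.

Every stochastic draw flows from a single :class:`numpy.random.Generator`
seeded from the truth record, so identical inputs give bit-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from pyteomics import mass as _pmass

from .errors import ConfigurationError

# Orbitrap transient duration (ms) by nominal resolving power at m/z 200.
TRANSIENT_MS: dict[int, float] = {
    15_000: 32.0,
    30_000: 64.0,
    60_000: 128.0,
    120_000: 256.0,
    240_000: 512.0,
}

REFERENCE_MZ = 200.0
#: Calibration constant of the centroid mass-error model (see mass_error_sigma).
MASS_ERROR_COEFF = 10.0

#: Heavy-label monoisotopic mass offsets (Da) by C-terminal residue:
#: 13C6 15N2 lysine and 13C6 15N4 arginine.
HEAVY_OFFSET = {"K": 8.0142, "R": 10.0083}

GRADIENT_MIN = 75.0
#: Chromatographic peak FWHM in minutes (Gaussian elution model).
PEAK_FWHM_MIN = 0.25
PEAK_SIGMA_MIN = PEAK_FWHM_MIN / 2.354820045


def transient_ms(resolution: float) -> float:
    """Transient time for a nominal resolving power; nearest tabulated value."""
    keys = np.array(sorted(TRANSIENT_MS))
    nearest = int(keys[np.argmin(np.abs(keys - resolution))])
    return TRANSIENT_MS[nearest]


@dataclass(frozen=True)
class AcquisitionSettings:
    """Instrument parameters of one PRM acquisition.

    resolution : resolving power specified at m/z 200 (dimensionless)
    injection_time : maximum ion accumulation time, ms
    isolation_width : full quadrupole isolation window, m/z
    agc_target : maximum accumulated charges per scan
    rt_window : scheduling window length, min
    scan_overhead : fixed per-scan overhead, ms
    """

    resolution: float = 240_000.0
    injection_time: float = 500.0
    isolation_width: float = 0.4
    agc_target: float = 3e6
    rt_window: float = 2.0
    scan_overhead: float = 10.0

    def __post_init__(self) -> None:
        for name in ("resolution", "injection_time", "isolation_width",
                     "agc_target", "rt_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scan_overhead < 0:
            raise ValueError("scan_overhead must be non-negative")

    @property
    def per_scan_ms(self) -> float:
        """Wall time of one scan: fill and transient overlap, the longer wins."""
        return max(self.injection_time, transient_ms(self.resolution)) + self.scan_overhead


@dataclass(frozen=True)
class PeptideSpec:
    """One precursor (peptide + label) with its monitored fragments."""

    sequence: str
    protein: str
    charge: int
    precursor_mz: float
    label: str  # "light" | "heavy"
    rt_true: float
    fragment_names: tuple[str, ...]
    fragment_mzs: tuple[float, ...]
    fragment_rel_intensities: tuple[float, ...]
    response_factor: float = 1.0
    protein_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.label not in ("light", "heavy"):
            raise ValueError("label must be 'light' or 'heavy'")
        if any(p < 0 for p in self.fragment_rel_intensities):
            raise ValueError("relative intensities must be non-negative")

    @property
    def key(self) -> tuple[str, str]:
        return (self.sequence, self.label)


@dataclass(frozen=True)
class Interferent:
    """A co-eluting matrix species that may be co-isolated with a target.

    mz_offset: precursor m/z distance from the target precursor; the species
    is co-isolated when ``|mz_offset| <= isolation_width / 2``.
    """

    target_sequence: str
    mz_offset: float
    rt: float
    intensity: float  # peak ion rate, ions/ms
    fragment_mzs: tuple[float, ...]
    #: Elution width (min). Co-isolated matrix is chromatographically broad
    #: by default, raising the background across the scheduling window.
    rt_sigma: float = 1.0


@dataclass
class SimulationTruth:
    """Ground truth of a simulated run: spiked amounts, interferents, seed."""

    amounts: dict[tuple[str, str], float]
    interferents: list[Interferent] = field(default_factory=list)
    seed: int = 0
    baseline_rate: float = 0.002  # electronic noise floor, ions/ms/fragment
    replicate_cv: float = 0.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amounts.values()):
            raise ValueError("amounts must be non-negative")


@dataclass(frozen=True)
class Scan:
    """Centroids recorded for one precursor at one retention time."""

    rt: float
    sequence: str
    label: str
    mz: np.ndarray
    intensity: np.ndarray
    signal_total: int  # drawn analyte ion count before noise/interference


@dataclass
class RawAcquisition:
    """A full simulated run: scans plus the settings/truth that produced it."""

    scans: list[Scan]
    settings: AcquisitionSettings
    truth: SimulationTruth
    panel: list[PeptideSpec]

    def scans_for(self, sequence: str, label: str) -> list[Scan]:
        return [s for s in self.scans if s.sequence == sequence and s.label == label]

    def spec_for(self, sequence: str, label: str) -> PeptideSpec:
        for p in self.panel:
            if p.sequence == sequence and p.label == label:
                return p
        raise KeyError((sequence, label))


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------

# 21 tryptic peptides covering the eight core UPR signaling proteins
# (receptors IRE1/PERK/ATF6, effectors ATF3/ATF4/CHOP/GADD34/XBP1).
# Four are real assay peptides; the rest are synthetic proteotypic-style
# sequences. APLSPSLLIR carries an ambiguous protein attribution in the
# source assays (GADD34 vs XBP1); it is assigned to GADD34 and flagged.
_PANEL_TABLE: list[tuple[str, str, int, bool]] = [
    ("GGFGVVFEAK", "PERK", 2, False),
    ("YLTDFEPIQCLGR", "PERK", 2, False),
    ("LSNPDLVALK", "PERK", 2, False),
    ("APLSPSLLIR", "GADD34", 2, True),
    ("GSDLSALEVSK", "GADD34", 2, False),
    ("AEPQPLSPASSSYSVSSPR", "ATF6", 2, False),
    ("LTEENLQSVK", "ATF6", 2, False),
    ("VDPSSLTTGEYR", "ATF6", 2, False),
    ("ILDSNQVLLGTK", "IRE1", 2, False),
    ("SGEYFDLVPTK", "IRE1", 2, False),
    ("NPFSTEELAVR", "IRE1", 2, False),
    ("TSDLEPVSGQK", "ATF4", 2, False),
    ("GLESPFDSLLDK", "ATF4", 2, False),
    ("AQTLDSVAEPR", "ATF4", 2, False),
    ("DSLEPTVNFGK", "ATF3", 2, False),
    ("QVEPLSDFSLR", "ATF3", 2, False),
    ("ELSDSFNQLAK", "CHOP", 2, False),
    ("TPDSEVLQGLR", "CHOP", 2, False),
    ("VSDGLTPEFNK", "XBP1", 2, False),
    ("LEAQPSDLFSR", "XBP1", 2, False),
    ("GNVDLSEPTQK", "XBP1", 2, False),
]


def _y_ion_mz(sequence: str, n: int, heavy: bool) -> float:
    mz = _pmass.fast_mass(sequence[-n:], ion_type="y", charge=1)
    if heavy:
        mz += HEAVY_OFFSET.get(sequence[-1], HEAVY_OFFSET["K"])
    return mz


def build_upr_panel(seed: int = 0) -> list[PeptideSpec]:
    """Build the 21-pair UPR quantification panel (42 precursors).

    Sequences and protein assignments are fixed; the seed controls retention
    times (spread over a 75-min gradient), fragment relative intensities and
    per-peptide response factors. Light/heavy partners share everything but
    the label mass offset.
    """
    rng = np.random.default_rng(seed)
    n = len(_PANEL_TABLE)
    rts = np.linspace(8.0, 70.0, n) + rng.uniform(-1.2, 1.2, n)
    order = rng.permutation(n)
    panel: list[PeptideSpec] = []
    for i, (seq, protein, charge, ambiguous) in enumerate(_PANEL_TABLE):
        rt = float(rts[order[i]])
        n_frag = 5
        lengths = list(range(3, 3 + n_frag))
        rel = rng.dirichlet(np.full(n_frag, 4.0))
        rel = rel / rel.sum()
        rf = float(rng.lognormal(0.0, 0.25))
        for label in ("light", "heavy"):
            heavy = label == "heavy"
            prec = _pmass.fast_mass(seq, charge=charge)
            if heavy:
                prec += HEAVY_OFFSET.get(seq[-1], HEAVY_OFFSET["K"]) / charge
            panel.append(
                PeptideSpec(
                    sequence=seq,
                    protein=protein,
                    charge=charge,
                    precursor_mz=prec,
                    label=label,
                    rt_true=rt,
                    fragment_names=tuple(f"y{k}" for k in lengths),
                    fragment_mzs=tuple(_y_ion_mz(seq, k, heavy) for k in lengths),
                    fragment_rel_intensities=tuple(float(x) for x in rel),
                    response_factor=rf,
                    protein_ambiguous=ambiguous,
                )
            )
    return panel


def panel_pairs(panel: list[PeptideSpec]) -> list[tuple[PeptideSpec, PeptideSpec]]:
    """Group a panel into (light, heavy) pairs by sequence."""
    by_seq: dict[str, dict[str, PeptideSpec]] = {}
    for p in panel:
        by_seq.setdefault(p.sequence, {})[p.label] = p
    pairs = []
    for seq, d in by_seq.items():
        if "light" in d and "heavy" in d:
            pairs.append((d["light"], d["heavy"]))
    return pairs


# ---------------------------------------------------------------------------
# Physics
# ---------------------------------------------------------------------------

def effective_resolution(resolution_at_ref: float, mz: float) -> float:
    """Orbitrap resolving power falls off as 1/sqrt(m/z) from the reference."""
    return resolution_at_ref * np.sqrt(REFERENCE_MZ / mz)


def mass_error_sigma(resolution_at_ref: float, mz: float, ion_count: float) -> float:
    """Standard deviation (ppm) of the centroid mass error.

    sigma = C * FWHM_ppm(effective resolution at mz) / sqrt(ion_count).
    Centroiding precision improves with ion statistics as 1/sqrt(N) and with
    the analyzer peak width; C is calibrated once so that at 60k resolving
    power and a 1000-ion reference the mean absolute error exceeds 5 ppm
    while at 240k it stays below 2 ppm.
    """
    if resolution_at_ref <= 0 or mz <= 0 or ion_count <= 0:
        raise ValueError("resolution, mz and ion_count must be positive")
    fwhm_ppm = 1e6 / effective_resolution(resolution_at_ref, mz)
    return MASS_ERROR_COEFF * fwhm_ppm / np.sqrt(ion_count)


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------

def _scan_times(panel: list[PeptideSpec], settings: AcquisitionSettings,
                ) -> dict[tuple[str, str], np.ndarray]:
    """Scheduled scan clock: per-precursor scan times honoring cycle time.

    Precursors are active within rt_true +/- rt_window/2. Within a segment of
    constant concurrency the cycle time is n_active * per-scan time and each
    active precursor occupies one slot per cycle.
    """
    per_scan_min = settings.per_scan_ms / 60_000.0
    windows = [(p.rt_true - settings.rt_window / 2,
                p.rt_true + settings.rt_window / 2, p.key) for p in panel]
    edges = sorted({w[0] for w in windows} | {w[1] for w in windows})
    times: dict[tuple[str, str], list[np.ndarray]] = {p.key: [] for p in panel}
    for a, b in zip(edges[:-1], edges[1:]):
        active = [k for (lo, hi, k) in windows if lo <= a and b <= hi]
        if not active:
            continue
        cycle = len(active) * per_scan_min
        starts = np.arange(a, b, cycle)
        for slot, key in enumerate(active):
            times[key].append(starts + slot * per_scan_min)
    return {k: np.concatenate(v) if v else np.empty(0) for k, v in times.items()}


def _merge_centroids(mz: np.ndarray, inten: np.ndarray,
                     resolution: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge centroids closer than the analyzer FWHM (unresolved at this R)."""
    if len(mz) < 2:
        return mz, inten
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    out_mz, out_int = [], []
    cm, ci = mz[0], inten[0]
    for m, i in zip(mz[1:], inten[1:]):
        fwhm = cm / effective_resolution(resolution, cm)
        if m - cm < fwhm:
            tot = ci + i
            cm = (cm * ci + m * i) / tot if tot > 0 else cm
            ci = tot
        else:
            out_mz.append(cm)
            out_int.append(ci)
            cm, ci = m, i
    out_mz.append(cm)
    out_int.append(ci)
    return np.array(out_mz), np.array(out_int)


def simulate_acquisition(panel: list[PeptideSpec], settings: AcquisitionSettings,
                         truth: SimulationTruth) -> RawAcquisition:
    """Simulate a scheduled PRM run over the panel.

    Per scan: accumulated analyte ions = min(agc_target, rate * injection_time)
    with rate = amount * response_factor * Gaussian(rt; rt_true, peak sigma),
    Poisson-sampled, then split multinomially over the fragment pattern.
    Interferents whose precursor offset falls inside the isolation half-width
    contribute their own fragment centroids; an electronic baseline adds a
    small floor per fragment. Centroid m/z is drawn with the mass-error model
    and unresolved centroids are merged at the analyzer peak width.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    for p in panel:
        if p.key not in truth.amounts:
            raise ConfigurationError(f"no truth amount for {p.key}")

    rng = np.random.default_rng(truth.seed)
    times = _scan_times(panel, settings)
    half_iso = settings.isolation_width / 2.0
    inj = settings.injection_time
    scans: list[Scan] = []

    for p in panel:
        t = times[p.key]
        if t.size == 0:
            continue
        amount = truth.amounts[p.key]
        rate = amount * p.response_factor * _gauss(t, p.rt_true, PEAK_SIGMA_MIN)
        expected = np.minimum(rate * inj, settings.agc_target)
        totals = rng.poisson(expected)
        pvals = np.asarray(p.fragment_rel_intensities, dtype=float)
        pvals = pvals / pvals.sum()
        frag_counts = rng.multinomial(totals, pvals)
        baseline = rng.poisson(truth.baseline_rate * inj, size=frag_counts.shape)
        frag_mzs = np.asarray(p.fragment_mzs)

        co_isolated = [itf for itf in truth.interferents
                       if itf.target_sequence == p.sequence
                       and abs(itf.mz_offset) <= half_iso]
        itf_counts = []
        for itf in co_isolated:
            lam = itf.intensity * inj * _gauss(t, itf.rt, itf.rt_sigma)
            itf_counts.append((np.asarray(itf.fragment_mzs),
                               rng.poisson(np.outer(lam / len(itf.fragment_mzs),
                                                    np.ones(len(itf.fragment_mzs))))))

        for i, rt in enumerate(t):
            mz_list, int_list = [], []
            counts_i = frag_counts[i] + baseline[i]
            for j, c in enumerate(counts_i):
                if c <= 0:
                    continue
                sd = mass_error_sigma(settings.resolution, frag_mzs[j], c) * 1e-6
                mz_list.append(frag_mzs[j] * (1.0 + rng.normal(0.0, sd)))
                int_list.append(float(c))
            for itf_mzs, itf_c in itf_counts:
                for j, c in enumerate(itf_c[i]):
                    if c <= 0:
                        continue
                    sd = mass_error_sigma(settings.resolution, itf_mzs[j], c) * 1e-6
                    mz_list.append(itf_mzs[j] * (1.0 + rng.normal(0.0, sd)))
                    int_list.append(float(c))
            mz_arr, int_arr = _merge_centroids(np.array(mz_list), np.array(int_list),
                                               settings.resolution)
            scans.append(Scan(rt=float(rt), sequence=p.sequence, label=p.label,
                              mz=mz_arr, intensity=int_arr,
                              signal_total=int(totals[i])))

    scans.sort(key=lambda s: (s.rt, s.sequence, s.label))
    return RawAcquisition(scans=scans, settings=settings, truth=truth, panel=panel)


# ---------------------------------------------------------------------------
# Experiment-level generators
# ---------------------------------------------------------------------------

#: Default endogenous (light) amounts on column, amol, by protein — chosen to
#: span the copy-number range of the UPR panel (~400 to ~60,000 copies/cell
#: at 5000 cells on column).
DEFAULT_LIGHT_AMOL = {
    "ATF6": 498.0, "PERK": 166.0, "ATF4": 80.0, "IRE1": 50.0,
    "ATF3": 40.0, "CHOP": 25.0, "GADD34": 12.0, "XBP1": 3.3,
}

#: Internal-standard spike range, amol (heavy), matched to the assay design.
IS_AMOL_MIN, IS_AMOL_MAX = 29.5, 490.4


def default_truth(panel: list[PeptideSpec], seed: int = 0,
                  with_interference: bool = True) -> SimulationTruth:
    """Realistic default ground truth for the UPR panel.

    Light amounts follow the protein copy-number span; heavy internal
    standards are log-spaced over the spike range. Each pair optionally gets
    one matrix interferent near (but outside +/-0.2 m/z of) its precursor.
    """
    rng = np.random.default_rng(_derive_seed(seed, "truth"))
    amounts: dict[tuple[str, str], float] = {}
    interferents: list[Interferent] = []
    pairs = panel_pairs(panel)
    is_levels = np.geomspace(IS_AMOL_MIN, IS_AMOL_MAX, len(pairs))
    for i, (light, heavy) in enumerate(pairs):
        amounts[light.key] = DEFAULT_LIGHT_AMOL.get(light.protein, 50.0)
        amounts[heavy.key] = float(is_levels[i])
        if with_interference:
            offs = float(rng.uniform(0.25, 0.7) * rng.choice([-1.0, 1.0]))
            ppm_shift = rng.uniform(8.0, 25.0, size=3) * rng.choice([-1, 1], size=3)
            fmzs = tuple(float(m * (1 + s * 1e-6))
                         for m, s in zip(light.fragment_mzs[:3], ppm_shift))
            interferents.append(Interferent(
                target_sequence=light.sequence, mz_offset=offs,
                rt=light.rt_true + float(rng.uniform(-0.1, 0.1)),
                intensity=float(rng.uniform(5.0, 20.0)), fragment_mzs=fmzs))
    return SimulationTruth(amounts=amounts, interferents=interferents, seed=seed)


def _derive_seed(seed: int, tag: str) -> int:
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def simulate_dilution_series(pair: tuple[PeptideSpec, PeptideSpec],
                             start_conc: float, factor: float, steps: int,
                             settings: AcquisitionSettings, seed: int,
                             heavy_amol: float = 100.0,
                             injection_ul: float = 1.0,
                             with_interference: bool = True,
                             level_cv: float = 0.0,
                             ) -> list[tuple[float, RawAcquisition]]:
    """Simulate a dilution series for one light/heavy pair.

    Level k carries nominal concentration start_conc / factor**k (amol/ul);
    the amount on column is nominal * injection_ul. The heavy standard stays
    constant across levels. ``level_cv`` adds multiplicative (pipetting)
    noise to the true on-column amount on top of the inherent counting
    noise; the nominal label is unaffected. Returns steps+1
    (nominal_amol, acquisition) tuples, highest level first.
    """
    if start_conc <= 0:
        raise ValueError("start_conc must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    light, heavy = pair
    out = []
    for k in range(steps + 1):
        nominal = start_conc / factor**k
        interferents = []
        if with_interference:
            rng = np.random.default_rng(_derive_seed(seed, f"itf:{light.sequence}"))
            ppm_shift = rng.uniform(8.0, 25.0, size=3) * rng.choice([-1, 1], size=3)
            fmzs = tuple(float(m * (1 + s * 1e-6))
                         for m, s in zip(light.fragment_mzs[:3], ppm_shift))
            interferents.append(Interferent(
                target_sequence=light.sequence,
                mz_offset=float(rng.uniform(0.25, 0.7)),
                rt=light.rt_true + float(rng.uniform(-0.1, 0.1)),
                intensity=float(rng.uniform(5.0, 15.0)), fragment_mzs=fmzs))
        on_column = nominal * injection_ul
        if level_cv > 0:
            sigma = np.sqrt(np.log1p(level_cv**2))
            lrng = np.random.default_rng(_derive_seed(seed, f"cv:{k}"))
            on_column *= float(np.exp(lrng.normal(-0.5 * sigma**2, sigma)))
        truth = SimulationTruth(
            amounts={light.key: on_column, heavy.key: heavy_amol},
            interferents=interferents,
            seed=_derive_seed(seed, f"level:{k}"))
        out.append((nominal, simulate_acquisition([light, heavy], settings, truth)))
    return out


def simulate_condition_experiment(panel: list[PeptideSpec],
                                  fold_changes: dict[str, float],
                                  replicates: int,
                                  settings: AcquisitionSettings,
                                  seed: int,
                                  cv: float = 0.10,
                                  ) -> dict[str, list[RawAcquisition]]:
    """Simulate a control/treated comparison with protein-level fold changes.

    Light amounts in the treated condition are the control amounts scaled by
    the protein's fold change; heavy standards are identical across
    conditions. Each replicate applies multiplicative log-normal noise with
    the requested CV to the light amounts; the noiseless truth ratio
    treated/control equals the programmed fold change exactly.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    proteins = {p.protein for p in panel}
    unknown = set(fold_changes) - proteins
    if unknown:
        raise ConfigurationError(f"fold changes for unknown proteins: {sorted(unknown)}")
    base = default_truth(panel, seed=seed, with_interference=False)
    sigma = np.sqrt(np.log1p(cv**2))
    out: dict[str, list[RawAcquisition]] = {"control": [], "treated": []}
    for condition in ("control", "treated"):
        for r in range(replicates):
            rep_seed = _derive_seed(seed, f"{condition}:{r}")
            rng = np.random.default_rng(rep_seed)
            amounts = {}
            for key, amol in base.amounts.items():
                seq, label = key
                if label == "heavy":
                    amounts[key] = amol
                    continue
                protein = next(p.protein for p in panel if p.sequence == seq)
                fold = fold_changes.get(protein, 1.0) if condition == "treated" else 1.0
                noise = float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if cv > 0 else 1.0
                amounts[key] = amol * fold * noise
            truth = SimulationTruth(amounts=amounts, interferents=[],
                                    seed=rep_seed, replicate_cv=cv)
            out[condition].append(simulate_acquisition(panel, settings, truth))
    return out
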