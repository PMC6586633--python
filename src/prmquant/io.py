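"""Readers/writers for transition lists, chromatograms and run configs.

The native interchange format is long-form delimited text with explicit
units in the headers ('.' decimal separator, UTF-8); mzML chromatogram
lists are supported read-only through pyteomics.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, UnsupportedContentError
from .signal import ChromatogramTrace, QcThresholds, extract_precursor_traces
from .simulator import AcquisitionSettings, Interferent, RawAcquisition, SimulationTruth
from .quantify import LOADED_PEPTIDE_UG, PROTEIN_PER_CELL_NG

TRANSITION_COLUMNS = ["peptide", "protein", "precursor_mz", "charge",
                      "fragment", "fragment_mz", "label", "is_amount_amol"]
TRACE_COLUMNS = ["scan_rt_min", "peptide", "label", "fragment",
                 "measured_mz", "intensity"]


@dataclass
class RunConfig:
    """Everything needed to replay a run: instrument settings, QC
    thresholds, quantification constants and the seed."""

    settings: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    loq_max_deviation_pct: float = 20.0
    protein_per_cell_ng: float = PROTEIN_PER_CELL_NG
    loaded_peptide_ug: float = LOADED_PEPTIDE_UG
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "settings": asdict(self.settings),
            "thresholds": asdict(self.thresholds),
            "loq_max_deviation_pct": self.loq_max_deviation_pct,
            "protein_per_cell_ng": self.protein_per_cell_ng,
            "loaded_peptide_ug": self.loaded_peptide_ug,
            "seed": self.seed,
        }, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(settings=AcquisitionSettings(**d["settings"]),
                   thresholds=QcThresholds(**d["thresholds"]),
                   loq_max_deviation_pct=d["loq_max_deviation_pct"],
                   protein_per_cell_ng=d["protein_per_cell_ng"],
                   loaded_peptide_ug=d["loaded_peptide_ug"],
                   seed=d["seed"])


# ---------------------------------------------------------------------------
# Transition lists
# ---------------------------------------------------------------------------

def read_transition_list(path: str | Path) -> pd.DataFrame:
    """Read and validate a delimited transition list.

    Required columns: peptide, protein, precursor_mz, charge, fragment,
    fragment_mz, label, is_amount_amol (blank allowed on light rows; heavy
    rows must carry the spiked amount). Unknown columns are preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRANSITION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ("precursor_mz", "fragment_mz", "is_amount_amol"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(f"malformed number in column {col!r} at line {line}")
        df[col] = coerced
    heavy_blank = (df["label"] == "heavy") & df["is_amount_amol"].isna()
    if heavy_blank.any():
        line = int(heavy_blank.idxmax()) + 2
        raise SchemaError(f"heavy row without is_amount_amol at line {line}")
    bad_label = ~df["label"].isin(["light", "heavy"])
    if bad_label.any():
        line = int(bad_label.idxmax()) + 2
        raise SchemaError(f"label must be light/heavy at line {line}")
    return df


def panel_to_transition_list(panel, truth: SimulationTruth | None = None) -> pd.DataFrame:
    """Flatten PeptideSpec entries into the transition-list table."""
    rows = []
    for p in panel:
        isa = None
        if truth is not None and p.label == "heavy":
            isa = truth.amounts.get(p.key)
        for name, mz, rel in zip(p.fragment_names, p.fragment_mzs,
                                 p.fragment_rel_intensities):
            rows.append({"peptide": p.sequence, "protein": p.protein,
                         "precursor_mz": p.precursor_mz, "charge": p.charge,
                         "fragment": name, "fragment_mz": mz, "label": p.label,
                         "is_amount_amol": isa, "rel_intensity": rel,
                         "rt_min": p.rt_true})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------

def write_acquisition(acquisition: RawAcquisition, path: str | Path,
                      tol_ppm: float = 10.0) -> None:
    """Write an acquisition as long-form per-transition traces.

    Columns: scan_rt_min, peptide, label, fragment, measured_mz, intensity.
    Centroids are assigned to fragments by ppm proximity (the same rule the
    extractor uses), so the file round-trips into identical traces.
    """
    rows = []
    for spec in acquisition.panel:
        if not acquisition.scans_for(spec.sequence, spec.label):
            continue
        for tr in extract_precursor_traces(acquisition, spec, tol_ppm):
            for rt, mz, inten in zip(tr.rts, tr.measured_mzs, tr.intensities):
                rows.append((rt, tr.peptide, tr.label, tr.fragment, mz, inten))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_chromatograms(path: str | Path, format: str = "long-csv",
                       ) -> list[ChromatogramTrace]:
    """Read per-transition traces from long-form CSV or an mzML
    chromatogram list (id convention: ``peptide|label|fragment``)."""
    if format == "long-csv":
        return _read_traces_csv(path)
    if format == "mzml":
        return _read_traces_mzml(path)
    raise ValueError(f"unknown format {format!r}")


def _read_traces_csv(path: str | Path) -> list[ChromatogramTrace]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # propagate with context
        raise SchemaError(f"unreadable chromatogram file {path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    traces = []
    for (pep, label, frag), g in df.groupby(["peptide", "label", "fragment"],
                                            sort=True):
        g = g.sort_values("scan_rt_min")
        traces.append(ChromatogramTrace(
            peptide=pep, label=label, fragment=frag,
            rts=g["scan_rt_min"].to_numpy(float),
            intensities=g["intensity"].to_numpy(float),
            measured_mzs=g["measured_mz"].to_numpy(float)))
    return traces


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, plain or zlib)."""
    import base64
    import zlib

    names = {cv.get("name") for cv in bda.iter()
             if cv.tag.endswith("cvParam")}
    binary = next((el for el in bda.iter() if el.tag.endswith("}binary")), None)
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "zlib compression" in names:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in names else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_traces_mzml(path: str | Path) -> list[ChromatogramTrace]:
    # minimal read-only chromatogram-list reader (time + intensity arrays);
    # pulls id convention peptide|label|fragment
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SchemaError(f"unreadable mzML {path}: {exc}") from exc
    traces = []
    for chrom in tree.iter("{*}chromatogram"):
        parts = chrom.get("id", "").split("|")
        arrays: dict[str, np.ndarray] = {}
        for bda in chrom.iter("{*}binaryDataArray"):
            names = {cv.get("name") for cv in bda.iter("{*}cvParam")}
            if "time array" in names:
                arrays["time"] = _decode_binary_array(bda)
            elif "intensity array" in names:
                arrays["intensity"] = _decode_binary_array(bda)
        if len(parts) != 3 or "time" not in arrays or "intensity" not in arrays:
            continue
        pep, label, frag = parts
        rts = arrays["time"]
        traces.append(ChromatogramTrace(
            peptide=pep, label=label, fragment=frag, rts=rts,
            intensities=arrays["intensity"], measured_mzs=np.zeros_like(rts)))
    if not traces:
        raise UnsupportedContentError(f"no chromatogram list in {path}")
    return traces


# ---------------------------------------------------------------------------
# Truth sidecar
# ---------------------------------------------------------------------------

def _plain(obj):
    """Recursively coerce numpy scalars/sequences to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_truth(truth: SimulationTruth, settings: AcquisitionSettings,
                path: str | Path) -> None:
    """Structured-text sidecar: seed, settings, amounts (amol), interferents."""
    Path(path).write_text(yaml.safe_dump(_plain({
        "seed": truth.seed,
        "settings": asdict(settings),
        "baseline_rate": truth.baseline_rate,
        "amounts_amol": {f"{seq}/{label}": float(a)
                         for (seq, label), a in sorted(truth.amounts.items())},
        "interferents": [asdict(i) | {"fragment_mzs": list(i.fragment_mzs)}
                         for i in truth.interferents],
    }), sort_keys=True))


def read_truth(path: str | Path) -> tuple[SimulationTruth, AcquisitionSettings]:
    d = yaml.safe_load(Path(path).read_text())
    amounts = {}
    for key, a in d["amounts_amol"].items():
        seq, label = key.rsplit("/", 1)
        amounts[(seq, label)] = float(a)
    interferents = [Interferent(target_sequence=i["target_sequence"],
                                mz_offset=i["mz_offset"], rt=i["rt"],
                                intensity=i["intensity"],
                                fragment_mzs=tuple(i["fragment_mzs"]),
                                rt_sigma=i.get("rt_sigma", 1.0))
                    for i in d.get("interferents", [])]
    truth = SimulationTruth(amounts=amounts, interferents=interferents,
                            seed=d["seed"], baseline_rate=d.get("baseline_rate", 0.002))
    return truth, AcquisitionSettings(**d["settings"])
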