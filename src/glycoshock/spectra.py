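"""MGF fragment spectra and diagnostic (oxonium) ion scanning.

Lewis-type fucosylation leaves characteristic low-mass fragments in MS/MS
spectra: m/z 512.20 (Hex-(Fuc)-HexNAc, [M+H]+) and 803.29 (NeuAc-Hex-(Fuc)-
HexNAc) in positive-mode HCD glycoproteomics, and m/z 364.2 (Lewis x) vs
348.2 (Lewis a) B/C-type ions in negative-mode CID glycomics. Scanning
fragment spectra for these ions gives a search-engine-free readout of Lewis
glyco-epitope content.

Two scanning parameterisations are provided: a "manual" mode (peaks with
intensity strictly above 1% of the base peak, inside an inclusive +-0.01 Th
window for HCD or +-0.20 Th for CID) and a "glycounter" mode (10 ppm window,
absolute intensity floor, signal-to-noise and top-N gates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mgf as _mgf

from .errors import MalformedSpectrumError

__all__ = [
    "SpectrumRecord",
    "DiagnosticIonConfig",
    "IonHit",
    "IonHitReport",
    "read_mgf",
    "write_mgf",
    "scan_spectrum",
    "diagnostic_fraction",
    "lex_lea_intensity_pairs",
    "HCD_LEWIS_TARGETS",
    "CID_LEWIS_TARGETS",
]

#: HCD glycoproteomics diagnostic ions: Lewis (Hex-(Fuc)-HexNAc) and
#: sialyl-Lewis (NeuAc-Hex-(Fuc)-HexNAc) oxonium fragments.
HCD_LEWIS_TARGETS = (512.20, 803.29)
#: CID glycomics diagnostic ions: Lewis x (364.2) and Lewis a (348.2).
CID_LEWIS_TARGETS = (364.2, 348.2)


@dataclass
class SpectrumRecord:
    """One MS/MS peak list with precursor metadata.

    Peaks are stored as an (n, 2) float array of (m/z, intensity), sorted
    ascending by m/z on construction.
    """

    sample_id: str
    scan_id: str
    precursor_mz: float
    charge: Optional[int]
    peaks: np.ndarray

    def __post_init__(self):
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.size and np.any(peaks[:, 1] < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]

    @property
    def title(self) -> str:
        return f"{self.sample_id}:{self.scan_id}"


def _prevalidate_mgf(path: Path) -> None:
    """Structural pass over an MGF file, reporting the first bad block."""
    block = -1
    in_block = False
    saw_pepmass = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MalformedSpectrumError(block, "nested BEGIN IONS")
                block += 1
                in_block = True
                saw_pepmass = False
            elif line == "END IONS":
                if not in_block:
                    raise MalformedSpectrumError(block + 1, "END IONS without BEGIN IONS")
                if not saw_pepmass:
                    raise MalformedSpectrumError(block, "missing PEPMASS")
                in_block = False
            elif in_block:
                if "=" in line:
                    if line.startswith("PEPMASS="):
                        saw_pepmass = True
                    continue
                parts = line.split()
                try:
                    [float(p) for p in parts[:2]]
                    if len(parts) < 2:
                        raise ValueError
                except ValueError:
                    raise MalformedSpectrumError(
                        block, f"non-numeric peak line {line!r}"
                    ) from None
    if in_block:
        raise MalformedSpectrumError(block, "missing END IONS")


def _split_title(title: str, index: int) -> Tuple[str, str]:
    if ":" in title:
        sample, _, scan = title.partition(":")
        return sample, scan
    return title or "unknown", str(index)


def read_mgf(path) -> List[SpectrumRecord]:
    """Read an MGF file into :class:`SpectrumRecord` objects.

    Titles of the form ``sample:scan`` populate ``sample_id``/``scan_id``;
    a missing CHARGE line is tolerated (charge ``None``). Malformed blocks
    (unterminated, missing PEPMASS, non-numeric peak lines) raise
    :class:`MalformedSpectrumError` with the zero-based block index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_mgf(path)
    records: List[SpectrumRecord] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            if "pepmass" not in params:
                raise MalformedSpectrumError(i, "missing PEPMASS")
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            else:
                charge = None
            sample_id, scan_id = _split_title(str(params.get("title", "")), i)
            peaks = np.column_stack([spec["m/z array"], spec["intensity array"]])
            records.append(
                SpectrumRecord(
                    sample_id=sample_id,
                    scan_id=scan_id,
                    precursor_mz=precursor,
                    charge=charge,
                    peaks=peaks,
                )
            )
    return records


def write_mgf(records: Iterable[SpectrumRecord], path) -> None:
    """Write records to MGF (BEGIN IONS / TITLE=sample:scan / PEPMASS / CHARGE)."""
    spectra = []
    for rec in records:
        params = {"title": rec.title, "pepmass": rec.precursor_mz}
        if rec.charge is not None:
            params["charge"] = rec.charge
        spectra.append(
            {
                "params": params,
                "m/z array": rec.peaks[:, 0],
                "intensity array": rec.peaks[:, 1],
            }
        )
    with open(path, "w") as fh:
        _mgf.write(spectra, fh)


@dataclass
class DiagnosticIonConfig:
    """Parameters of a diagnostic-ion scan.

    ``tolerance_mode`` is ``"absolute_th"`` (window of +-tolerance_value Th)
    or ``"ppm"`` (window of +-target * tolerance_value * 1e-6). The window is
    inclusive at its boundary; the relative-intensity threshold is strict
    (a peak at exactly ``min_relative_intensity`` x base peak does not hit).
    ``snr_requirement`` approximates a signal-to-noise gate as intensity >=
    snr x median peak intensity of the spectrum. ``tic_fraction_cap``, when
    set, discards all hits of a spectrum whose summed matched intensity is
    below that fraction of the total ion current.
    """

    targets: Sequence[float] = HCD_LEWIS_TARGETS
    tolerance_mode: str = "absolute_th"
    tolerance_value: float = 0.01
    min_relative_intensity: float = 0.01
    min_absolute_intensity: float = 0.0
    top_n_restriction: Optional[int] = None
    snr_requirement: Optional[float] = None
    tic_fraction_cap: Optional[float] = None

    def __post_init__(self):
        if self.tolerance_mode not in ("absolute_th", "ppm"):
            raise ValueError(f"unknown tolerance_mode {self.tolerance_mode!r}")
        if self.tolerance_value <= 0:
            raise ValueError("tolerance_value must be > 0")
        if not 0 <= self.min_relative_intensity <= 1:
            raise ValueError("min_relative_intensity must be in [0, 1]")

    def window(self, target: float) -> float:
        if self.tolerance_mode == "ppm":
            return target * self.tolerance_value * 1e-6
        return self.tolerance_value

    # -- standard parameterisations ---------------------------------------
    @classmethod
    def manual_hcd(cls) -> "DiagnosticIonConfig":
        """Manual-script HCD mode: +-0.01 Th, intensity > 1% of base peak."""
        return cls(targets=HCD_LEWIS_TARGETS, tolerance_value=0.01)

    @classmethod
    def manual_cid(cls) -> "DiagnosticIonConfig":
        """Manual-script CID glycomics mode: +-0.20 Th, > 1% of base peak."""
        return cls(targets=CID_LEWIS_TARGETS, tolerance_value=0.20)

    @classmethod
    def glycounter_hcd(cls) -> "DiagnosticIonConfig":
        """GlyCounter-style mode: 10 ppm, S/N >= 3, intensity >= 1000, top-50."""
        return cls(
            targets=HCD_LEWIS_TARGETS,
            tolerance_mode="ppm",
            tolerance_value=10.0,
            min_relative_intensity=0.0,
            min_absolute_intensity=1000.0,
            top_n_restriction=50,
            snr_requirement=3.0,
        )


@dataclass(frozen=True)
class IonHit:
    """Match of one target ion in one spectrum."""

    hit: bool
    matched_mz: float = math.nan
    matched_intensity: float = 0.0
    relative_intensity: float = 0.0


@dataclass
class IonHitReport:
    """Per-target hits for one spectrum."""

    sample_id: str
    scan_id: str
    hits: Dict[float, IonHit] = field(default_factory=dict)

    def has_hit(self, target: float) -> bool:
        return self.hits[target].hit


def scan_spectrum(record: SpectrumRecord, cfg: DiagnosticIonConfig) -> IonHitReport:
    """Scan one spectrum for the configured diagnostic ions.

    A target hits iff some peak lies within the (inclusive) m/z window and
    passes every intensity gate; among qualifying peaks the most intense one
    is reported, ties broken toward the lower m/z.
    """
    peaks = record.peaks
    if peaks.shape[0] == 0:
        raise ValueError(f"spectrum {record.title} has no peaks")
    mz, inten = peaks[:, 0], peaks[:, 1]
    base = float(inten.max())
    eligible = inten > cfg.min_relative_intensity * base
    if cfg.min_absolute_intensity:
        eligible &= inten >= cfg.min_absolute_intensity
    if cfg.snr_requirement is not None:
        eligible &= inten >= cfg.snr_requirement * float(np.median(inten))
    if cfg.top_n_restriction is not None:
        n = min(cfg.top_n_restriction, len(inten))
        top_idx = np.argsort(-inten, kind="stable")[:n]
        top_mask = np.zeros(len(inten), dtype=bool)
        top_mask[top_idx] = True
        eligible &= top_mask

    report = IonHitReport(sample_id=record.sample_id, scan_id=record.scan_id)
    for target in cfg.targets:
        tol = cfg.window(target)
        in_window = (np.abs(mz - target) <= tol) & eligible
        if not in_window.any():
            report.hits[target] = IonHit(hit=False)
            continue
        idx = np.flatnonzero(in_window)
        # most intense qualifying peak; ties resolved to the lower m/z
        # (peaks are m/z-sorted, argmax returns the first maximum)
        best = idx[int(np.argmax(inten[idx]))]
        report.hits[target] = IonHit(
            hit=True,
            matched_mz=float(mz[best]),
            matched_intensity=float(inten[best]),
            relative_intensity=float(inten[best] / base),
        )
    if cfg.tic_fraction_cap is not None:
        tic = float(inten.sum())
        matched = sum(h.matched_intensity for h in report.hits.values() if h.hit)
        if matched < cfg.tic_fraction_cap * tic:
            report.hits = {t: IonHit(hit=False) for t in report.hits}
    return report


def diagnostic_fraction(
    spectra: Sequence[SpectrumRecord], cfg: DiagnosticIonConfig
) -> Dict[float, float]:
    """Fraction of spectra containing each diagnostic ion.

    A spectrum counts at most once per target regardless of how many peaks
    qualify, matching the "ratio of MS/MS spectra featuring the diagnostic
    ion" readout.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("diagnostic_fraction requires at least one spectrum")
    counts = {t: 0 for t in cfg.targets}
    for rec in spectra:
        report = scan_spectrum(rec, cfg)
        for t in cfg.targets:
            if report.has_hit(t):
                counts[t] += 1
    return {t: counts[t] / len(spectra) for t in cfg.targets}


def lex_lea_intensity_pairs(
    spectra: Sequence[SpectrumRecord],
    cfg: Optional[DiagnosticIonConfig] = None,
    lex_target: float = 364.2,
    lea_target: float = 348.2,
) -> np.ndarray:
    """Per-spectrum matched intensities of the Lewis x vs Lewis a ions.

    Returns an (n, 2) array of (I_lex, I_lea), zero where a target did not
    hit; suited as input to a paired one-sided Wilcoxon signed-rank test of
    Lewis x dominance.
    """
    if cfg is None:
        cfg = DiagnosticIonConfig.manual_cid()
    for t in (lex_target, lea_target):
        if t not in cfg.targets:
            raise ValueError(f"target {t} missing from scan config")
    pairs = []
    for rec in spectra:
        report = scan_spectrum(rec, cfg)
        pairs.append(
            (report.hits[lex_target].matched_intensity,
             report.hits[lea_target].matched_intensity)
        )
    return np.asarray(pairs, dtype=float)
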