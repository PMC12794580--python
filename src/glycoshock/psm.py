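"""GlycoPSM tables and Lewis-glycoform quantification by spectral counting.

A glycoPSM (glycopeptide-to-spectrum match) is the counting unit: the
relative level of Lewis glycoforms in a sample is the fraction of that
sample's glycoPSMs whose glycan carries antennary (Lewis) fucosylation, and
the per-protein carrier distribution is the share of Lewis glycoPSMs
assigned to each protein. Search-engine outputs are consumed as tables in a
canonical TSV schema; Byonic-like and I-GPA-like column dialects are mapped
onto it. FDR filtering is assumed to have happened upstream in the engines;
an optional score threshold is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import pandas as pd

from .errors import GlycoshockError
from .glycans import parse_composition
from .spectra import DiagnosticIonConfig, SpectrumRecord, scan_spectrum

__all__ = [
    "GlycoPSMTable",
    "REQUIRED_COLUMNS",
    "FUCOSE_TYPES",
    "read_glycopsm_table",
    "lewis_level",
    "protein_lewis_distribution",
    "protein_lewis_level",
    "narrow_filter",
    "score_filter",
]

REQUIRED_COLUMNS = [
    "sample_id", "scan_id", "peptide", "protein", "site",
    "composition", "fucose_type", "score",
]

FUCOSE_TYPES = {"core", "lewis", "none", "ambiguous"}

#: Column-name mappings from engine-flavoured exports onto the canonical schema.
DIALECTS: Dict[str, Dict[str, str]] = {
    "canonical": {c: c for c in REQUIRED_COLUMNS},
    "byonic_like": {
        "Sample": "sample_id",
        "Scan #": "scan_id",
        "Peptide": "peptide",
        "Protein Name": "protein",
        "Glycan Site": "site",
        "Glycans": "composition",
        "Score": "score",
        # Byonic reports no core-vs-antennary call; fucose_type is derived
        # from the composition (none when Fuc = 0, otherwise ambiguous).
    },
    "igpa_like": {
        "SampleID": "sample_id",
        "ScanNum": "scan_id",
        "PeptideSeq": "peptide",
        "ProteinID": "protein",
        "GlySite": "site",
        "GlycanComposition": "composition",
        "FucoseClass": "fucose_type",
        "SScore": "score",
    },
}


@dataclass
class GlycoPSMTable:
    """Canonical glycoPSM rows plus the dialect they were read from."""

    df: pd.DataFrame
    dialect: str = "canonical"

    def __len__(self):
        return len(self.df)

    def validate(self) -> "GlycoPSMTable":
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise GlycoshockError(f"glycoPSM table missing required column(s): {missing}")
        bad_types = set(self.df["fucose_type"]) - FUCOSE_TYPES
        if bad_types:
            raise GlycoshockError(f"unknown fucose_type value(s): {sorted(bad_types)}")
        lewis = self.df[self.df["fucose_type"] == "lewis"]
        for comp_text in lewis["composition"].unique():
            if parse_composition(comp_text).fuc < 1:
                raise GlycoshockError(
                    f"lewis-typed PSM with fucose-free composition {comp_text!r}"
                )
        return self


def read_glycopsm_table(path, dialect: str = "canonical") -> GlycoPSMTable:
    """Read a glycoPSM TSV in the given dialect into the canonical schema.

    Unmapped required columns raise an error naming the canonical column;
    extra columns are preserved as pass-through.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    # keep_default_na: a literal "None" fucose class must stay a string
    df = pd.read_csv(
        Path(path), sep="\t", keep_default_na=False, na_values=[""],
        dtype={"sample_id": str, "SampleID": str, "Sample": str},
    )
    mapping = DIALECTS[dialect]
    rename = {src: dst for src, dst in mapping.items() if src in df.columns}
    df = df.rename(columns=rename)
    if dialect == "byonic_like" and "fucose_type" not in df.columns:
        df["fucose_type"] = [
            "none" if parse_composition(c).fuc == 0 else "ambiguous"
            for c in df["composition"]
        ]
    if dialect == "igpa_like" and "fucose_type" in df.columns:
        df["fucose_type"] = df["fucose_type"].astype(str).str.lower()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise GlycoshockError(
            f"glycoPSM table {path} missing required column(s): {missing}"
        )
    df["sample_id"] = df["sample_id"].astype(str)
    df["scan_id"] = df["scan_id"].astype(str)
    return GlycoPSMTable(df=df, dialect=dialect).validate()


def _frame(table) -> pd.DataFrame:
    return table.df if isinstance(table, GlycoPSMTable) else table


def lewis_level(
    table,
    include_ambiguous: bool = False,
    samples: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Per-sample Lewis glycoform level: Lewis glycoPSMs / total glycoPSMs.

    Rows typed ``ambiguous`` stay in the denominator but join the numerator
    only when ``include_ambiguous`` is set (the default is conservative
    toward the Lewis estimate). When ``samples`` is given, samples with zero
    PSMs raise an error listing them.
    """
    df = _frame(table)
    if df.empty:
        raise GlycoshockError("empty glycoPSM table")
    numerator_types = {"lewis", "ambiguous"} if include_ambiguous else {"lewis"}
    total = df.groupby("sample_id").size()
    lewis = (
        df[df["fucose_type"].isin(numerator_types)].groupby("sample_id").size()
    ).reindex(total.index, fill_value=0)
    if samples is not None:
        empty = [s for s in samples if s not in total.index]
        if empty:
            raise GlycoshockError(f"samples with zero glycoPSMs: {empty}")
    return (lewis / total).rename("lewis_level")


def protein_lewis_distribution(table) -> pd.Series:
    """Share of Lewis glycoPSMs carried by each protein, sorted descending."""
    df = _frame(table)
    lewis = df[df["fucose_type"] == "lewis"]
    if lewis.empty:
        raise GlycoshockError("no Lewis-typed glycoPSMs in table")
    counts = lewis.groupby("protein").size()
    shares = (counts / counts.sum()).sort_values(ascending=False, kind="stable")
    return shares.rename("lewis_share")


def protein_lewis_level(table, protein: str) -> pd.Series:
    """Per-sample level of one protein's Lewis glycoforms.

    Numerator: Lewis glycoPSMs assigned to ``protein``; denominator: all
    glycoPSMs of the sample. Summing over every protein recovers
    :func:`lewis_level` exactly. A protein absent from the table yields zeros
    with a warning rather than an error.
    """
    df = _frame(table)
    if df.empty:
        raise GlycoshockError("empty glycoPSM table")
    if protein not in set(df["protein"]):
        warnings.warn(f"protein {protein!r} absent from glycoPSM table; returning zeros")
    total = df.groupby("sample_id").size()
    hits = (
        df[(df["fucose_type"] == "lewis") & (df["protein"] == protein)]
        .groupby("sample_id")
        .size()
    ).reindex(total.index, fill_value=0)
    return (hits / total).rename(f"{protein}_lewis_level")


def narrow_filter(
    table,
    spectra: Mapping[str, SpectrumRecord] | Sequence[SpectrumRecord],
    cfg: Optional[DiagnosticIonConfig] = None,
    target: float = 512.20,
    on_missing: str = "error",
) -> GlycoPSMTable:
    """Retain glycoPSMs whose fragment spectrum contains the Lewis ion.

    Emulates the targeted ("narrow") search strategy that considers only
    MS/MS spectra carrying the m/z 512.20 Lewis oxonium ion; the default
    scan window is +-0.02 Th with the >1%-of-base-peak intensity rule.
    ``on_missing`` controls unresolvable scan ids: ``"error"`` raises,
    ``"skip"`` drops the row with a warning.
    """
    if cfg is None:
        cfg = DiagnosticIonConfig(targets=(target,), tolerance_value=0.02)
    if target not in cfg.targets:
        raise ValueError(f"narrow-filter target {target} missing from scan config")
    if on_missing not in ("error", "skip"):
        raise ValueError("on_missing must be 'error' or 'skip'")
    if not isinstance(spectra, Mapping):
        spectra = {(rec.sample_id, rec.scan_id): rec for rec in spectra}
    df = _frame(table)
    keep = []
    n_missing = 0
    hit_cache: Dict[tuple, bool] = {}
    for row in df.itertuples():
        key = (row.sample_id, row.scan_id)
        rec = spectra.get(key)
        if rec is None:
            if on_missing == "error":
                raise GlycoshockError(f"scan {key} not found in spectra")
            n_missing += 1
            keep.append(False)
            continue
        if key not in hit_cache:
            hit_cache[key] = scan_spectrum(rec, cfg).has_hit(target)
        keep.append(hit_cache[key])
    if n_missing:
        warnings.warn(f"narrow_filter skipped {n_missing} rows with unresolvable scans")
    dialect = table.dialect if isinstance(table, GlycoPSMTable) else "canonical"
    return GlycoPSMTable(df=df[pd.Series(keep, index=df.index)].copy(), dialect=dialect)


def score_filter(table, min_score: float) -> GlycoPSMTable:
    """Optional engine-score threshold (tables are normally pre-filtered)."""
    df = _frame(table)
    dialect = table.dialect if isinstance(table, GlycoPSMTable) else "canonical"
    return GlycoPSMTable(df=df[df["score"] >= min_score].copy(), dialect=dialect)
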