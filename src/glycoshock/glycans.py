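"""Glycan compositions, structure catalogs and N-glycome feature aggregation.

The serum N-glycome is reported as relative abundances (percent, summing to
100 per sample) over a catalog of structures. Each catalog entry carries a
monosaccharide composition (HexNAc/Hex/Fuc/NeuAc counts) plus structure-level
annotations that composition alone cannot resolve: whether fucoses sit on the
chitobiose core or on an antenna (forming Lewis epitopes), sialic-acid linkage
(alpha-2,3 vs alpha-2,6), antennarity and bisecting GlcNAc. Those annotations
drive the feature aggregates (percent oligomannose, percent Lewis
fucosylation, ...) used throughout the analysis.

Core/Lewis fucose and sialyl-linkage assignments are consumed from the catalog
rather than inferred: in practice they are resolved upstream by CID-MS/MS
diagnostic ions and PGC retention behaviour, which is a manual, expert step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, Iterable, Mapping

import pandas as pd

from .errors import CatalogMismatchError, CompositionParseError

__all__ = [
    "GlycanComposition",
    "GlycanStructure",
    "GlycomeProfile",
    "FeatureVector",
    "Catalog",
    "parse_composition",
    "classify_type",
    "aggregate_features",
    "feature_table",
    "day_to_day_fluctuation",
    "normalize_profile",
]

GLYCAN_TYPES = ("oligomannose", "paucimannose", "hybrid", "complex")


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide class counts of a released N-glycan."""

    hexnac: int
    hex: int
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{f.name} must be a nonnegative integer, got {v!r}")

    def __str__(self) -> str:
        parts = []
        for token, count in (
            ("HexNAc", self.hexnac),
            ("Hex", self.hex),
            ("Fuc", self.fuc),
            ("NeuAc", self.neuac),
        ):
            if count:
                parts.append(f"{token}{count}")
        return "".join(parts)


# Longest tokens first so "HexNAc" is not consumed as "Hex".
_TOKEN_RE = re.compile(r"(HexNAc|NeuAc|Hex|Fuc)(?:\((\d+)\)|(\d+))?")

_TOKEN_FIELD = {"HexNAc": "hexnac", "Hex": "hex", "Fuc": "fuc", "NeuAc": "neuac"}


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string like ``"HexNAc4Hex5Fuc1NeuAc2"``.

    Tokens may appear in any order; an absent token means count zero; a token
    without an explicit multiplicity counts once; ``HexNAc(4)`` style
    parenthesised multiplicities are accepted. Repeated tokens accumulate.

    Raises
    ------
    CompositionParseError
        On empty input or any unrecognized token, reporting the offset.
    """
    if not isinstance(text, str) or not text.strip():
        raise CompositionParseError(str(text), 0, "empty composition")
    counts = {"hexnac": 0, "hex": 0, "fuc": 0, "neuac": 0}
    pos = 0
    s = text.strip()
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise CompositionParseError(text, pos, f"unknown token starting at {s[pos:]!r}")
        mult = m.group(2) or m.group(3)
        counts[_TOKEN_FIELD[m.group(1)]] += int(mult) if mult is not None else 1
        pos = m.end()
    return GlycanComposition(**counts)


def classify_type(comp: GlycanComposition) -> str:
    """Assign the broad N-glycan type from composition alone.

    Rules (total function): oligomannose iff HexNAc2 Fuc0 NeuAc0 with 5-9 Hex;
    paucimannose iff HexNAc2 with at most 4 Hex; hybrid iff HexNAc3 (one
    processed arm); complex otherwise. These are the standard conventions for
    released serum N-glycans admitted to a catalog (HexNAc >= 2, Hex >= 3).
    """
    if comp.hexnac == 2 and comp.hex <= 4:
        return "paucimannose"
    if comp.hexnac == 2 and comp.fuc == 0 and comp.neuac == 0 and 5 <= comp.hex <= 9:
        return "oligomannose"
    if comp.hexnac == 3:
        return "hybrid"
    return "complex"


@dataclass(frozen=True)
class GlycanStructure:
    """A catalog entry: composition plus structure-level annotation flags."""

    id: str
    composition: GlycanComposition
    gtype: str
    antennae: int = 0
    core_fucose: int = 0
    lewis_fucose: int = 0
    sialyl_a23: int = 0
    sialyl_a26: int = 0
    bisecting: bool = False

    def __post_init__(self):
        if self.gtype not in GLYCAN_TYPES:
            raise ValueError(f"unknown gtype {self.gtype!r}")
        if self.core_fucose + self.lewis_fucose > self.composition.fuc:
            raise ValueError(
                f"structure {self.id}: core_fucose + lewis_fucose exceeds Fuc count"
            )
        if self.sialyl_a23 + self.sialyl_a26 > self.composition.neuac:
            raise ValueError(
                f"structure {self.id}: sialyl linkage counts exceed NeuAc count"
            )
        if self.gtype == "complex" and self.antennae < 1:
            raise ValueError(f"structure {self.id}: complex type requires antennae >= 1")
        if self.composition.hexnac < 2 or self.composition.hex < 3:
            raise ValueError(
                f"structure {self.id}: composition below the N-glycan core (HexNAc2Hex3)"
            )


class Catalog:
    """An ordered collection of :class:`GlycanStructure`, keyed by id."""

    def __init__(self, structures: Iterable[GlycanStructure]):
        self._by_id: Dict[str, GlycanStructure] = {}
        for s in structures:
            if s.id in self._by_id:
                raise ValueError(f"duplicate structure id {s.id!r}")
            self._by_id[s.id] = s

    def __len__(self):
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __contains__(self, sid):
        return sid in self._by_id

    def __getitem__(self, sid) -> GlycanStructure:
        return self._by_id[sid]

    @property
    def ids(self):
        return list(self._by_id)

    def lewis_ids(self):
        return [s.id for s in self if s.lewis_fucose >= 1]

    # -- CSV round trip ----------------------------------------------------
    _COLUMNS = [
        "id", "composition", "gtype", "antennae", "core_fucose",
        "lewis_fucose", "sialyl_a23", "sialyl_a26", "bisecting",
    ]

    def to_csv(self, path) -> None:
        rows = [
            {
                "id": s.id,
                "composition": str(s.composition),
                "gtype": s.gtype,
                "antennae": s.antennae,
                "core_fucose": s.core_fucose,
                "lewis_fucose": s.lewis_fucose,
                "sialyl_a23": s.sialyl_a23,
                "sialyl_a26": s.sialyl_a26,
                "bisecting": int(s.bisecting),
            }
            for s in self
        ]
        pd.DataFrame(rows, columns=self._COLUMNS).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Catalog":
        df = pd.read_csv(Path(path), dtype={"id": str})
        missing = [c for c in cls._COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"catalog file missing columns: {missing}")
        return cls(
            GlycanStructure(
                id=str(r.id),
                composition=parse_composition(r.composition),
                gtype=r.gtype,
                antennae=int(r.antennae),
                core_fucose=int(r.core_fucose),
                lewis_fucose=int(r.lewis_fucose),
                sialyl_a23=int(r.sialyl_a23),
                sialyl_a26=int(r.sialyl_a26),
                bisecting=bool(r.bisecting),
            )
            for r in df.itertuples()
        )


@dataclass
class GlycomeProfile:
    """Per-sample relative abundances over a catalog, in percent of total."""

    sample_id: str
    abundances: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.abundances.values())
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError(f"profile {self.sample_id}: negative abundance")
        if abs(total - 100.0) > 1e-6:
            raise ValueError(
                f"profile {self.sample_id}: abundances sum to {total}, expected 100"
            )


@dataclass(frozen=True)
class FeatureVector:
    """Glycome feature aggregates, each in percent of the total glycome."""

    pct_oligomannose: float
    pct_hybrid: float
    pct_complex: float
    pct_core_fuc: float
    pct_lewis_fuc: float
    pct_sialyl_a23: float
    pct_sialyl_a26: float
    pct_biantennary: float
    pct_triantennary: float
    pct_bisecting: float

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _feature_flags(structure: GlycanStructure) -> Dict[str, bool]:
    return {
        "pct_oligomannose": structure.gtype == "oligomannose",
        "pct_hybrid": structure.gtype == "hybrid",
        "pct_complex": structure.gtype == "complex",
        "pct_core_fuc": structure.core_fucose >= 1,
        "pct_lewis_fuc": structure.lewis_fucose >= 1,
        "pct_sialyl_a23": structure.sialyl_a23 >= 1,
        "pct_sialyl_a26": structure.sialyl_a26 >= 1,
        "pct_biantennary": structure.gtype == "complex" and structure.antennae == 2,
        "pct_triantennary": structure.gtype == "complex" and structure.antennae == 3,
        "pct_bisecting": structure.bisecting,
    }


def aggregate_features(abundances: Mapping[str, float], catalog: Catalog) -> FeatureVector:
    """Sum structure abundances into glycome feature aggregates.

    A structure with ``lewis_fucose >= 1`` contributes its full abundance to
    ``pct_lewis_fuc`` (weighting by abundance, not residue multiplicity), and
    analogously for the other flags, so features are linear in the profile.
    """
    if isinstance(abundances, GlycomeProfile):
        abundances = abundances.abundances
    missing = [sid for sid in abundances if sid not in catalog]
    if missing:
        raise CatalogMismatchError(missing)
    totals = {name: 0.0 for name in FeatureVector.__dataclass_fields__}
    for sid, value in abundances.items():
        for name, flagged in _feature_flags(catalog[sid]).items():
            if flagged:
                totals[name] += float(value)
    return FeatureVector(**totals)


def feature_table(profiles: pd.DataFrame, catalog: Catalog) -> pd.DataFrame:
    """Vectorised :func:`aggregate_features` over a samples x structures table."""
    missing = [c for c in profiles.columns if c not in catalog]
    if missing:
        raise CatalogMismatchError(missing)
    flags = pd.DataFrame(
        {sid: _feature_flags(catalog[sid]) for sid in profiles.columns}
    ).T.astype(float)
    return profiles.fillna(0.0) @ flags


def day_to_day_fluctuation(profile_a: Mapping[str, float], profile_b: Mapping[str, float]) -> float:
    """Total-variation distance between two profiles of one patient, in percent.

    Defined as half the sum of absolute per-structure abundance differences;
    bounded in [0, 100], symmetric, and zero iff the profiles coincide.
    """
    if isinstance(profile_a, GlycomeProfile):
        profile_a = profile_a.abundances
    if isinstance(profile_b, GlycomeProfile):
        profile_b = profile_b.abundances
    if set(profile_a) != set(profile_b):
        raise ValueError(
            "profiles cover different structure ids: "
            f"{sorted(set(profile_a) ^ set(profile_b))}"
        )
    return 0.5 * sum(abs(profile_a[k] - profile_b[k]) for k in profile_a)


def normalize_profile(raw: Mapping[str, float]) -> Dict[str, float]:
    """Scale nonnegative raw abundances (e.g. XIC areas) to sum to 100."""
    if any(v < 0 for v in raw.values()):
        raise ValueError("raw abundances must be nonnegative")
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return {k: 100.0 * v / total for k, v in raw.items()}
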