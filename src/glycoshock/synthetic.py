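"""Synthetic cohorts, glycome profiles, MGF spectra and glycoPSM tables.

This module generates data with the statistical structure the downstream
analysis assumes, so the whole pipeline is testable without any instrument
data: a two-group longitudinal ICU cohort (29 survivors with 2-6 daily serum
samples each, 8 nonsurvivors with 3-7), per-sample N-glycome profiles over an
illustrative ~25-structure serum catalog in which the antennary (Lewis)
fucosylated structures 22a/23a/36 are elevated in nonsurvivors on ICU days
1-2 (group means near 5.4% vs 3.2% of the glycome) and converge from day 3,
fragment-spectrum files with controllable diagnostic-ion content, and
glycoPSM tables in which AGP-1 carries ~75% of the Lewis glycoPSMs.

Every generated artifact records its construction ground truth (engineered
hit counts, configured Lewis fractions, group means) in a JSON manifest so
tests can assert against construction rather than re-estimation.

The abundance noise model is compositional: per-sample profiles are built
from a group/day-specific mean composition, a persistent patient-level
logistic-normal offset (serum N-glycomes are strongly patient-stable, with
interpersonal variation exceeding day-to-day intrapersonal drift) and a
day-level logistic-normal perturbation; the Lewis-feature total itself is
drawn at the configured group/day mean so effect sizes are controlled
exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import GlycoshockError, SpecValidationError
from .glycans import Catalog, GlycanStructure, parse_composition
from .psm import GlycoPSMTable, REQUIRED_COLUMNS
from .spectra import SpectrumRecord, write_mgf

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "SpectrumSetSpec",
    "GlycoPSMSetSpec",
    "default_catalog",
    "DEFAULT_BASELINE",
    "generate_cohort",
    "generate_glycome_profiles",
    "generate_spectra",
    "generate_glycopsm_table",
    "default_lewis_fractions",
    "lewis_feature_target",
    "DEFAULT_PROTEIN_SHARES",
]


# --------------------------------------------------------------------------
# Default serum N-glycan catalog (illustrative)
# --------------------------------------------------------------------------
# id, composition, antennae, core_fuc, lewis_fuc, a23, a26, bisecting,
# baseline survivor relative abundance (normalized to 100 at build time).
# The mix is chosen so feature aggregates land in realistic serum ranges
# (oligomannose ~5%, core fucosylation ~27%, alpha-2,6-sialylation ~88%,
# biantennary ~85%, Lewis fucosylation ~3.2% at the survivor baseline).
# Ids 22a/23a/36 are the Lewis-fucosylated structures: biantennary
# complex-type glycans carrying a (sialyl-)Lewis epitope on the 3' arm and a
# sialyl-LacNAc on the 6' arm without core fucosylation (36 triantennary).
_CATALOG_ROWS = [
    ("1",   "HexNAc2Hex5",             0, 0, 0, 0, 0, 0, 2.4),
    ("2",   "HexNAc2Hex6",             0, 0, 0, 0, 0, 0, 1.1),
    ("3",   "HexNAc2Hex7",             0, 0, 0, 0, 0, 0, 0.7),
    ("4",   "HexNAc2Hex8",             0, 0, 0, 0, 0, 0, 0.4),
    ("5",   "HexNAc2Hex9",             0, 0, 0, 0, 0, 0, 0.3),
    ("6",   "HexNAc3Hex6NeuAc1",       1, 0, 0, 0, 1, 0, 0.9),
    ("7",   "HexNAc3Hex5",             1, 0, 0, 0, 0, 0, 0.5),
    ("8",   "HexNAc3Hex6NeuAc1",       1, 0, 0, 1, 0, 0, 0.4),
    ("10",  "HexNAc4Hex3",             2, 0, 0, 0, 0, 0, 0.8),
    ("11",  "HexNAc4Hex4NeuAc1",       2, 0, 0, 0, 1, 0, 1.6),
    ("12",  "HexNAc4Hex5",             2, 0, 0, 0, 0, 0, 1.0),
    ("13",  "HexNAc4Hex5NeuAc1",       2, 0, 0, 0, 1, 0, 6.0),
    ("14",  "HexNAc4Hex5NeuAc1",       2, 0, 0, 1, 0, 0, 1.2),
    ("15",  "HexNAc4Hex5NeuAc2",       2, 0, 0, 0, 2, 0, 40.0),
    ("15a", "HexNAc4Hex5NeuAc2",       2, 0, 0, 1, 1, 0, 2.6),
    ("16",  "HexNAc4Hex5Fuc1",         2, 1, 0, 0, 0, 0, 1.6),
    ("17",  "HexNAc4Hex5Fuc1NeuAc1",   2, 1, 0, 0, 1, 0, 4.2),
    ("18",  "HexNAc4Hex5Fuc1NeuAc2",   2, 1, 0, 0, 2, 0, 14.0),
    ("19",  "HexNAc5Hex5Fuc1NeuAc2",   2, 1, 0, 0, 2, 1, 2.8),
    ("20",  "HexNAc5Hex6NeuAc2",       3, 0, 0, 0, 2, 0, 1.2),
    ("21",  "HexNAc5Hex6NeuAc3",       3, 0, 0, 0, 3, 0, 3.0),
    ("21a", "HexNAc5Hex6Fuc1NeuAc3",   3, 1, 0, 0, 3, 0, 2.5),
    ("22a", "HexNAc4Hex5Fuc1NeuAc1",   2, 0, 1, 0, 1, 0, 1.7),
    ("23a", "HexNAc4Hex5Fuc1NeuAc2",   2, 0, 1, 1, 1, 0, 1.2),
    ("36",  "HexNAc5Hex6Fuc1NeuAc3",   3, 0, 1, 1, 2, 0, 0.3),
    ("24",  "HexNAc6Hex7NeuAc4",       4, 0, 0, 1, 3, 0, 0.5),
]


def default_catalog() -> Catalog:
    """The illustrative default serum N-glycan catalog (25 + 2 isomer ids)."""
    from .glycans import classify_type

    structures = []
    for sid, comp_text, ant, cf, lf, a23, a26, bis, _ in _CATALOG_ROWS:
        comp = parse_composition(comp_text)
        structures.append(
            GlycanStructure(
                id=sid,
                composition=comp,
                gtype=classify_type(comp),
                antennae=ant,
                core_fucose=cf,
                lewis_fucose=lf,
                sialyl_a23=a23,
                sialyl_a26=a26,
                bisecting=bool(bis),
            )
        )
    return Catalog(structures)


def _baseline() -> Dict[str, float]:
    raw = {row[0]: row[8] for row in _CATALOG_ROWS}
    total = sum(raw.values())
    return {k: 100.0 * v / total for k, v in raw.items()}


#: Baseline (survivor day-1) mean composition, percent, summing to 100.
DEFAULT_BASELINE: Dict[str, float] = _baseline()

#: How the group-level Lewis elevation divides over Lewis structures: the
#: discriminating isomers 22a/23a carry it all, while structure 36 stays
#: near its baseline in both groups (elevated-but-not-discriminating).
DEFAULT_EFFECT_SHARES: Dict[str, float] = {"22a": 0.55, "23a": 0.45}


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------
@dataclass
class CohortSpec:
    """Cohort shape: group sizes and samples-per-patient ranges.

    Interval lower bounds must be >= 2 so every patient has a day-1 sample
    plus at least one later sample, keeping the longitudinal split defined.
    """

    n_survivors: int = 29
    n_nonsurvivors: int = 8
    days_range_survivor: Tuple[int, int] = (2, 6)
    days_range_nonsurvivor: Tuple[int, int] = (3, 7)
    seed: int = 0

    def __post_init__(self):
        if self.n_survivors < 1:
            raise SpecValidationError("n_survivors", "must be >= 1")
        if self.n_nonsurvivors < 1:
            raise SpecValidationError("n_nonsurvivors", "must be >= 1")
        for name in ("days_range_survivor", "days_range_nonsurvivor"):
            lo, hi = getattr(self, name)
            if lo < 2:
                raise SpecValidationError(name, "lower bound must be >= 2")
            if hi < lo:
                raise SpecValidationError(name, "upper bound below lower bound")
        if not isinstance(self.seed, (int, np.integer)):
            raise SpecValidationError("seed", "must be an integer")


@dataclass
class EffectSpec:
    """Group/day structure of the Lewis-fucosylation effect.

    Group means are for the Lewis feature (summed abundance of the
    Lewis-flagged structures, percent of the glycome) on ICU days 1-2;
    from ``convergence_day`` onward both groups sit at the nonsurvivor level
    (survivors rise to meet it). ``within_group_sd`` is the cross-sectional
    SD of the Lewis feature, of which ``patient_effect_fraction`` of the
    variance is a stable per-patient offset. The remaining composition is
    perturbed logistic-normally with the given concentration parameters.
    """

    lewis_mean_nonsurvivor_day12: float = 5.4
    lewis_mean_survivor_day12: float = 3.2
    convergence_day: int = 4
    within_group_sd: float = 0.65
    abundance_noise_model: str = "logistic_normal"
    patient_effect_fraction: float = 0.75
    composition_sigma_patient: float = 0.25
    composition_sigma_day: float = 0.09
    lewis_split_sigma_patient: float = 0.03
    lewis_split_sigma_day: float = 0.03
    patient_axes: int = 2
    effect_share_by_structure: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        for name in ("lewis_mean_nonsurvivor_day12", "lewis_mean_survivor_day12"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise SpecValidationError(name, "must be a percent in (0, 100)")
        if self.convergence_day < 2:
            raise SpecValidationError("convergence_day", "must be >= 2")
        if self.within_group_sd <= 0:
            raise SpecValidationError("within_group_sd", "must be > 0")
        if self.abundance_noise_model != "logistic_normal":
            raise SpecValidationError(
                "abundance_noise_model", "only 'logistic_normal' is implemented"
            )
        if not 0 <= self.patient_effect_fraction <= 1:
            raise SpecValidationError("patient_effect_fraction", "must be in [0, 1]")
        if self.patient_axes < 1:
            raise SpecValidationError("patient_axes", "must be >= 1")
        if self.effect_share_by_structure is not None:
            total = sum(self.effect_share_by_structure.values())
            if abs(total - 1.0) > 1e-9:
                raise SpecValidationError(
                    "effect_share_by_structure", f"shares sum to {total}, expected 1"
                )


@dataclass
class SpectrumSetSpec:
    """Controls for engineered MGF fixtures used to exercise the scanner."""

    n_spectra: int = 100
    target_ions: Sequence[float] = (512.20, 803.29)
    hit_fraction_per_target: Mapping[float, float] | float = 0.4
    hit_relative_intensity: float = 0.05
    decoy_peak_count: int = 30
    mz_jitter: float = 0.005
    seed: int = 0
    sample_id: str = "SIM"
    mz_range: Tuple[float, float] = (200.0, 1200.0)
    exclusion_halfwidth: float = 0.5  # decoy-free zone around each target
    base_intensity: float = 1000.0

    def fractions(self) -> Dict[float, float]:
        if isinstance(self.hit_fraction_per_target, Mapping):
            return {float(t): float(self.hit_fraction_per_target[t]) for t in self.target_ions}
        return {float(t): float(self.hit_fraction_per_target) for t in self.target_ions}

    def __post_init__(self):
        if self.n_spectra < 1:
            raise SpecValidationError("n_spectra", "must be >= 1")
        for t, f in self.fractions().items():
            if not 0 <= f <= 1:
                raise SpecValidationError(
                    "hit_fraction_per_target", f"fraction for {t} not in [0, 1]"
                )
        if not 0 <= self.hit_relative_intensity <= 1:
            raise SpecValidationError("hit_relative_intensity", "must be in [0, 1]")
        if self.mz_jitter < 0:
            raise SpecValidationError("mz_jitter", "must be >= 0")
        if self.exclusion_halfwidth < 2 * self.mz_jitter:
            raise SpecValidationError(
                "exclusion_halfwidth", "must be >= 2 x mz_jitter"
            )


#: Carrier shares of Lewis glycoPSMs: AGP-1 dominant, then haptoglobin,
#: alpha-1-antitrypsin, hemopexin, ANKRD36, and a pooled remainder.
DEFAULT_PROTEIN_SHARES: Dict[str, float] = {
    "AGP1": 0.753,
    "HP": 0.077,
    "SERPINA1": 0.036,
    "HPX": 0.017,
    "ANKRD36": 0.015,
    "OTHER": 0.102,
}


@dataclass
class GlycoPSMSetSpec:
    """Controls for synthetic glycoPSM tables."""

    n_psms_per_sample: int = 200
    lewis_fraction_by_group_day: Optional[Mapping[Tuple[str, int], float]] = None
    protein_shares_among_lewis: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_SHARES)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_psms_per_sample < 1:
            raise SpecValidationError("n_psms_per_sample", "must be >= 1")
        total = sum(self.protein_shares_among_lewis.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecValidationError(
                "protein_shares_among_lewis", f"shares sum to {total}, expected 1"
            )
        if self.lewis_fraction_by_group_day is not None:
            for key, f in self.lewis_fraction_by_group_day.items():
                if not 0 <= f <= 1:
                    raise SpecValidationError(
                        "lewis_fraction_by_group_day", f"fraction for {key} not in [0, 1]"
                    )


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------
def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per serum sample: patient_id, outcome, icu_day, sample_id.

    Sampling-day schedules are contiguous from day 1 ("collected daily");
    the number of samples per patient is drawn uniformly from the group's
    inclusive interval. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    groups = [
        ("survivor", "S", spec.n_survivors, spec.days_range_survivor),
        ("nonsurvivor", "NS", spec.n_nonsurvivors, spec.days_range_nonsurvivor),
    ]
    for outcome, prefix, n, (lo, hi) in groups:
        n_days = rng.integers(lo, hi + 1, size=n)
        for k in range(n):
            pid = f"{prefix}{k + 1:02d}"
            for day in range(1, int(n_days[k]) + 1):
                rows.append(
                    {
                        "patient_id": pid,
                        "outcome": outcome,
                        "icu_day": day,
                        "sample_id": f"{pid}_d{day}",
                    }
                )
    return pd.DataFrame(rows, columns=["patient_id", "outcome", "icu_day", "sample_id"])


# --------------------------------------------------------------------------
# Glycome profiles
# --------------------------------------------------------------------------
def lewis_feature_target(effect: EffectSpec, outcome: str, icu_day: int) -> float:
    """Configured mean of the Lewis feature for a group/day cell (percent).

    Nonsurvivors sit at their elevated level throughout; survivors hold
    their day-1/2 level through day 2 and then rise linearly, reaching the
    nonsurvivor level at ``convergence_day`` (a gradual increase within the
    survivor group rather than a step).
    """
    if outcome == "nonsurvivor" or icu_day >= effect.convergence_day:
        return effect.lewis_mean_nonsurvivor_day12
    if icu_day <= 2:
        return effect.lewis_mean_survivor_day12
    span = effect.convergence_day - 2
    frac = (icu_day - 2) / span
    return (effect.lewis_mean_survivor_day12
            + frac * (effect.lewis_mean_nonsurvivor_day12 - effect.lewis_mean_survivor_day12))


def generate_glycome_profiles(
    cohort: pd.DataFrame,
    catalog: Optional[Catalog] = None,
    effect: Optional[EffectSpec] = None,
    seed: int = 0,
    baseline: Optional[Mapping[str, float]] = None,
) -> Tuple[pd.DataFrame, Dict]:
    """Per-sample glycome profiles (samples x structures, percent).

    Every row sums to 100 within 1e-6; the Lewis-feature group means follow
    the :class:`EffectSpec` on days 1-2 and equalize from the convergence
    day. Returns the profile table (indexed by sample_id) and a manifest of
    configured ground truth.
    """
    catalog = catalog if catalog is not None else default_catalog()
    effect = effect if effect is not None else EffectSpec()
    baseline = dict(baseline) if baseline is not None else dict(DEFAULT_BASELINE)
    lewis_ids = catalog.lewis_ids()
    if not lewis_ids:
        raise GlycoshockError("catalog has no Lewis-flagged structures")
    other_ids = [sid for sid in catalog.ids if sid not in lewis_ids]
    missing = [sid for sid in catalog.ids if sid not in baseline]
    if missing:
        raise GlycoshockError(f"baseline missing structures: {missing}")

    lw_base = np.array([baseline[s] for s in lewis_ids], dtype=float)
    base_total = lw_base.sum()
    shares = (dict(effect.effect_share_by_structure)
              if effect.effect_share_by_structure is not None
              else dict(DEFAULT_EFFECT_SHARES))
    unknown = set(shares) - set(lewis_ids)
    if unknown:
        raise GlycoshockError(
            f"effect shares name non-Lewis structures: {sorted(unknown)}"
        )
    share_vec = np.array([shares.get(s, 0.0) for s in lewis_ids], dtype=float)
    nw = np.array([baseline[s] for s in other_ids], dtype=float)
    nw = nw / nw.sum()

    sd_patient = effect.within_group_sd * np.sqrt(effect.patient_effect_fraction)
    sd_day = effect.within_group_sd * np.sqrt(1.0 - effect.patient_effect_fraction)

    rng = np.random.default_rng(seed)
    pat_tbl = cohort[["patient_id", "outcome"]].drop_duplicates()
    patients = pat_tbl["patient_id"].tolist()
    outcomes = pat_tbl["outcome"].to_numpy()

    def _group_centered(draws: np.ndarray) -> np.ndarray:
        # patient-level random effects represent outcome-independent
        # physiology; centering within each outcome group makes them carry
        # no survivorship information by construction, so the configured
        # Lewis effect is the only group difference in the data
        out = draws.astype(float).copy()
        for g in np.unique(outcomes):
            mask = outcomes == g
            out[mask] -= out[mask].mean(axis=0)
        return out

    # Interpersonal variation of the non-Lewis composition is low-rank:
    # every patient's stable offset is a loading-weighted mix of a few latent
    # physiological axes, so fingerprint variance is shared across many
    # correlated structures rather than independent per structure.
    loadings = rng.normal(0.0, 1.0, size=(len(other_ids), effect.patient_axes))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    # the Lewis-total offsets stay iid across patients so rank tests on the
    # Lewis feature keep their nominal null behaviour
    p_offset = dict(zip(patients, rng.normal(0.0, sd_patient, size=len(patients))))
    axis_scores = _group_centered(
        rng.normal(0.0, 1.0, size=(len(patients), effect.patient_axes))
    )
    p_comp = {
        p: effect.composition_sigma_patient * (loadings @ axis_scores[i])
        for i, p in enumerate(patients)
    }
    lsplit = _group_centered(
        rng.normal(0.0, effect.lewis_split_sigma_patient,
                   size=(len(patients), len(lewis_ids)))
    )
    p_lsplit = dict(zip(patients, lsplit))

    data = np.empty((len(cohort), len(catalog.ids)), dtype=float)
    col_index = {sid: i for i, sid in enumerate(catalog.ids)}
    li = [col_index[s] for s in lewis_ids]
    oi = [col_index[s] for s in other_ids]
    targets = []
    for r, row in enumerate(cohort.itertuples()):
        target = lewis_feature_target(effect, row.outcome, int(row.icu_day))
        targets.append(target)
        lewis_total = np.clip(
            target + p_offset[row.patient_id] + rng.normal(0.0, sd_day), 0.05, 80.0
        )
        # the group-level elevation (target above the baseline Lewis total)
        # loads onto the discriminating structures only
        mean_vec = np.clip(lw_base + (target - base_total) * share_vec, 0.01, None)
        split = mean_vec * np.exp(
            p_lsplit[row.patient_id]
            + rng.normal(0.0, effect.lewis_split_sigma_day, size=len(lewis_ids))
        )
        split /= split.sum()
        comp = nw * np.exp(
            p_comp[row.patient_id]
            + rng.normal(0.0, effect.composition_sigma_day, size=len(other_ids))
        )
        comp /= comp.sum()
        vec = np.empty(len(catalog.ids))
        vec[li] = lewis_total * split
        vec[oi] = (100.0 - lewis_total) * comp
        data[r] = vec / vec.sum() * 100.0
    profiles = pd.DataFrame(data, index=pd.Index(cohort["sample_id"], name="sample_id"),
                            columns=catalog.ids)
    manifest = {
        "seed": int(seed),
        "n_samples": int(len(cohort)),
        "lewis_ids": lewis_ids,
        "effect": asdict(effect),
        "group_day_lewis_mean": {
            f"{g}:{d}": lewis_feature_target(effect, g, int(d))
            for g in ("survivor", "nonsurvivor")
            for d in sorted(cohort["icu_day"].unique())
        },
        "per_sample_lewis_target": dict(zip(cohort["sample_id"], targets)),
    }
    return profiles, manifest


# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------
def _draw_decoy_mz(rng, spec: SpectrumSetSpec, size: int) -> np.ndarray:
    """Uniform m/z values outside every target exclusion window."""
    lo, hi = spec.mz_range
    out = np.empty(size)
    filled = 0
    while filled < size:
        cand = rng.uniform(lo, hi, size=size - filled)
        ok = np.ones(len(cand), dtype=bool)
        for t in spec.target_ions:
            ok &= np.abs(cand - t) > spec.exclusion_halfwidth
        good = cand[ok]
        out[filled:filled + len(good)] = good
        filled += len(good)
    return out


def generate_spectra(spec: SpectrumSetSpec, path) -> Dict:
    """Write an engineered MGF file and its ground-truth manifest.

    Exactly ``round(hit_fraction * n_spectra)`` spectra carry each target
    ion, placed within ``mz_jitter`` of the target at
    ``hit_relative_intensity`` x the base peak; decoy peaks are kept outside
    the exclusion window of every target so scans at any tolerance up to
    that halfwidth recover the engineered fractions exactly.
    """
    rng = np.random.default_rng(spec.seed)
    fractions = spec.fractions()
    hit_sets = {}
    for t in spec.target_ions:
        n_hits = round(fractions[float(t)] * spec.n_spectra)
        hit_sets[float(t)] = set(
            rng.choice(spec.n_spectra, size=n_hits, replace=False).tolist()
        )
    records = []
    for i in range(spec.n_spectra):
        mzs = list(_draw_decoy_mz(rng, spec, spec.decoy_peak_count))
        intens = list(rng.uniform(0.02, 0.8, size=spec.decoy_peak_count) * spec.base_intensity)
        # base peak: guaranteed maximum, away from all targets
        mzs.append(float(_draw_decoy_mz(rng, spec, 1)[0]))
        intens.append(spec.base_intensity)
        for t in spec.target_ions:
            if i in hit_sets[float(t)]:
                mzs.append(float(t + rng.uniform(-spec.mz_jitter, spec.mz_jitter)))
                intens.append(spec.hit_relative_intensity * spec.base_intensity)
        records.append(
            SpectrumRecord(
                sample_id=spec.sample_id,
                scan_id=f"s{i:05d}",
                precursor_mz=float(rng.uniform(400.0, 1600.0)),
                charge=2,
                peaks=np.column_stack([mzs, intens]),
            )
        )
    write_mgf(records, path)
    manifest = {
        "seed": int(spec.seed),
        "n_spectra": int(spec.n_spectra),
        "hit_relative_intensity": spec.hit_relative_intensity,
        "mz_jitter": spec.mz_jitter,
        "targets": {
            str(t): {
                "engineered_hits": len(hit_sets[float(t)]),
                "engineered_fraction": len(hit_sets[float(t)]) / spec.n_spectra,
                "scan_ids": sorted(f"s{i:05d}" for i in hit_sets[float(t)]),
            }
            for t in spec.target_ions
        },
    }
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# --------------------------------------------------------------------------
# GlycoPSM tables
# --------------------------------------------------------------------------
_LEWIS_COMPS = ("HexNAc4Hex5Fuc1NeuAc1", "HexNAc4Hex5Fuc1NeuAc2")
_CORE_COMP = "HexNAc4Hex5Fuc1NeuAc2"
_PLAIN_COMP = "HexNAc4Hex5NeuAc2"
_BACKGROUND_PROTEINS = ("IGHG1", "TF", "A2M", "HP", "SERPINA1", "AGP1", "APOH", "CP")


def default_lewis_fractions(
    cohort: pd.DataFrame,
    survivor: float = 0.032,
    nonsurvivor: float = 0.054,
    convergence_day: int = 3,
) -> Dict[Tuple[str, int], float]:
    """A complete (group, day) -> Lewis-glycoPSM-fraction mapping for a cohort."""
    mapping = {}
    for g, d in cohort[["outcome", "icu_day"]].drop_duplicates().itertuples(index=False):
        if g == "nonsurvivor" or d >= convergence_day:
            mapping[(g, int(d))] = nonsurvivor
        else:
            mapping[(g, int(d))] = survivor
    return mapping


def generate_glycopsm_table(
    cohort: pd.DataFrame,
    spec: GlycoPSMSetSpec,
    path=None,
) -> Tuple[GlycoPSMTable, Dict]:
    """Synthetic glycoPSM rows with configured Lewis content per sample.

    Per sample, exactly ``round(lewis_fraction x n_psms_per_sample)`` rows
    are Lewis-typed and assigned to carrier proteins multinomially with the
    configured shares; the remainder split between core-fucosylated and
    fucose-free glycoforms on background serum proteins. When ``path`` is
    given the canonical TSV and a JSON manifest are written next to it.
    """
    rng = np.random.default_rng(spec.seed)
    fractions = (
        dict(spec.lewis_fraction_by_group_day)
        if spec.lewis_fraction_by_group_day is not None
        else default_lewis_fractions(cohort)
    )
    proteins = list(spec.protein_shares_among_lewis)
    shares = np.array([spec.protein_shares_among_lewis[p] for p in proteins])
    rows = []
    truth = {}
    for srow in cohort.itertuples():
        key = (srow.outcome, int(srow.icu_day))
        if key not in fractions:
            raise GlycoshockError(f"no Lewis fraction configured for (group, day) {key}")
        n = spec.n_psms_per_sample
        n_lewis = round(fractions[key] * n)
        lewis_prots = rng.choice(proteins, size=n_lewis, p=shares)
        truth[srow.sample_id] = {
            "n_psms": n,
            "n_lewis": int(n_lewis),
            "lewis_fraction": n_lewis / n,
        }
        for j in range(n):
            if j < n_lewis:
                prot = str(lewis_prots[j])
                ftype = "lewis"
                comp = _LEWIS_COMPS[int(rng.integers(0, len(_LEWIS_COMPS)))]
            else:
                prot = str(_BACKGROUND_PROTEINS[int(rng.integers(0, len(_BACKGROUND_PROTEINS)))])
                ftype = "core" if rng.random() < 0.45 else "none"
                comp = _CORE_COMP if ftype == "core" else _PLAIN_COMP
            rows.append(
                {
                    "sample_id": srow.sample_id,
                    "scan_id": f"{srow.sample_id}_scan{j:05d}",
                    "peptide": f"PEP{prot}K",
                    "protein": prot,
                    "site": int(rng.integers(30, 400)),
                    "composition": comp,
                    "fucose_type": ftype,
                    "score": float(np.round(rng.uniform(100.0, 300.0), 2)),
                }
            )
    table = GlycoPSMTable(
        df=pd.DataFrame(rows, columns=REQUIRED_COLUMNS), dialect="canonical"
    ).validate()
    manifest = {
        "seed": int(spec.seed),
        "n_psms_per_sample": spec.n_psms_per_sample,
        "protein_shares_among_lewis": dict(spec.protein_shares_among_lewis),
        "per_sample": truth,
    }
    if path is not None:
        table.df.to_csv(path, sep="\t", index=False)
        Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))
    return table, manifest
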