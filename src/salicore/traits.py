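"""Derivation of the 14 seedling salt-tolerance traits from raw phenotype records.

Growth under control and salt stress is summarized into three salt-tolerance
indices (RGR, RNIL, RLER: the stress/control ratio of shoot growth rate,
number of leaves increased, and leaf expansion rate), and eleven stress-side
traits: leaf senescence scale (Sen, ordinal 1-9), shoot and root water
contents (SWC, RWC, %), shoot and root Na+ and K+ concentrations (SNC, RNC,
SKC, RKC, mg/g dry mass) and the four ion ratios SN/RN, SK/RK, SK/N, RK/N.

Each trait carries a direction: *positive* traits increase with salt
tolerance, *negative* traits (senescence and Na+/K+ accumulation measures)
decrease with it. The default direction map assigns negative to
{Sen, SNC, RNC, SN/RN, SKC, RKC} and positive to the remaining eight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DivisionDomainError,
    ExclusionWarning,
    InvalidMassError,
    MissingTimepointError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Canonical order of the 14 salt-tolerance traits.
TRAIT_NAMES: tuple[str, ...] = (
    "RGR", "RNIL", "RLER", "Sen", "SWC", "RWC", "SNC",
    "RNC", "SN/RN", "SKC", "RKC", "SK/RK", "SK/N", "RK/N",
)

#: Traits for which a larger value indicates *lower* salt tolerance.
NEGATIVE_TRAITS: frozenset[str] = frozenset({"Sen", "SNC", "RNC", "SN/RN", "SKC", "RKC"})

#: Default trait -> direction map ("positive" | "negative").
DEFAULT_DIRECTIONS: dict[str, str] = {
    name: ("negative" if name in NEGATIVE_TRAITS else "positive") for name in TRAIT_NAMES
}

GENOTYPE_COLUMN = "genotype_id"

WaterContentFormula = Literal["fresh_basis", "dry_basis"]


@dataclass
class RawPhenotypeRecord:
    """One genotype x treatment x replicate set of raw measurements.

    Height/leaf series are keyed by DAS (days after starting the stress
    treatment). Senescence score and ion concentrations are recorded under
    stress only; masses are in grams, ion concentrations in mg per g dry mass.
    """

    genotype_id: str
    treatment: Literal["control", "stress"]
    replicate: int
    height_cm_at_das: dict[int, float] = field(default_factory=dict)
    leaf_count_at_das: dict[int, float] = field(default_factory=dict)
    marked_leaf_length_cm_at_das: dict[int, float] = field(default_factory=dict)
    shoot_fresh_g: float | None = None
    shoot_dry_g: float | None = None
    root_fresh_g: float | None = None
    root_dry_g: float | None = None
    senescence_score: float | None = None
    shoot_na_mg_g: float | None = None
    root_na_mg_g: float | None = None
    shoot_k_mg_g: float | None = None
    root_k_mg_g: float | None = None

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "stress"):
            raise ValueError(f"treatment must be 'control' or 'stress', got {self.treatment!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        for series in (self.height_cm_at_das, self.leaf_count_at_das,
                       self.marked_leaf_length_cm_at_das):
            for das, value in series.items():
                if value < 0:
                    raise ValueError(f"negative measurement at DAS {das}")
        for fresh, dry, organ in ((self.shoot_fresh_g, self.shoot_dry_g, "shoot"),
                                  (self.root_fresh_g, self.root_dry_g, "root")):
            if fresh is not None and dry is not None and dry > fresh:
                raise InvalidMassError(f"{organ} dry mass {dry} g exceeds fresh mass {fresh} g")
        if self.senescence_score is not None and not (1 <= self.senescence_score <= 9):
            raise ValueError("senescence_score must lie in [1, 9]")


@dataclass
class TraitTable:
    """Genotype x 14-trait matrix plus per-trait direction metadata.

    ``data`` is indexed by genotype id with the canonical trait columns;
    ``extra`` keeps any non-trait columns found alongside the table on disk.
    """

    data: pd.DataFrame
    directions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [t for t in self.data.columns if t not in self.directions]
        if missing:
            raise SchemaError(f"no direction defined for trait(s) {missing}")

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, genotype_ids: Sequence[str]) -> "TraitTable":
        """Row-subset preserving directions (used for core-vs-entire comparisons)."""
        return TraitTable(self.data.loc[list(genotype_ids)].copy(), dict(self.directions))

    def check_ion_ratio_consistency(self, rtol: float = 1e-9) -> bool:
        """True when the four ion ratios are consistent with their base traits row-wise."""
        d = self.data
        needed = {"SNC", "RNC", "SKC", "RKC", "SN/RN", "SK/RK", "SK/N", "RK/N"}
        if not needed.issubset(d.columns):
            return True
        checks = [
            np.allclose(d["SK/N"] * d["SNC"], d["SKC"], rtol=rtol, equal_nan=True),
            np.allclose(d["RK/N"] * d["RNC"], d["RKC"], rtol=rtol, equal_nan=True),
            np.allclose(d["SN/RN"] * d["RNC"], d["SNC"], rtol=rtol, equal_nan=True),
            np.allclose(d["SK/RK"] * d["RKC"], d["SKC"], rtol=rtol, equal_nan=True),
        ]
        return all(checks)


@dataclass
class Exclusion:
    genotype_id: str
    reason: str
    trait: str | None = None


@dataclass
class AssemblyResult:
    """assemble_trait_table output: the table plus an exclusion report."""

    table: TraitTable
    exclusions: list[Exclusion]


def derive_growth_rates(record: RawPhenotypeRecord,
                        which: Iterable[str] = ("GR", "NIL", "LER")) -> dict[str, float]:
    """Derive growth rates from one record's time series.

    GR (cm/day) is the mean of the daily height increase over DAS 2->7 and
    2->17; NIL is the leaf count increase from DAS 1 to 17; LER (cm/day) is
    the mean daily elongation of the marked leaf over DAS 2->7 and 2->12.

    Raises
    ------
    MissingTimepointError
        If a DAS key needed for a requested output is absent; the message
        names the blocked trait.
    """
    out: dict[str, float] = {}
    which = tuple(which)

    def _need(series: Mapping[int, float], das: int, trait: str) -> float:
        if das not in series:
            raise MissingTimepointError(
                f"record {record.genotype_id}/{record.treatment}/rep{record.replicate}: "
                f"DAS {das} missing, cannot derive {trait}")
        return series[das]

    if "GR" in which:
        h2 = _need(record.height_cm_at_das, 2, "GR")
        h7 = _need(record.height_cm_at_das, 7, "GR")
        h17 = _need(record.height_cm_at_das, 17, "GR")
        out["GR"] = ((h7 - h2) / 5.0 + (h17 - h2) / 15.0) / 2.0
    if "NIL" in which:
        n1 = _need(record.leaf_count_at_das, 1, "NIL")
        n17 = _need(record.leaf_count_at_das, 17, "NIL")
        out["NIL"] = n17 - n1
    if "LER" in which:
        l2 = _need(record.marked_leaf_length_cm_at_das, 2, "LER")
        l7 = _need(record.marked_leaf_length_cm_at_das, 7, "LER")
        l12 = _need(record.marked_leaf_length_cm_at_das, 12, "LER")
        out["LER"] = ((l7 - l2) / 5.0 + (l12 - l2) / 10.0) / 2.0
    return out


def compute_sti_sii(stress_value: float, control_value: float) -> dict[str, float]:
    """Salt tolerance index STI = stress/control and salt-injury index SII = 1 - STI."""
    if control_value <= 0:
        raise DivisionDomainError(f"control value must be positive, got {control_value}")
    sti = stress_value / control_value
    return {"STI": sti, "SII": 1.0 - sti}


def compute_water_content(fresh_g: float, dry_g: float,
                          formula: WaterContentFormula = "fresh_basis") -> float:
    """Tissue water content in percent.

    The default fresh-basis formula is (fresh - dry)/fresh * 100; a dry-basis
    alternative (fresh - dry)/dry * 100 is selectable. The fresh-basis default
    is a documented assumption: published seedling panels report water-content
    scales that no single convention reproduces, so the choice is configurable.
    """
    if fresh_g <= 0:
        raise InvalidMassError(f"fresh mass must be positive, got {fresh_g}")
    if dry_g < 0 or dry_g > fresh_g:
        raise InvalidMassError(f"dry mass {dry_g} g outside [0, fresh={fresh_g}] g")
    if formula == "fresh_basis":
        return (fresh_g - dry_g) / fresh_g * 100.0
    if formula == "dry_basis":
        if dry_g == 0:
            raise InvalidMassError("dry-basis water content undefined for zero dry mass")
        return (fresh_g - dry_g) / dry_g * 100.0
    raise ValueError(f"unknown water-content formula {formula!r}")


def _replicate_mean(values: list[float]) -> float:
    return float(np.mean(values))


def assemble_trait_table(records: Iterable[RawPhenotypeRecord],
                         directions: Mapping[str, str] | None = None,
                         water_content_formula: WaterContentFormula = "fresh_basis",
                         ) -> AssemblyResult:
    """Build the genotype x 14-trait table from raw records.

    Replicate measurements are averaged per genotype x treatment before the
    stress/control ratios are formed (ratio of replicate means). Genotypes
    missing a treatment arm are excluded with a logged warning and reported.
    A genotype whose control mean for a growth trait is zero gets NaN for that
    ratio trait (reported per-trait) rather than an infinite index.
    """
    directions = dict(directions) if directions is not None else dict(DEFAULT_DIRECTIONS)

    by_genotype: dict[str, dict[str, list[RawPhenotypeRecord]]] = {}
    order: list[str] = []
    for rec in records:
        if rec.genotype_id not in by_genotype:
            by_genotype[rec.genotype_id] = {"control": [], "stress": []}
            order.append(rec.genotype_id)
        by_genotype[rec.genotype_id][rec.treatment].append(rec)

    rows: dict[str, dict[str, float]] = {}
    exclusions: list[Exclusion] = []
    for gid in order:
        arms = by_genotype[gid]
        if not arms["control"] or not arms["stress"]:
            missing_arm = "control" if not arms["control"] else "stress"
            msg = f"genotype {gid} has no {missing_arm} records; excluded"
            logger.warning(msg)
            warnings.warn(msg, ExclusionWarning, stacklevel=2)
            exclusions.append(Exclusion(gid, f"missing {missing_arm} arm"))
            continue

        row: dict[str, float] = {}
        # Growth-rate STIs from replicate means of the per-replicate rates.
        for raw_name, sti_name in (("GR", "RGR"), ("NIL", "RNIL"), ("LER", "RLER")):
            means = {}
            for arm in ("control", "stress"):
                means[arm] = _replicate_mean(
                    [derive_growth_rates(r, which=(raw_name,))[raw_name] for r in arms[arm]])
            if means["control"] <= 0:
                exclusions.append(Exclusion(gid, "non-positive control mean", sti_name))
                row[sti_name] = np.nan
            else:
                row[sti_name] = means["stress"] / means["control"]

        stress = arms["stress"]
        row["Sen"] = _replicate_mean(
            [r.senescence_score for r in stress if r.senescence_score is not None])
        row["SWC"] = _replicate_mean(
            [compute_water_content(r.shoot_fresh_g, r.shoot_dry_g, water_content_formula)
             for r in stress if r.shoot_fresh_g is not None])
        row["RWC"] = _replicate_mean(
            [compute_water_content(r.root_fresh_g, r.root_dry_g, water_content_formula)
             for r in stress if r.root_fresh_g is not None])
        row["SNC"] = _replicate_mean([r.shoot_na_mg_g for r in stress
                                      if r.shoot_na_mg_g is not None])
        row["RNC"] = _replicate_mean([r.root_na_mg_g for r in stress
                                      if r.root_na_mg_g is not None])
        row["SKC"] = _replicate_mean([r.shoot_k_mg_g for r in stress
                                      if r.shoot_k_mg_g is not None])
        row["RKC"] = _replicate_mean([r.root_k_mg_g for r in stress
                                      if r.root_k_mg_g is not None])
        row["SN/RN"] = row["SNC"] / row["RNC"]
        row["SK/RK"] = row["SKC"] / row["RKC"]
        row["SK/N"] = row["SKC"] / row["SNC"]
        row["RK/N"] = row["RKC"] / row["RNC"]
        rows[gid] = row

    data = pd.DataFrame.from_dict(rows, orient="index", columns=list(TRAIT_NAMES))
    data.index.name = GENOTYPE_COLUMN
    return AssemblyResult(TraitTable(data, directions), exclusions)


def load_trait_table(path, directions: Mapping[str, str] | None = None) -> TraitTable:
    """Load a wide trait CSV (genotype_id + 14 canonical trait columns).

    Unknown columns are preserved on ``table.extra`` but excluded from the
    trait matrix. A missing trait column raises :class:`SchemaError`.
    Lines starting with ``#`` are treated as provenance comments.
    """
    df = pd.read_csv(path, comment="#")
    if GENOTYPE_COLUMN not in df.columns:
        raise SchemaError(f"missing required column {GENOTYPE_COLUMN!r}")
    missing = [t for t in TRAIT_NAMES if t not in df.columns]
    if missing:
        raise SchemaError(f"missing trait column(s): {', '.join(missing)}")
    df = df.set_index(GENOTYPE_COLUMN)
    df.index = df.index.astype(str)
    extra_cols = [c for c in df.columns if c not in TRAIT_NAMES]
    extra = df[extra_cols].copy() if extra_cols else None
    data = df[list(TRAIT_NAMES)].astype(float)
    dirmap = dict(directions) if directions is not None else dict(DEFAULT_DIRECTIONS)
    return TraitTable(data, dirmap, extra)


def write_trait_table(table: TraitTable, path, provenance: str | None = None) -> None:
    """Write a trait table to CSV, round-trippable to 12+ significant digits."""
    out = table.data.copy()
    if table.extra is not None:
        out = out.join(table.extra)
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        out.to_csv(fh, float_format="%.17g")


def load_directions_yaml(path) -> dict[str, str]:
    """Read a trait -> positive|negative map from YAML, validating values."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("directions YAML must map trait names to 'positive'/'negative'")
    for trait, direction in raw.items():
        if direction not in ("positive", "negative"):
            raise SchemaError(f"invalid direction {direction!r} for trait {trait!r}")
    return {str(k): str(v) for k, v in raw.items()}


_SERIES_MEASURES = {
    "height_cm": "height_cm_at_das",
    "leaf_count": "leaf_count_at_das",
    "marked_leaf_length_cm": "marked_leaf_length_cm_at_das",
}
_SCALAR_MEASURES = (
    "shoot_fresh_g", "shoot_dry_g", "root_fresh_g", "root_dry_g",
    "senescence_score", "shoot_na_mg_g", "root_na_mg_g",
    "shoot_k_mg_g", "root_k_mg_g",
)


def load_raw_phenotypes(path) -> list[RawPhenotypeRecord]:
    """Read long-format raw records (genotype_id, treatment, replicate, measure, das, value)."""
    df = pd.read_csv(path, comment="#")
    required = {"genotype_id", "treatment", "replicate", "measure", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"raw phenotype CSV missing column(s): {sorted(missing)}")
    records: dict[tuple[str, str, int], RawPhenotypeRecord] = {}
    for row in df.itertuples(index=False):
        key = (str(row.genotype_id), str(row.treatment), int(row.replicate))
        rec = records.get(key)
        if rec is None:
            rec = RawPhenotypeRecord(genotype_id=key[0], treatment=key[1], replicate=key[2])
            records[key] = rec
        measure = str(row.measure)
        if measure in _SERIES_MEASURES:
            das = getattr(row, "das", None)
            if das is None or pd.isna(das):
                raise SchemaError(f"measure {measure!r} requires a das value")
            getattr(rec, _SERIES_MEASURES[measure])[int(das)] = float(row.value)
        elif measure in _SCALAR_MEASURES:
            setattr(rec, measure, float(row.value))
        else:
            raise SchemaError(f"unknown measure {measure!r}")
    out = list(records.values())
    for rec in out:
        rec.__post_init__()  # re-validate masses/scores after field assignment
    return out


def write_raw_phenotypes(records: Iterable[RawPhenotypeRecord], path,
                         provenance: str | None = None) -> None:
    """Write records in the long CSV format read by :func:`load_raw_phenotypes`."""
    rows = []
    for rec in records:
        base = {"genotype_id": rec.genotype_id, "treatment": rec.treatment,
                "replicate": rec.replicate}
        for measure, attr in _SERIES_MEASURES.items():
            for das, value in sorted(getattr(rec, attr).items()):
                rows.append({**base, "measure": measure, "das": das, "value": value})
        for measure in _SCALAR_MEASURES:
            value = getattr(rec, measure)
            if value is not None:
                rows.append({**base, "measure": measure, "das": "", "value": value})
    df = pd.DataFrame(rows, columns=["genotype_id", "treatment", "replicate",
                                     "measure", "das", "value"])
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
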