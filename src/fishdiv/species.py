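"""Species-table schema, I/O and record-selection rules.

The unit of analysis is one published microsatellite study per species: the
table carries the taxonomic ranks used as a phylogeny proxy, the habitat and
IUCN classifications, two life-history traits, and the study's sample size
and diversity estimates (mean observed heterozygosity and mean number of
alleles per locus).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import IOConfig

logger = logging.getLogger(__name__)

HABITATS = ("marine", "freshwater", "mixed")
IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD", "NE", "missing")

#: canonical CSV column order
COLUMNS = (
    "species_id",
    "class_rank",
    "order_rank",
    "family_rank",
    "genus_rank",
    "habitat",
    "iucn_category",
    "age_at_maturity",
    "fecundity",
    "n_individuals",
    "n_loci",
    "mean_obs_het",
    "mean_alleles",
    "rarefied_alleles",
)


class ConservationClass(str, Enum):
    """Binary threat status derived from the IUCN Red List category.

    Least-concern and near-threatened species count as not threatened;
    vulnerable, endangered and critically endangered as threatened. Extinct
    categories are removed from the dataset entirely, while data-deficient
    and not-evaluated species are dropped only from conservation-status
    models.
    """

    NOT_THREATENED = "not_threatened"
    THREATENED = "threatened"
    EXCLUDED_ALL = "excluded_all"
    EXCLUDED_CONSERVATION_ONLY = "excluded_conservation_only"


_IUCN_MAP = {
    "LC": ConservationClass.NOT_THREATENED,
    "NT": ConservationClass.NOT_THREATENED,
    "VU": ConservationClass.THREATENED,
    "EN": ConservationClass.THREATENED,
    "CR": ConservationClass.THREATENED,
    "EX": ConservationClass.EXCLUDED_ALL,
    "EW": ConservationClass.EXCLUDED_ALL,
    "DD": ConservationClass.EXCLUDED_CONSERVATION_ONLY,
    "NE": ConservationClass.EXCLUDED_CONSERVATION_ONLY,
    "missing": ConservationClass.EXCLUDED_CONSERVATION_ONLY,
}


class SpeciesTableError(ValueError):
    """Raised for malformed species tables; carries the offending row."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One study row: taxonomy, classifications, design and diversity."""

    species_id: str
    class_rank: str
    order_rank: str
    family_rank: str
    genus_rank: str
    habitat: str
    iucn_category: str = "missing"
    age_at_maturity: float | None = None
    fecundity: float | None = None
    n_individuals: int = 10
    n_loci: int = 1
    mean_obs_het: float | None = None
    mean_alleles: float = 1.0
    rarefied_alleles: int | None = None
    row: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise SpeciesTableError(
                f"row {self.row}: unknown habitat {self.habitat!r} "
                f"(expected one of {HABITATS})"
            )
        if self.iucn_category not in IUCN_CATEGORIES:
            raise SpeciesTableError(
                f"row {self.row}: unknown IUCN category {self.iucn_category!r}"
            )
        if self.mean_obs_het is not None and not 0.0 <= self.mean_obs_het <= 1.0:
            raise SpeciesTableError(
                f"row {self.row}: mean_obs_het {self.mean_obs_het} outside [0, 1]"
            )
        if self.mean_alleles < 1:
            raise SpeciesTableError(
                f"row {self.row}: mean_alleles {self.mean_alleles} < 1"
            )
        if self.n_individuals < 1 or self.n_loci < 1:
            raise SpeciesTableError(
                f"row {self.row}: n_individuals and n_loci must be >= 1"
            )
        if self.n_individuals < 10:
            logger.warning(
                "row %s (%s): n_individuals=%d below the usual minimum of 10",
                self.row, self.species_id, self.n_individuals,
            )
        if self.rarefied_alleles is not None and self.rarefied_alleles < 2:
            raise SpeciesTableError(
                f"row {self.row}: rarefied_alleles {self.rarefied_alleles} < 2"
            )
        for trait in ("age_at_maturity", "fecundity"):
            v = getattr(self, trait)
            if v is not None and v < 0:
                raise SpeciesTableError(f"row {self.row}: {trait} {v} < 0")

    @property
    def conservation(self) -> ConservationClass:
        return classify_conservation(self.iucn_category)


def classify_conservation(iucn_category: str) -> ConservationClass:
    """Map an IUCN category to the analysis' threat dichotomy."""
    try:
        return _IUCN_MAP[iucn_category]
    except KeyError:
        raise SpeciesTableError(f"unknown IUCN category {iucn_category!r}") from None


def _canonical_columns(header: Sequence[str], io_cfg: IOConfig) -> dict[str, str]:
    """Resolve header names (case-insensitive, synonym-aware) to canonical."""
    lookup: dict[str, str] = {}
    for canon, synonyms in io_cfg.column_synonyms.items():
        lookup[canon.lower()] = canon
        for s in synonyms:
            lookup[s.lower()] = canon
    for canon in COLUMNS:
        lookup.setdefault(canon.lower(), canon)
    mapping = {}
    for col in header:
        canon = lookup.get(col.strip().lower())
        if canon is not None:
            mapping[col] = canon
    return mapping


def _opt_float(value, row: int, column: str, strict: bool) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.upper() == "NA":
        return None
    try:
        return float(s)
    except ValueError:
        if strict:
            raise SpeciesTableError(
                f"row {row}: non-numeric value {s!r} in column {column}"
            ) from None
        logger.warning("row %d: non-numeric %r in %s treated as missing", row, s, column)
        return None


def parse_species_table(
    path: str | Path, io_cfg: IOConfig | None = None, strict: bool | None = None
) -> list[SpeciesRecord]:
    """Read a species CSV into validated records.

    Missing cells (empty or ``NA``) become explicit ``None``; the original
    1-based data-row number is kept on each record for error reporting. In
    strict mode a non-numeric diversity cell is an error, otherwise it is
    demoted to missing with a warning.
    """
    io_cfg = io_cfg or IOConfig()
    if strict is None:
        strict = io_cfg.strict
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = _canonical_columns(df.columns, io_cfg)
    df = df.rename(columns=mapping)
    required = set(COLUMNS) - {"rarefied_alleles", "iucn_category"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise SpeciesTableError(f"missing required columns: {sorted(missing_cols)}")
    if df.empty:
        logger.warning("species table %s has a header but no data rows", path)
        return []

    records: list[SpeciesRecord] = []
    for idx, raw in enumerate(df.to_dict("records"), start=1):
        def cell(col: str) -> str:
            return str(raw.get(col, "")).strip()

        iucn = cell("iucn_category") or "missing"
        if iucn.upper() == "NA":
            iucn = "missing"
        het = _opt_float(raw.get("mean_obs_het"), idx, "mean_obs_het", strict)
        alleles = _opt_float(raw.get("mean_alleles"), idx, "mean_alleles", strict)
        if alleles is None:
            raise SpeciesTableError(f"row {idx}: mean_alleles is required")
        rare = _opt_float(raw.get("rarefied_alleles"), idx, "rarefied_alleles", strict)
        records.append(
            SpeciesRecord(
                species_id=cell("species_id"),
                class_rank=cell("class_rank"),
                order_rank=cell("order_rank"),
                family_rank=cell("family_rank"),
                genus_rank=cell("genus_rank"),
                habitat=cell("habitat").lower(),
                iucn_category=iucn if iucn == "missing" else iucn.upper(),
                age_at_maturity=_opt_float(raw.get("age_at_maturity"), idx,
                                           "age_at_maturity", strict),
                fecundity=_opt_float(raw.get("fecundity"), idx, "fecundity", strict),
                n_individuals=int(float(cell("n_individuals"))),
                n_loci=int(float(cell("n_loci"))),
                mean_obs_het=het,
                mean_alleles=alleles,
                rarefied_alleles=None if rare is None else int(round(rare)),
                row=idx,
            )
        )
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_species_table(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    """Write records back to CSV in canonical column order (UTF-8, '' = missing)."""
    rows = []
    for r in records:
        rows.append({c: _fmt(getattr(r, c)) for c in COLUMNS})
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, index=False)


def select_best_study(records: Sequence[SpeciesRecord]) -> list[SpeciesRecord]:
    """Keep, per species, the study with the largest number of individuals.

    Ties keep the first record in input order (logged), so the operation is
    deterministic and idempotent.
    """
    best: dict[str, SpeciesRecord] = {}
    order: list[str] = []
    for rec in records:
        cur = best.get(rec.species_id)
        if cur is None:
            best[rec.species_id] = rec
            order.append(rec.species_id)
        elif rec.n_individuals > cur.n_individuals:
            best[rec.species_id] = rec
        elif rec.n_individuals == cur.n_individuals:
            logger.warning(
                "species %s: tie at n=%d, keeping first record (row %s)",
                rec.species_id, rec.n_individuals, cur.row,
            )
    return [best[sid] for sid in order]


def drop_extinct(records: Sequence[SpeciesRecord]) -> list[SpeciesRecord]:
    """Remove extinct / extinct-in-the-wild species from the dataset."""
    kept = [r for r in records
            if r.conservation is not ConservationClass.EXCLUDED_ALL]
    if len(kept) < len(records):
        logger.info("dropped %d extinct/extinct-in-the-wild records",
                    len(records) - len(kept))
    return kept


def filter_for_pgls(
    records: Sequence[SpeciesRecord], io_cfg: IOConfig | None = None
) -> list[SpeciesRecord]:
    """Trim to bony fishes (Osteichthyes, synonym-aware) for PGLS fitting.

    The other fish classes are represented by too few species for stable
    covariance estimation and are dropped with per-class counts logged.
    """
    io_cfg = io_cfg or IOConfig()
    accepted = {s.lower() for s in io_cfg.osteichthyes_synonyms}
    kept, dropped = [], {}
    for r in records:
        if r.class_rank.lower() in accepted:
            kept.append(r)
        else:
            dropped[r.class_rank] = dropped.get(r.class_rank, 0) + 1
    for cls, n in sorted(dropped.items()):
        logger.info("PGLS trim: dropped %d records of class %s", n, cls)
    if not kept:
        raise SpeciesTableError(
            "no records remain after the bony-fish trim; check class_rank values "
            f"against accepted synonyms {sorted(accepted)}"
        )
    return kept


def with_rarefied(record: SpeciesRecord, rarefied: int) -> SpeciesRecord:
    return replace(record, rarefied_alleles=rarefied)
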