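"""Reading and writing the package's tabular formats.

Population tables follow the public Living-Planet-style wide CSV dialect:
fixed metadata columns (ID, Binomial, Class, System, Realm, Zone, Units,
Source, Confidential) followed by one column per calendar year, with "NULL"
(also accepted: empty, "NA") marking unobserved years. Raw taxonomic classes
and realms are merged into the index groups at read time via configurable
mapping tables, so source files stay untouched and the merge is auditable.

Weight schemes are flat CSV or YAML tables with ``level`` in
{system, realm, taxon} plus ``system``, ``realm``, ``taxon``, ``weight`` and
an optional ``known_species`` column; weights are renormalized per parent on
read.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    DEFAULT_CLASS_MAP,
    DEFAULT_REALM_MAP,
    Dataset,
    PopulationRecord,
    ValidationWarning,
    WeightScheme,
)

METADATA_COLUMNS = (
    "ID",
    "Binomial",
    "Class",
    "System",
    "Realm",
    "Zone",
    "Units",
    "Source",
    "Confidential",
)

MISSING_TOKENS = {"NULL", "", "NA"}


def _map_label(raw: str, mapping: dict[str, str]) -> str:
    return mapping.get(raw.strip().lower(), raw.strip())


def read_population_table(
    path: str | Path,
    window: tuple[int, int] = (1970, 2012),
    class_map: dict[str, str] | None = None,
    realm_map: dict[str, str] | None = None,
) -> Dataset:
    """Read an LPD-style wide CSV into a validated Dataset.

    Observations outside the window are truncated; rows left with fewer than
    two observed years (or containing only zero counts of missingness
    tokens) are dropped with a ValidationWarning naming the population.
    """
    path = Path(path)
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    realm_map = DEFAULT_REALM_MAP if realm_map is None else realm_map
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_meta = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValueError(
            f"{path.name}: malformed header, missing column(s) {missing_meta}"
        )
    year_cols = []
    for c in df.columns:
        if c in METADATA_COLUMNS:
            continue
        try:
            year_cols.append((int(c), c))
        except ValueError:
            raise ValueError(
                f"{path.name}: column {c!r} is neither metadata nor an integer year"
            ) from None

    records: list[PopulationRecord] = []
    for _, row in df.iterrows():
        series: dict[int, float] = {}
        for year, col in year_cols:
            cell = row[col].strip()
            if cell.upper() in MISSING_TOKENS:
                continue
            series[year] = float(cell)
        record = PopulationRecord(
            population_id=row["ID"],
            binomial=row["Binomial"],
            group=_map_label(row["Class"], class_map),
            system=row["System"].strip().lower(),
            realm=_map_label(row["Realm"], realm_map),
            zone=row["Zone"].strip().lower(),
            series=series,
            units=row["Units"],
            source_id=row["Source"],
            confidential=row["Confidential"].strip().lower() in {"1", "true", "yes"},
        ).truncated(window)
        if len(record.series) < 2:
            warnings.warn(
                f"population {record.population_id!r}: fewer than 2 observed "
                "years inside the index window; excluded",
                ValidationWarning,
                stacklevel=2,
            )
            continue
        record.validate()
        records.append(record)
    return Dataset(records, window)


def write_population_table(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset back to the wide CSV dialect ("NULL" for missing)."""
    years = [int(y) for y in dataset.years]
    rows = []
    for r in dataset.records:
        row = {
            "ID": r.population_id,
            "Binomial": r.binomial,
            "Class": r.group,
            "System": r.system,
            "Realm": r.realm,
            "Zone": r.zone,
            "Units": r.units,
            "Source": r.source_id,
            "Confidential": int(r.confidential),
        }
        for y in years:
            row[str(y)] = repr(r.series[y]) if y in r.series else "NULL"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_weight_scheme(path: str | Path) -> WeightScheme:
    """Read a weight scheme from CSV or YAML.

    Rows with level "taxon" need system, realm, taxon and weight; rows with
    level "realm" need system, realm and weight; rows with level "system"
    need system and weight. Duplicate keys and negative weights raise.
    """
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        df = pd.DataFrame(raw if isinstance(raw, list) else raw["weights"])
    else:
        df = pd.read_csv(path)
    if "level" not in df.columns or "weight" not in df.columns:
        raise ValueError(f"{path.name}: weight table needs 'level' and 'weight' columns")

    taxon_w: dict[tuple[str, str, str], float] = {}
    realm_w: dict[tuple[str, str], float] = {}
    system_w: dict[str, float] = {}
    counts: dict[tuple[str, str, str], float] = {}
    for _, row in df.iterrows():
        level = str(row["level"]).strip().lower()
        weight = float(row["weight"])
        if weight < 0:
            raise ValueError(f"{path.name}: negative weight {weight}")
        system = str(row.get("system", "")).strip().lower()
        if level == "taxon":
            key = (system, str(row["realm"]).strip(), str(row["taxon"]).strip())
            if key in taxon_w:
                raise ValueError(f"{path.name}: duplicate taxon key {key}")
            taxon_w[key] = weight
            known = row.get("known_species")
            if known is not None and not pd.isna(known):
                counts[key] = float(known)
        elif level == "realm":
            rkey = (system, str(row["realm"]).strip())
            if rkey in realm_w:
                raise ValueError(f"{path.name}: duplicate realm key {rkey}")
            realm_w[rkey] = weight
        elif level == "system":
            if system in system_w:
                raise ValueError(f"{path.name}: duplicate system key {system!r}")
            system_w[system] = weight
        else:
            raise ValueError(f"{path.name}: unknown level {level!r}")
    if not taxon_w:
        raise ValueError(f"{path.name}: no taxon-level rows found")
    return WeightScheme(
        taxon_w,
        realm_weights=realm_w or None,
        system_weights=system_w or None,
        reference_counts=counts or None,
    )


def write_weight_scheme(scheme: WeightScheme, path: str | Path) -> None:
    """Write a (normalized) weight scheme to flat CSV."""
    rows = []
    for (system, realm, taxon), w in sorted(scheme.taxon_weights.items()):
        rows.append(
            {
                "level": "taxon",
                "system": system,
                "realm": realm,
                "taxon": taxon,
                "weight": w,
                "known_species": scheme.reference_counts.get((system, realm, taxon), ""),
            }
        )
    for (system, realm), w in sorted(scheme.realm_weights.items()):
        rows.append(
            {"level": "realm", "system": system, "realm": realm, "taxon": "", "weight": w, "known_species": ""}
        )
    for system, w in sorted(scheme.system_weights.items()):
        rows.append(
            {"level": "system", "system": system, "realm": "", "taxon": "", "weight": w, "known_species": ""}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_reference_counts(path: str | Path) -> dict[tuple[str, str, str], int]:
    """Known-species counts per (system, realm, taxon) from CSV."""
    df = pd.read_csv(path)
    needed = {"system", "realm", "taxon", "known_species"}
    if not needed.issubset(df.columns):
        raise ValueError(f"reference table needs columns {sorted(needed)}")
    out: dict[tuple[str, str, str], int] = {}
    for _, row in df.iterrows():
        key = (
            str(row["system"]).strip().lower(),
            str(row["realm"]).strip(),
            str(row["taxon"]).strip(),
        )
        if key in out:
            raise ValueError(f"duplicate reference key {key}")
        out[key] = int(row["known_species"])
    return out


def read_species_categories(path: str | Path) -> pd.DataFrame:
    """Species -> Red List category table (binomial, taxon, category[, criterion_a])."""
    df = pd.read_csv(path)
    needed = {"binomial", "taxon", "category"}
    if not needed.issubset(df.columns):
        raise ValueError(f"category table needs columns {sorted(needed)}")
    if "criterion_a" in df.columns:
        df["criterion_a"] = df["criterion_a"].astype(bool)
    return df


def write_index_result(result, path: str | Path) -> None:
    """Index (and CI bounds when present) as a tidy year-per-row CSV."""
    result.to_frame().to_csv(path, index=False)
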