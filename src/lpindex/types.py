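"""Domain containers shared across the pipeline.

Lambda arrays are always aligned to the full index window: position ``i``
holds the annual log10 rate of change from year ``base + i - 1`` to year
``base + i``, so position 0 (the baseline year) is always NaN, as is any year
a series does not cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

SYSTEMS = ("terrestrial", "freshwater", "marine")
ZONES = ("tropical", "temperate")

#: default merge of raw taxonomic classes into the four index groups
#: (reptiles and amphibians are pooled into one herpetological group)
DEFAULT_CLASS_MAP: dict[str, str] = {
    "aves": "Birds",
    "birds": "Birds",
    "mammalia": "Mammals",
    "mammals": "Mammals",
    "reptilia": "Herps",
    "amphibia": "Herps",
    "reptiles": "Herps",
    "amphibians": "Herps",
    "herps": "Herps",
    "actinopterygii": "Fish",
    "sarcopterygii": "Fish",
    "chondrichthyes": "Fish",
    "cephalaspidomorphi": "Fish",
    "petromyzontida": "Fish",
    "myxini": "Fish",
    "pisces": "Fish",
    "fish": "Fish",
    "fishes": "Fish",
}

#: default merge of small biogeographic realms into a combined Indo-Pacific
DEFAULT_REALM_MAP: dict[str, str] = {
    "australasia": "Indo-Pacific",
    "oceania": "Indo-Pacific",
    "indo-malaya": "Indo-Pacific",
    "indomalaya": "Indo-Pacific",
    "indo-pacific": "Indo-Pacific",
}


class ValidationWarning(UserWarning):
    """Emitted when an input record violates an invariant and is dropped."""


@dataclass
class PopulationRecord:
    """One monitored population: metadata plus a sparse year -> abundance map."""

    population_id: str
    binomial: str
    group: str
    system: str
    realm: str
    zone: str
    series: dict[int, float]
    units: str = ""
    source_id: str = ""
    confidential: bool = False

    def observed_years(self) -> list[int]:
        return sorted(self.series)

    def validate(self) -> None:
        if len(self.series) < 2:
            raise ValueError(
                f"population {self.population_id!r}: needs at least 2 observed years"
            )
        for year, value in self.series.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"population {self.population_id!r}: abundance in {year} "
                    f"is {value!r}, must be finite and >= 0"
                )
        if self.system not in SYSTEMS:
            raise ValueError(
                f"population {self.population_id!r}: unknown system {self.system!r}"
            )
        if self.zone not in ZONES:
            raise ValueError(
                f"population {self.population_id!r}: unknown zone {self.zone!r}"
            )

    def truncated(self, window: tuple[int, int]) -> "PopulationRecord":
        """Copy with observations outside [base, final] removed."""
        base, final = window
        series = {y: v for y, v in self.series.items() if base <= y <= final}
        return PopulationRecord(
            population_id=self.population_id,
            binomial=self.binomial,
            group=self.group,
            system=self.system,
            realm=self.realm,
            zone=self.zone,
            series=series,
            units=self.units,
            source_id=self.source_id,
            confidential=self.confidential,
        )


@dataclass
class Dataset:
    """A validated collection of population records over a fixed index window."""

    records: list[PopulationRecord]
    window: tuple[int, int] = (1970, 2012)

    def __post_init__(self) -> None:
        base, final = self.window
        if base >= final:
            raise ValueError(f"window base {base} must precede final {final}")
        ids = [r.population_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate population_id values: {dupes}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)

    def __len__(self) -> int:
        return len(self.records)

    def species(self) -> list[str]:
        return sorted({r.binomial for r in self.records})

    def group_keys(self) -> list[tuple[str, str, str]]:
        """Sorted distinct (system, realm, group) keys present."""
        return sorted({(r.system, r.realm, r.group) for r in self.records})

    def subset(self, predicate) -> "Dataset":
        return Dataset([r for r in self.records if predicate(r)], self.window)


def _year_index(years: np.ndarray, year: int) -> int:
    return int(year - years[0])


@dataclass
class LambdaSeries:
    """Annual log10 rates of change for one population, window-aligned."""

    label: str
    years: np.ndarray
    lambdas: np.ndarray
    method: str = "chain"  # "gam" or "chain"

    def defined_years(self) -> np.ndarray:
        return self.years[np.isfinite(self.lambdas)]


@dataclass
class SpeciesTrend:
    """Per-year mean annual log10 rate of change across a species' populations."""

    binomial: str
    years: np.ndarray
    lambdas: np.ndarray
    n_populations: np.ndarray = field(default=None)  # per-year contributing count


@dataclass
class GroupTrend:
    """Averaged trend for a hierarchy node, with per-year species counts."""

    key: tuple
    years: np.ndarray
    lambdas: np.ndarray
    n_species: np.ndarray


@dataclass
class IndexResult:
    """A baseline-1 index with optional bootstrap confidence bounds."""

    years: np.ndarray
    index: np.ndarray
    method: str  # "U" or "D"
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_species: int = 0
    n_populations: int = 0

    def __post_init__(self) -> None:
        if abs(self.index[0] - 1.0) > 0:
            raise ValueError("index must equal 1 exactly in the baseline year")
        if not np.all(self.index > 0):
            raise ValueError("index values must be positive")

    def final(self) -> float:
        return float(self.index[-1])

    def to_frame(self):
        import pandas as pd

        data = {"year": self.years, "index": self.index}
        if self.ci_low is not None:
            data["ci_low"] = self.ci_low
            data["ci_high"] = self.ci_high
        return pd.DataFrame(data)


class WeightScheme:
    """Three-level proportional weights: system, realm-within-system,
    taxon-within-realm-and-system.

    Weights are renormalized to sum to 1 within each parent on construction.
    ``reference_counts`` optionally carries the known-species counts the
    proportions were derived from.
    """

    def __init__(
        self,
        taxon_weights: Mapping[tuple[str, str, str], float],
        realm_weights: Mapping[tuple[str, str], float] | None = None,
        system_weights: Mapping[str, float] | None = None,
        reference_counts: Mapping[tuple[str, str, str], float] | None = None,
    ) -> None:
        for key, w in list(taxon_weights.items()):
            if w < 0:
                raise ValueError(f"negative weight {w} for {key}")
        if realm_weights:
            for key, w in realm_weights.items():
                if w < 0:
                    raise ValueError(f"negative weight {w} for {key}")
        self.taxon_weights = self._normalize(
            dict(taxon_weights), parent=lambda k: (k[0], k[1])
        )
        if realm_weights is None:
            # equal weights over the realms present in the taxon table
            realm_weights = {
                (s, r): 1.0 for (s, r, _t) in self.taxon_weights
            }
        self.realm_weights = self._normalize(
            dict(realm_weights), parent=lambda k: k[0]
        )
        if system_weights is None:
            systems = sorted({k[0] for k in self.realm_weights})
            system_weights = {s: 1.0 / len(systems) for s in systems}
        total = sum(system_weights.values())
        self.system_weights = {s: w / total for s, w in system_weights.items()}
        self.reference_counts = dict(reference_counts or {})

    @staticmethod
    def _normalize(weights: dict, parent) -> dict:
        sums: dict = {}
        for key, w in weights.items():
            sums[parent(key)] = sums.get(parent(key), 0.0) + w
        out = {}
        for key, w in weights.items():
            s = sums[parent(key)]
            if s <= 0:
                raise ValueError(
                    f"weights under parent {parent(key)!r} sum to {s}, must be > 0"
                )
            out[key] = w / s
        return out

    def taxon_weight(self, system: str, realm: str, taxon: str) -> float:
        try:
            return self.taxon_weights[(system, realm, taxon)]
        except KeyError:
            raise KeyError(
                f"no taxon weight for ({system!r}, {realm!r}, {taxon!r})"
            ) from None

    def realm_weight(self, system: str, realm: str) -> float:
        try:
            return self.realm_weights[(system, realm)]
        except KeyError:
            raise KeyError(f"no realm weight for ({system!r}, {realm!r})") from None

    def system_weight(self, system: str) -> float:
        try:
            return self.system_weights[system]
        except KeyError:
            raise KeyError(f"no system weight for {system!r}") from None

    def check_covers(self, keys: Iterable[tuple[str, str, str]]) -> None:
        """Raise listing every (system, realm, taxon) key without a weight."""
        missing = [
            k
            for k in keys
            if k not in self.taxon_weights or (k[0], k[1]) not in self.realm_weights
        ]
        if missing:
            raise KeyError(f"groups present in data but not in weight scheme: {missing}")

    @classmethod
    def equal(cls, keys: Iterable[tuple[str, str, str]]) -> "WeightScheme":
        """Equal weights at every level over the given keys (useful in tests)."""
        return cls({tuple(k): 1.0 for k in keys})
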