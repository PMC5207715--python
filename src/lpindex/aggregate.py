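"""Hierarchical aggregation of species trends into indices.

Two hierarchies are supported:

* **LPI-U** (unweighted): species trends are averaged within each of the six
  zone-by-system subsets (tropical/temperate x terrestrial/freshwater/marine);
  within each zone the three system trends are averaged equally; the two zone
  trends are averaged equally.
* **LPI-D** (diversity-weighted): species trends are averaged within each
  (system, realm, taxon) group; taxon trends are combined within each realm
  using the proportion of known species each taxon represents; realm trends
  are combined within each system by the realm's share of known species; the
  three system trends are averaged equally.

In both cases averaging happens on the lambda (log10 rate) scale and only the
final averaged trend is converted to an index with the baseline year set to 1
(I_t = I_{t-1} * 10^{lambda_t}). Where a child has no data in a year, the
weights of the children that do have data are renormalized to sum to one for
that year, so groups entering or leaving the record never create jumps.
"""

from __future__ import annotations

import warnings

import numpy as np

from .trends import PipelineConfig, population_lambdas, species_mean_lambdas
from .types import (
    Dataset,
    GroupTrend,
    IndexResult,
    SpeciesTrend,
    ValidationWarning,
    WeightScheme,
)


def group_mean(species: list[SpeciesTrend], key: tuple = ()) -> GroupTrend:
    """Per-year arithmetic mean of species lambdas, tracking species counts."""
    if not species:
        raise ValueError("need at least one species trend")
    years = species[0].years
    stack = np.vstack([s.lambdas for s in species])
    counts = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(stack, axis=0)
    means[counts == 0] = np.nan
    return GroupTrend(key=key, years=years, lambdas=means, n_species=counts)


def weighted_combine(
    children: list[GroupTrend], weights: list[float], key: tuple = ()
) -> GroupTrend:
    """Weighted per-year mean of child trends.

    In each year the weights of the children that have a lambda are
    renormalized to sum to one; a year with no data in any child stays NaN.
    """
    if not children:
        raise ValueError("need at least one child trend")
    if len(weights) != len(children):
        raise ValueError("one weight per child required")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    years = children[0].years
    stack = np.vstack([c.lambdas for c in children])
    present = np.isfinite(stack)
    wmat = np.where(present, w[:, None], 0.0)
    wsum = wmat.sum(axis=0)
    any_present = present.any(axis=0)
    if np.any(any_present & (wsum <= 0)):
        raise ValueError("all children present in some year carry zero weight")
    out = np.full(years.shape, np.nan)
    filled = np.where(present, stack, 0.0)
    valid = wsum > 0
    out[valid] = (wmat[:, valid] * filled[:, valid]).sum(axis=0) / wsum[valid]
    n_species = np.vstack([c.n_species for c in children]).sum(axis=0)
    return GroupTrend(key=key, years=years, lambdas=out, n_species=n_species)


def lambdas_to_index(
    lambdas: np.ndarray | dict[int, float],
    base_year: int,
    years: np.ndarray | None = None,
    on_missing: str = "error",
) -> np.ndarray:
    """Convert annual log10 rates to a baseline-1 index.

    I_base = 1 and I_t = I_{t-1} * 10^{lambda_t}. ``lambdas`` may be a
    window-aligned array (position 0 = base year, always ignored) or a
    year -> value dict covering consecutive years after ``base_year``.
    ``on_missing``: "error" raises on an undefined year after the baseline;
    "hold" carries the index over (treats the missing rate as 0).
    """
    if isinstance(lambdas, dict):
        if lambdas:
            last = max(lambdas)
            expect = range(base_year + 1, last + 1)
            if sorted(lambdas) != list(expect):
                raise ValueError("lambda years must be consecutive from base_year+1")
            arr = np.concatenate(
                ([np.nan], [lambdas[y] for y in expect])
            )
        else:
            arr = np.array([np.nan])
    else:
        arr = np.asarray(lambdas, dtype=float)
        if years is not None and years[0] != base_year:
            raise ValueError("years array must start at base_year")
    steps = arr[1:].copy()
    if np.any(~np.isfinite(steps)):
        if on_missing == "error":
            raise ValueError(
                "undefined lambda inside the index window; "
                "use on_missing='hold' to carry the index across gaps"
            )
        steps[~np.isfinite(steps)] = 0.0
    index = np.empty(arr.shape)
    index[0] = 1.0
    index[1:] = 10.0 ** np.cumsum(steps)
    return index


def annualized_rate(final_index: float, n_years: int) -> float:
    """Average annual percent change implied by a total index change.

    ``100 * (1 - final_index**(1/n_years))`` — positive for a decline,
    negative for an increase.
    """
    if final_index <= 0:
        raise ValueError("final_index must be > 0")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    return 100.0 * (1.0 - final_index ** (1.0 / n_years))


# ---------------------------------------------------------------------------
# species-trend computation and the two hierarchies
# ---------------------------------------------------------------------------

def species_trends(
    dataset: Dataset,
    key_fn,
    config: PipelineConfig | None = None,
) -> dict[tuple, list[SpeciesTrend]]:
    """Compute one trend per (group key, species) pair.

    ``key_fn`` maps a record to its lowest-level hierarchy key. A species
    recorded in two systems contributes one trend to each.
    """
    config = config or PipelineConfig()
    by_species: dict[tuple, list] = {}
    for record in dataset.records:
        lam = population_lambdas(record, dataset.window, config)
        if lam is None:
            continue
        by_species.setdefault((key_fn(record), record.binomial), []).append(lam)
    out: dict[tuple, list[SpeciesTrend]] = {}
    for (key, binomial), pops in sorted(by_species.items()):
        out.setdefault(key, []).append(species_mean_lambdas(pops, binomial))
    return out


def combine_u(
    groups: dict[tuple, list[SpeciesTrend]],
    years: np.ndarray,
    order: str = "systems_within_zone",
) -> GroupTrend:
    """Combine (zone, system) species-trend groups with equal weights.

    By default systems are averaged equally within each zone and the
    tropical and temperate trends then averaged equally. The alternative
    ``order="zones_within_system"`` averages zones within each system first;
    the two differ only when subsets are missing years.
    """
    if order not in ("systems_within_zone", "zones_within_system"):
        raise ValueError(f"unknown order {order!r}")
    outer_level = 0 if order == "systems_within_zone" else 1
    outer: list[GroupTrend] = []
    for label in sorted({k[outer_level] for k in groups}):
        inner = [
            group_mean(groups[k], key=k)
            for k in sorted(groups)
            if k[outer_level] == label
        ]
        outer.append(weighted_combine(inner, [1.0] * len(inner), key=(label,)))
    return weighted_combine(outer, [1.0] * len(outer), key=("global",))


def combine_d(
    groups: dict[tuple, list[SpeciesTrend]],
    weights: WeightScheme,
    years: np.ndarray,
) -> GroupTrend:
    """Combine (system, realm, taxon) groups through the weighted hierarchy."""
    weights.check_covers(groups.keys())
    system_trends: list[GroupTrend] = []
    system_w: list[float] = []
    for system in sorted({k[0] for k in groups}):
        realm_trends: list[GroupTrend] = []
        realm_w: list[float] = []
        for realm in sorted({k[1] for k in groups if k[0] == system}):
            taxa = [
                group_mean(groups[k], key=k)
                for k in sorted(groups)
                if k[0] == system and k[1] == realm
            ]
            taxon_w = [weights.taxon_weight(*t.key) for t in taxa]
            realm_trends.append(
                weighted_combine(taxa, taxon_w, key=(system, realm))
            )
            realm_w.append(weights.realm_weight(system, realm))
        system_trends.append(
            weighted_combine(realm_trends, realm_w, key=(system,))
        )
        system_w.append(weights.system_weight(system))
    return weighted_combine(system_trends, system_w, key=("global",))


def _finalize(
    trend: GroupTrend,
    dataset: Dataset,
    method: str,
    n_species: int,
    on_missing: str = "error",
) -> IndexResult:
    index = lambdas_to_index(
        trend.lambdas, dataset.window[0], years=trend.years, on_missing=on_missing
    )
    return IndexResult(
        years=trend.years,
        index=index,
        method=method,
        n_species=n_species,
        n_populations=len(dataset),
    )


def assemble_lpi_u(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    on_missing: str = "error",
    order: str = "systems_within_zone",
) -> IndexResult:
    """Build the unweighted index over the six zone-by-system subsets."""
    groups = species_trends(dataset, lambda r: (r.zone, r.system), config)
    if not groups:
        raise ValueError("dataset produced no usable species trends")
    trend = combine_u(groups, dataset.years, order=order)
    n_species = len({s.binomial for sts in groups.values() for s in sts})
    return _finalize(trend, dataset, "U", n_species, on_missing)


def assemble_lpi_d(
    dataset: Dataset,
    weights: WeightScheme,
    config: PipelineConfig | None = None,
    on_missing: str = "error",
) -> IndexResult:
    """Build the diversity-weighted index over (system, realm, taxon) groups."""
    groups = species_trends(dataset, lambda r: (r.system, r.realm, r.group), config)
    if not groups:
        raise ValueError("dataset produced no usable species trends")
    trend = combine_d(groups, weights, dataset.years)
    n_species = len({s.binomial for sts in groups.values() for s in sts})
    return _finalize(trend, dataset, "D", n_species, on_missing)


def exclude_low_representation(
    dataset: Dataset,
    representation: dict[tuple, float],
    threshold: float = 0.01,
) -> tuple[Dataset, list[tuple]]:
    """Drop every record whose (system, realm, taxon) group is represented by
    fewer than ``threshold`` of its known species.

    ``representation`` maps group keys to representation fractions (species
    in the dataset / known species). Returns the filtered dataset and the
    removed keys.
    """
    keys = dataset.group_keys()
    missing = [k for k in keys if k not in representation]
    if missing:
        raise KeyError(f"representation fractions missing for groups: {missing}")
    removed = sorted(k for k in keys if representation[k] < threshold)
    removed_set = set(removed)
    filtered = dataset.subset(
        lambda r: (r.system, r.realm, r.group) not in removed_set
    )
    if not filtered.records:
        warnings.warn(
            "all groups fall below the representation threshold; dataset is empty",
            ValidationWarning,
            stacklevel=2,
        )
    return filtered, removed
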