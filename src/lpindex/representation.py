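"""Representation diagnostics: how well a population database covers the
species that actually exist.

Two comparisons are provided, both built on a two-sample test of equal
proportions (2x2 chi-squared, Yates continuity correction by default):

* taxonomic coverage — for each realm, the share of dataset species in each
  taxonomic group versus that group's share of known species;
* Red List coverage — for each taxon, the share of dataset species in each
  extinction-risk category versus the share among all assessed species,
  optionally restricted to threatened species listed under the
  population-reduction criterion (Criterion A), whose listing implies a
  declining trend.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .types import Dataset, ValidationWarning

RED_LIST_CATEGORIES = ("LC", "NT/LR", "VU", "EN", "CR")
THREATENED = ("VU", "EN", "CR")

_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cut, mark in _STARS:
        if p < cut:
            return mark
    return ""


def proportion_test(x1: int, n1: int, x2: int, n2: int, correction: bool = True):
    """Two-sample test of equal proportions via a 2x2 chi-squared.

    Returns ``(chi2, p, direction)`` where direction is "over" when the
    first sample's proportion exceeds the second's, else "under" (ties
    count as "under").
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both totals must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        chi2, p = 0.0, 1.0  # degenerate margin: no evidence either way
    else:
        chi2, p, _, _ = chi2_contingency(table, correction=correction)
    direction = "over" if x1 / n1 > x2 / n2 else "under"
    return float(chi2), float(p), direction


def representation_table(
    dataset: Dataset,
    reference: dict[tuple[str, str, str], int],
    correction: bool = True,
) -> pd.DataFrame:
    """Coverage of known species per (system, realm, taxon) group.

    ``reference`` maps group keys to known-species counts and must cover
    every group present in the dataset. For each group the table reports the
    number of distinct species in the dataset, the representation fraction
    (dataset species / known species), and a within-realm test comparing the
    group's share of dataset species against its share of known species.
    """
    data_keys = dataset.group_keys()
    missing = [k for k in data_keys if k not in reference]
    if missing:
        raise KeyError(f"reference counts missing for groups: {missing}")
    # reference groups absent from the dataset still get a row (0% coverage)
    keys = sorted(set(data_keys) | set(reference))

    species_by_key: dict[tuple, set] = {k: set() for k in keys}
    for r in dataset.records:
        species_by_key[(r.system, r.realm, r.group)].add(r.binomial)

    rows = []
    realms = sorted({(s, r) for (s, r, _t) in keys})
    for system, realm in realms:
        taxa = [k for k in keys if k[0] == system and k[1] == realm]
        n1_total = sum(len(species_by_key[k]) for k in taxa)
        n2_total = sum(reference[k] for k in taxa)
        for key in taxa:
            n_in = len(species_by_key[key])
            n_known = reference[key]
            chi2, p, direction = proportion_test(
                n_in, max(n1_total, 1), n_known, max(n2_total, 1), correction
            )
            rows.append(
                {
                    "system": system,
                    "realm": realm,
                    "taxon": key[2],
                    "n_in_dataset": n_in,
                    "n_known": n_known,
                    "representation_fraction": n_in / n_known if n_known else np.nan,
                    "proportion_dataset": n_in / n1_total if n1_total else 0.0,
                    "proportion_reference": n_known / n2_total if n2_total else 0.0,
                    "chi2": chi2,
                    "p": p,
                    "direction": direction,
                    "significant": p < 0.05,
                    "stars": _stars(p),
                }
            )
    return pd.DataFrame(rows)


def redlist_comparison(
    species: pd.DataFrame,
    reference: pd.DataFrame,
    criterion_a_only: bool = False,
    correction: bool = True,
) -> pd.DataFrame:
    """Compare Red List category shares in a dataset against all assessed species.

    ``species`` needs columns ``binomial``, ``taxon``, ``category`` and
    (optionally) a boolean ``criterion_a``; ``reference`` needs ``taxon``,
    ``category``, ``count`` and (optionally) ``count_a`` with the number of
    threatened species assessed under Criterion A. Categories are restricted
    to LC, NT/LR, VU, EN, CR — Data Deficient, Extinct and Extinct in the
    Wild species do not belong here because no abundance trend is expected
    for them, and an unknown label raises.

    With ``criterion_a_only``, threatened species (VU/EN/CR) lacking a
    Criterion A flag are dropped from the dataset side, and the reference
    counts for threatened categories switch to ``count_a``.
    """
    species = species.drop_duplicates(subset=["binomial", "taxon"]).copy()
    bad = set(species["category"]) - set(RED_LIST_CATEGORIES)
    if bad:
        raise ValueError(f"unknown Red List categories: {sorted(bad)}")
    bad = set(reference["category"]) - set(RED_LIST_CATEGORIES)
    if bad:
        raise ValueError(f"unknown Red List categories in reference: {sorted(bad)}")

    ref = reference.copy()
    if criterion_a_only:
        flags = species.get("criterion_a")
        if flags is None:
            flags = pd.Series(False, index=species.index)
        threatened = species["category"].isin(THREATENED)
        species = species[~threatened | flags.fillna(False).astype(bool)]
        if "count_a" in ref.columns:
            is_thr = ref["category"].isin(THREATENED)
            ref.loc[is_thr, "count"] = ref.loc[is_thr, "count_a"]
        if not (species["category"].isin(THREATENED)).any():
            warnings.warn(
                "no threatened species carry a Criterion A flag; "
                "threatened rows are empty",
                ValidationWarning,
                stacklevel=2,
            )

    rows = []
    for taxon in sorted(set(species["taxon"]) | set(ref["taxon"])):
        sp_t = species[species["taxon"] == taxon]
        ref_t = ref[ref["taxon"] == taxon]
        n1 = len(sp_t)
        n2 = int(ref_t["count"].sum())
        if n1 == 0 or n2 == 0:
            continue
        for category in RED_LIST_CATEGORIES:
            x1 = int((sp_t["category"] == category).sum())
            x2 = int(ref_t.loc[ref_t["category"] == category, "count"].sum())
            chi2, p, direction = proportion_test(x1, n1, x2, n2, correction)
            rows.append(
                {
                    "taxon": taxon,
                    "category": category,
                    "n_in_dataset": x1,
                    "n_dataset_total": n1,
                    "n_reference": x2,
                    "n_reference_total": n2,
                    "proportion_dataset": x1 / n1,
                    "proportion_reference": x2 / n2,
                    "chi2": chi2,
                    "p": p,
                    "direction": direction,
                    "significant": p < 0.05,
                    "stars": _stars(p),
                }
            )
    return pd.DataFrame(rows)
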