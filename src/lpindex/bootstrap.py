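"""Bootstrap confidence intervals for assembled indices.

Species are the resampling unit: within each lowest-level hierarchy group
(zone x system for the unweighted index, system x realm x taxon for the
weighted one) species trends are drawn with replacement, preserving each
group's size so the hierarchy weights keep their meaning. The full hierarchy
is recomputed for every iteration and per-year percentile bounds are taken
across iterations; the point estimate is always the non-resampled index.

A single seed determines every draw, so identical seeds give bit-identical
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .aggregate import combine_d, combine_u, lambdas_to_index, species_trends
from .trends import PipelineConfig
from .types import Dataset, IndexResult, WeightScheme

log = logging.getLogger(__name__)


@dataclass
class BootstrapConfig:
    """Resampling settings: iteration count, seed and interval level."""

    n_iterations: int = 10_000
    seed: int = 0
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


def bootstrap_index(
    dataset: Dataset,
    method: str = "u",
    weights: WeightScheme | None = None,
    cfg: BootstrapConfig | None = None,
    pipeline: PipelineConfig | None = None,
) -> IndexResult:
    """Assemble an index and attach percentile bootstrap confidence bounds.

    ``method`` selects the hierarchy ("u" or "d"; "d" requires ``weights``).
    Missing group-years arising from resampling are carried across (rate 0)
    so every iteration yields a full-length index.
    """
    cfg = cfg or BootstrapConfig()
    method = method.lower()
    if method == "d" and weights is None:
        raise ValueError("the weighted hierarchy needs a WeightScheme")
    if method == "u":
        key_fn = lambda r: (r.zone, r.system)
        combine = lambda groups: combine_u(groups, dataset.years)
    elif method == "d":
        key_fn = lambda r: (r.system, r.realm, r.group)
        combine = lambda groups: combine_d(groups, weights, dataset.years)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'u' or 'd'")

    groups = species_trends(dataset, key_fn, pipeline)
    if not groups:
        raise ValueError("dataset produced no usable species trends")
    for key, sts in groups.items():
        if len(sts) == 1:
            log.info("group %s has a single species; its resample is degenerate", key)

    base = dataset.window[0]
    point_trend = combine(groups)
    point = lambdas_to_index(point_trend.lambdas, base, on_missing="hold")

    rng = np.random.default_rng(cfg.seed)
    keys = sorted(groups)
    sizes = {k: len(groups[k]) for k in keys}
    n_years = len(dataset.years)
    paths = np.empty((cfg.n_iterations, n_years))
    for it in range(cfg.n_iterations):
        resampled = {
            k: [groups[k][j] for j in rng.integers(0, sizes[k], size=sizes[k])]
            for k in keys
        }
        trend = combine(resampled)
        paths[it] = lambdas_to_index(trend.lambdas, base, on_missing="hold")

    lo = (1.0 - cfg.level) / 2.0
    ci_low = np.quantile(paths, lo, axis=0)
    ci_high = np.quantile(paths, 1.0 - lo, axis=0)
    n_species = len({s.binomial for sts in groups.values() for s in sts})
    return IndexResult(
        years=dataset.years,
        index=point,
        method=method.upper(),
        ci_low=ci_low,
        ci_high=ci_high,
        n_species=n_species,
        n_populations=len(dataset),
    )
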