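"""Cluster annotation and population quantification.

Clusters are annotated with per-marker expression categories on a 1-4
scale (1: negative, 2: low, 3: positive, 4: high) and the multimer+
population is called with a fixed cutoff rule: CD3 > 1 (when the panel
stains CD3), CD8 > 1, multimer > 2, and — for dump-channel panels —
dump = 1.  The same rule is applied to every sample; no per-sample
tuning.

The category of a cluster on a marker is the quartile (by equal-width
split of the observed event-value range on the analysis scale) into
which its centroid falls.  This is a deliberately simple, deterministic
rule; like any fixed cutoff it can misfire on samples whose intensity
layout deviates from the bulk, which the evaluation layer is able to
exhibit.

Frequencies are reported on two denominators: live single lymphocytes
(primary) and CD8+ T cells (when a CD8 denominator is supplied).  A
population counts as detected when it holds at least `threshold_events`
events — by default 10, the conventional threshold for calling a
positive multimer staining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cluster import ClusterModel

#: Number of expression categories and their semantics.
N_LEVELS = 4
LEVEL_SEMANTICS = {1: "negative", 2: "low", 3: "positive", 4: "high"}

#: Default event threshold for calling a population detected.
DEFAULT_DETECTION_THRESHOLD = 10


@dataclass
class PopulationCall:
    """A multimer+ population call for one sample."""

    multimer_cluster_ids: frozenset
    event_count: int
    denominator_live_single: int
    denominator_cd8: int | None
    freq_of_lymphocytes: float
    freq_of_cd8: float | None
    detected: bool
    threshold_events: int = DEFAULT_DETECTION_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq_of_lymphocytes <= 100.0:
            raise ValueError("frequency out of [0, 100]")


ExpressionCategory = dict[int, dict[str, int]]
"""Per cluster id, per marker role: expression level in {1, 2, 3, 4}."""


def categorize_expression(model: ClusterModel) -> ExpressionCategory:
    """Assign each cluster a 1-4 level per clustering marker.

    The observed event range of each channel (the model's frozen
    normalization scale) is split into four equal-width intervals; a
    cluster's level on a marker is the interval its centroid falls in.
    A degenerate channel (max = min) yields level 1 for every cluster,
    with a warning.
    """
    scaled = model.scaled_centroids()
    categories: ExpressionCategory = {}
    degenerate = model.scale[:, 1] <= model.scale[:, 0]
    if degenerate.any():
        bad = [model.channel_roles[j] for j in np.flatnonzero(degenerate)]
        warnings.warn(
            f"categorize_expression: degenerate range on {bad}; level 1 assigned"
        )
    for i in range(model.n_clusters):
        levels = {}
        for j, role in enumerate(model.channel_roles):
            if degenerate[j]:
                levels[role] = 1
            else:
                levels[role] = int(np.clip(np.floor(scaled[i, j] * N_LEVELS), 0,
                                           N_LEVELS - 1)) + 1
        categories[i] = levels
    return categories


def call_multimer_population(
    categories: ExpressionCategory,
    multimer_role: str = "multimer-PE",
) -> frozenset:
    """Select the multimer+ clusters with the fixed cutoff rule.

    A cluster is selected iff its level is > 2 on the multimer channel and
    > 1 on CD8; when CD3 was clustered its level must be > 1, and when a
    dump channel was clustered its level must be exactly 1 (lineage
    exclusion).  The rule is monotone in the multimer level.
    """
    if not categories:
        raise ValueError("no clusters to annotate")
    roles_present = set(next(iter(categories.values())))
    if multimer_role not in roles_present:
        raise ValueError(
            f"multimer role {multimer_role!r} absent from clustering roles "
            f"{sorted(roles_present)}"
        )
    if "CD8" not in roles_present and len(roles_present) > 2:
        raise ValueError("annotation rule requires a CD8 channel")
    selected = set()
    for cid, levels in categories.items():
        if levels[multimer_role] <= 2:
            continue
        if "CD8" in levels and levels["CD8"] <= 1:
            continue
        if "CD3" in levels and levels["CD3"] <= 1:
            continue
        if "dump" in levels and levels["dump"] != 1:
            continue
        selected.add(cid)
    return frozenset(selected)


def compute_frequencies(
    multimer_cluster_ids: frozenset | Sequence[int],
    cluster_counts: np.ndarray,
    live_single_count: int,
    cd8_count: int | None = None,
    threshold_events: int = DEFAULT_DETECTION_THRESHOLD,
) -> PopulationCall:
    """Turn selected clusters into a population call with frequencies on
    the live-single-lymphocyte (primary) and CD8 (optional) denominators.
    """
    if live_single_count <= 0:
        raise ZeroDivisionError("live_single_count must be positive")
    if cd8_count is not None and cd8_count <= 0:
        raise ZeroDivisionError("cd8_count, when given, must be positive")
    ids = frozenset(int(i) for i in multimer_cluster_ids)
    event_count = int(sum(int(cluster_counts[i]) for i in ids))
    freq_lsl = 100.0 * event_count / live_single_count
    freq_cd8 = 100.0 * event_count / cd8_count if cd8_count else None
    return PopulationCall(
        multimer_cluster_ids=ids,
        event_count=event_count,
        denominator_live_single=live_single_count,
        denominator_cd8=cd8_count,
        freq_of_lymphocytes=freq_lsl,
        freq_of_cd8=freq_cd8,
        detected=event_count >= threshold_events,
        threshold_events=threshold_events,
    )


def mean_of_duplicates(freqs: Sequence[float]) -> float:
    """Report the arithmetic mean of duplicate runs; a single value passes
    through unchanged (single-run fallback)."""
    if len(freqs) == 0:
        raise ValueError("mean_of_duplicates: empty list")
    return float(np.mean(freqs))
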