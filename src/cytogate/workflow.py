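"""End-to-end analysis workflows.

:class:`AutoGatingPipeline` chains the stages for one sample: arcsinh
transform of fluorescence channels, DAG density-contour prefiltering to
live single lymphocytes, grid-density clustering on the marker channels,
1-4 expression categorization, and the fixed multimer+ cutoff rule.  The
primary output is the multimer+ frequency as a percentage of live single
lymphocytes (the prefiltered events); when ground-truth labels are
present, the CD8-denominator frequency is also computed from the
label-true CD8+ count.

Two alternative orchestrations mirror common automated-gating designs:
``analyze_with_template`` clusters a subsampled multi-sample consensus
once and assigns every sample to the shared centroids;
``two_stage_analyze`` clusters scatter/viability first, keeps the
lymphocyte-like clusters, then re-clusters CD8 x multimer within them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .annotate import (
    DEFAULT_DETECTION_THRESHOLD,
    PopulationCall,
    call_multimer_population,
    categorize_expression,
    compute_frequencies,
)
from .cluster import (
    ClusterModel,
    GridDensityCluster,
    assign_to_centroids,
    build_template,
)
from .io import EventTable, arcsinh_transform, subsample_concat
from .prefilter import DAGPrefilter, GateStep
from .simulate import CD8_LABELS

DEFAULT_COFACTOR = 150.0


def _prepare(table: EventTable, cofactor: float) -> EventTable:
    return arcsinh_transform(table, cofactor) if table.transform_state == "raw" else table


def _truth_cd8_count(table: EventTable) -> int | None:
    if table.labels is None:
        return None
    n = int(np.isin(table.labels, list(CD8_LABELS)).sum())
    return n if n > 0 else None


class AutoGatingPipeline(BaseEstimator):
    """Full automated gating of one sample, scikit-learn style.

    Parameters
    ----------
    steps : list of GateStep or None
        DAG gate sequence; None = default lymphocyte/singlet/viability
        sequence.
    cofactor : float
        arcsinh cofactor for fluorescence channels.
    cluster_roles : sequence of str or None
        Marker roles for clustering; None = all marker roles present.
    bins, min_density, max_clusters
        Grid-density clustering parameters.
    multimer_role : str
        Which multimer channel the cutoff rule targets.
    threshold_events : int
        Detection threshold (events) for the ``detected`` flag.

    Attributes
    ----------
    prefilter_ : fitted DAGPrefilter
    clusterer_ : fitted GridDensityCluster
    categories_ : per-cluster 1-4 levels per marker
    call_ : PopulationCall for the fitted sample
    """

    def __init__(
        self,
        steps: list[GateStep] | None = None,
        cofactor: float = DEFAULT_COFACTOR,
        cluster_roles: Sequence[str] | None = None,
        bins: int = 16,
        min_density: int | None = None,
        max_clusters: int = 100,
        multimer_role: str = "multimer-PE",
        threshold_events: int = DEFAULT_DETECTION_THRESHOLD,
    ):
        self.steps = steps
        self.cofactor = cofactor
        self.cluster_roles = cluster_roles
        self.bins = bins
        self.min_density = min_density
        self.max_clusters = max_clusters
        self.multimer_role = multimer_role
        self.threshold_events = threshold_events

    def fit(self, X: EventTable, y=None) -> "AutoGatingPipeline":
        prepared = _prepare(X, self.cofactor)
        self.prefilter_ = DAGPrefilter(steps=self.steps)
        retained = self.prefilter_.fit_transform(prepared)
        self.retained_n_ = retained.n_events
        self.clusterer_ = GridDensityCluster(
            roles=self.cluster_roles, bins=self.bins,
            min_density=self.min_density, max_clusters=self.max_clusters,
        ).fit(retained)
        self.categories_ = categorize_expression(self.clusterer_.model_)
        ids = call_multimer_population(self.categories_, self.multimer_role)
        self.call_ = compute_frequencies(
            ids,
            self.clusterer_.model_.counts,
            live_single_count=retained.n_events,
            cd8_count=_truth_cd8_count(retained),
            threshold_events=self.threshold_events,
        )
        return self

    def analyze(self, table: EventTable) -> PopulationCall:
        """Fit on `table` and return its population call."""
        return self.fit(table).call_


# ----------------------------------------------------------------------
# Template (consensus) mode
# ----------------------------------------------------------------------


@dataclass
class TemplateResult:
    template: ClusterModel
    categories: dict
    multimer_cluster_ids: frozenset
    calls: list[PopulationCall]


def analyze_with_template(
    samples: Sequence[EventTable],
    n_per_sample: int = 250_000,
    seed: int = 0,
    steps: list[GateStep] | None = None,
    cofactor: float = DEFAULT_COFACTOR,
    cluster_roles: Sequence[str] | None = None,
    bins: int = 16,
    min_density: int | None = None,
    max_clusters: int = 100,
    multimer_role: str = "multimer-PE",
    threshold_events: int = DEFAULT_DETECTION_THRESHOLD,
) -> TemplateResult:
    """Consensus-template workflow over a set of samples.

    Each sample is prefiltered with DAG; up to `n_per_sample` retained
    events per sample form the consensus, which is clustered once into a
    reference template.  Every sample is then assigned to the template
    centroids, and the single template annotation yields each sample's
    multimer+ call.
    """
    retained: list[EventTable] = []
    for t in samples:
        prepared = _prepare(t, cofactor)
        retained.append(DAGPrefilter(steps=steps).fit_transform(prepared))
    consensus = subsample_concat(retained, n_per_sample, seed=seed)
    roles = cluster_roles
    if roles is None:
        roles = GridDensityCluster()._resolve_roles(consensus)
    template = build_template(consensus, roles, bins=bins,
                              min_density=min_density, max_clusters=max_clusters)
    categories = categorize_expression(template)
    ids = call_multimer_population(categories, multimer_role)
    calls = []
    for t in retained:
        _, counts = assign_to_centroids(t, template)
        calls.append(
            compute_frequencies(
                ids, counts, live_single_count=t.n_events,
                cd8_count=_truth_cd8_count(t), threshold_events=threshold_events,
            )
        )
    return TemplateResult(template=template, categories=categories,
                          multimer_cluster_ids=ids, calls=calls)


# ----------------------------------------------------------------------
# Two-stage mode
# ----------------------------------------------------------------------

#: Analysis-scale rectangle a stage-1 cluster centroid must fall in to
#: count as live lymphocytes: (FSC-A lo, FSC-A hi, SSC-A lo, SSC-A hi,
#: viability hi on the arcsinh scale).
DEFAULT_STAGE1_SELECTION = (26_000.0, 88_000.0, 0.0, 55_000.0, 4.0)


def two_stage_analyze(
    table: EventTable,
    cofactor: float = DEFAULT_COFACTOR,
    stage1_bins: int = 16,
    stage2_bins: int = 16,
    min_density: int | None = None,
    selection: tuple[float, float, float, float, float] = DEFAULT_STAGE1_SELECTION,
    multimer_role: str = "multimer-PE",
    threshold_events: int = DEFAULT_DETECTION_THRESHOLD,
) -> PopulationCall:
    """Two-stage clustering: scatter/viability clusters first, automated
    selection of lymphocyte-like clusters by centroid position, then
    CD8 x multimer clustering within the selection.

    The lymphocyte selection that is done by eye in interactive tools is
    replaced by the `selection` rectangle test on stage-1 centroids.
    """
    prepared = _prepare(table, cofactor)
    stage1_roles = [r for r in ("FSC-A", "SSC-A", "viability")
                    if prepared.has_role(r)]
    s1 = GridDensityCluster(roles=stage1_roles, bins=stage1_bins,
                            min_density=min_density).fit(prepared)
    model = s1.model_
    fa_lo, fa_hi, ss_lo, ss_hi, via_hi = selection
    role_idx = {r: j for j, r in enumerate(model.channel_roles)}
    keep_ids = []
    for i in range(model.n_clusters):
        c = model.centroids[i]
        if not fa_lo <= c[role_idx["FSC-A"]] <= fa_hi:
            continue
        if not ss_lo <= c[role_idx["SSC-A"]] <= ss_hi:
            continue
        if "viability" in role_idx and c[role_idx["viability"]] > via_hi:
            continue
        keep_ids.append(i)
    if not keep_ids:
        raise RuntimeError("two_stage_analyze: no stage-1 cluster passes the "
                           "lymphocyte selection")
    mask = np.isin(s1.labels_, keep_ids)
    selected = prepared.take(np.flatnonzero(mask))

    s2 = GridDensityCluster(roles=["CD8", multimer_role], bins=stage2_bins,
                            min_density=min_density).fit(selected)
    categories = categorize_expression(s2.model_)
    ids = call_multimer_population(categories, multimer_role)
    return compute_frequencies(
        ids, s2.model_.counts, live_single_count=selected.n_events,
        cd8_count=_truth_cd8_count(selected), threshold_events=threshold_events,
    )
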