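"""Correlation-graph construction, cluster filtering, merging and labelling.

The unsupervised discovery of responder classes works in four steps:

1. pairwise Pearson correlation between epoch-averaged dF/F feature
   vectors of responder cells; r above a threshold (default 0.9, signed —
   anticorrelation never creates an edge) draws an unweighted edge;
2. cells with no supra-threshold edge drop out of the graph;
3. the graph is clustered with MCL (see :mod:`drgpop.mcl`) and clusters
   below a minimum size are dissolved into an "unclustered" pool;
4. clusters whose centroids are near-identical in shape (centroid Pearson
   r above a merge threshold, default 0.95) are merged iteratively. This
   replaces, with a deterministic rule, the supervised merging of
   biologically equivalent clusters a human would perform; an explicit
   user-supplied merge map takes precedence when given.

Merged clusters are finally labelled by centroid shape: for the pressure
ramp, ``Ramp`` when an affine fit against cuff pressure explains the
centroid (R^2 >= 0.9, positive slope), otherwise ``Low`` / ``Mid`` /
``High`` by the pressure at the centroid's peak; for movement,
``Extension`` / ``Flexion`` by the dominant event type, ``Const`` when
both types carry near-equal mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .mcl import MclParams, MclResult, mcl
from .protocol import StimulusProtocol
from .traces import FeatureMatrix

log = logging.getLogger(__name__)

R_EDGE_THRESHOLD = 0.9
CENTROID_MERGE_R = 0.95
RAMP_R2_MIN = 0.9
LOW_MAX_MMHG = 100.0
HIGH_MIN_MMHG = 300.0
CONST_PARITY_TOL = 0.2


def build_correlation_graph(
    feature_matrix: FeatureMatrix, r_threshold: float = R_EDGE_THRESHOLD
) -> nx.Graph:
    """Pearson-correlation graph over feature-vector rows.

    Edges connect cells with r strictly above ``r_threshold``; isolated
    cells are absent from the graph. Cells with zero-variance feature
    vectors (Pearson undefined) are excluded and logged; their ids are
    recorded in ``graph.graph["excluded"]``.
    """
    if len(feature_matrix.cell_ids) < 2:
        raise ValidationError("need at least 2 cells to build a graph")
    if len(feature_matrix.epoch_labels) < 3:
        raise ValidationError("need at least 3 epochs per feature vector")

    values = feature_matrix.values
    sd = values.std(axis=1)
    keep = sd > 0
    excluded = [c for c, k in zip(feature_matrix.cell_ids, keep) if not k]
    for c in excluded:
        log.warning("excluding cell %s: zero-variance feature vector", c)

    ids = [c for c, k in zip(feature_matrix.cell_ids, keep) if k]
    graph = nx.Graph(threshold=r_threshold, excluded=excluded)
    if len(ids) >= 2:
        r = np.corrcoef(values[keep])
        iu, ju = np.triu_indices(len(ids), k=1)
        for i, j in zip(iu, ju):
            if r[i, j] > r_threshold:
                graph.add_edge(ids[i], ids[j], r=float(r[i, j]))
    return graph


def filter_small_clusters(
    clusters: Sequence[frozenset], min_cluster_size: int
) -> tuple[list[frozenset], set]:
    """Dissolve clusters below the minimum size into an unclustered pool."""
    kept, unclustered = [], set()
    for c in clusters:
        if len(c) >= min_cluster_size:
            kept.append(c)
        else:
            unclustered.update(c)
    return kept, unclustered


@dataclass
class ClusterResult:
    """A labelled partition of responder cells into response classes."""

    assignments: dict  # cell_id -> cluster_id or "unclustered"
    members: dict  # cluster_id -> list of cell_ids
    centroids: dict  # cluster_id -> mean feature vector (np.ndarray)
    epoch_labels: list[str]
    labels: dict = field(default_factory=dict)  # cluster_id -> archetype name
    merge_log: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def assignments_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": cell,
                "cluster_id": cid,
                "label": self.labels.get(cid, "") if cid != "unclustered" else "",
            }
            for cell, cid in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["cell_id", "cluster_id", "label"])

    def centroids_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {cid: self.centroids[cid] for cid in sorted(self.centroids)},
            index=self.epoch_labels,
        ).T
        df.index.name = "cluster_id"
        return df


def _centroid(fm: FeatureMatrix, cells: Sequence[str]) -> np.ndarray:
    idx = [fm.cell_ids.index(c) for c in cells]
    return fm.values[idx].mean(axis=0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def merge_clusters(
    clusters: Sequence[frozenset],
    feature_matrix: FeatureMatrix,
    centroid_r_threshold: float = CENTROID_MERGE_R,
    unclustered: Optional[set] = None,
    merge_map: Optional[Mapping[int, int]] = None,
) -> ClusterResult:
    """Merge near-identical clusters by centroid correlation.

    Iteratively merges the pair of clusters whose centroids correlate the
    strongest, as long as that correlation exceeds ``centroid_r_threshold``;
    the centroid is recomputed after every merge and each action is
    recorded in the merge log. A ``merge_map`` of raw-cluster index ->
    raw-cluster index overrides the automatic rule entirely.
    """
    if not clusters:
        raise ValidationError("nothing to merge: no clusters")
    groups: list[set] = [set(c) for c in clusters]
    merge_log: list[dict] = []

    if merge_map is not None:
        valid = range(len(groups))
        for src, dst in merge_map.items():
            if src not in valid or dst not in valid:
                raise ValidationError(f"merge map names unknown cluster id: {src}->{dst}")
        target: dict[int, int] = {}

        def resolve(i: int) -> int:
            seen = set()
            while i in merge_map and i not in seen:
                seen.add(i)
                i = merge_map[i]
            return i

        merged: dict[int, set] = {}
        for i, g in enumerate(groups):
            root = resolve(i)
            merged.setdefault(root, set()).update(g)
            if root != i:
                merge_log.append({"action": "merge", "source": i, "target": root, "rule": "map"})
        groups = list(merged.values())
    else:
        while len(groups) > 1:
            best_r, best_pair = -np.inf, None
            cents = [_centroid(feature_matrix, sorted(g)) for g in groups]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    r = _pearson(cents[i], cents[j])
                    if r > best_r:
                        best_r, best_pair = r, (i, j)
            if best_r <= centroid_r_threshold:
                break
            i, j = best_pair
            merge_log.append(
                {"action": "merge", "source": j, "target": i, "r": round(best_r, 6), "rule": "centroid"}
            )
            groups[i] = groups[i] | groups[j]
            del groups[j]

    # stable ids: biggest cluster first, ties by smallest member id
    groups.sort(key=lambda g: (-len(g), min(g)))
    members = {f"C{k + 1}": sorted(g) for k, g in enumerate(groups)}
    assignments = {cell: cid for cid, cells in members.items() for cell in cells}
    for cell in unclustered or ():
        assignments[cell] = "unclustered"
    centroids = {cid: _centroid(feature_matrix, cells) for cid, cells in members.items()}
    return ClusterResult(
        assignments=assignments,
        members=members,
        centroids=centroids,
        epoch_labels=list(feature_matrix.epoch_labels),
        merge_log=merge_log,
    )


def label_clusters(result: ClusterResult, protocol: StimulusProtocol) -> ClusterResult:
    """Name each cluster after the response archetype its centroid matches."""
    if protocol.kind == "pressure_ramp":
        intensities = np.array(
            [e.intensity for e in protocol.stimulation_epochs], dtype=float
        )
        for cid, centroid in result.centroids.items():
            result.labels[cid] = _label_pressure(centroid, intensities)
    elif protocol.kind == "movement":
        is_ext = np.array(
            [e.label.startswith("E") for e in protocol.stimulation_epochs]
        )
        for cid, centroid in result.centroids.items():
            result.labels[cid] = _label_movement(centroid, is_ext)
    else:
        raise ValidationError(f"cannot label clusters for protocol kind {protocol.kind!r}")
    return result


def _label_pressure(centroid: np.ndarray, intensities: np.ndarray) -> str:
    if centroid.size == 0 or not np.any(centroid):
        return "unknown"
    if centroid.std() > 0:
        fit = stats.linregress(intensities, centroid)
        if fit.slope > 0 and fit.rvalue**2 >= RAMP_R2_MIN:
            return "Ramp"
    peak = float(intensities[int(np.argmax(centroid))])
    if peak < LOW_MAX_MMHG:
        return "Low"
    if peak >= HIGH_MIN_MMHG:
        return "High"
    return "Mid"


def _label_movement(centroid: np.ndarray, is_extension: np.ndarray) -> str:
    if centroid.size == 0 or not np.any(centroid):
        return "unknown"
    mass = np.clip(centroid, 0.0, None)
    e_mass = float(mass[is_extension].sum())
    f_mass = float(mass[~is_extension].sum())
    top = max(e_mass, f_mass)
    if top == 0:
        return "unknown"
    if abs(e_mass - f_mass) / top <= CONST_PARITY_TOL:
        return "Const"
    return "Extension" if e_mass > f_mass else "Flexion"


def cluster_membership_by_group(
    result: ClusterResult, cell_records: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster cell counts and within-group percentages of clustered cells."""
    groups_by_cell = dict(zip(cell_records["cell_id"], cell_records["group"]))
    for cells in result.members.values():
        for c in cells:
            if c not in groups_by_cell:
                raise ValidationError(f"clustered cell {c!r} has no group label")
    group_names = sorted(set(groups_by_cell[c] for cells in result.members.values() for c in cells))
    totals = {
        g: sum(
            1
            for cells in result.members.values()
            for c in cells
            if groups_by_cell[c] == g
        )
        for g in group_names
    }
    rows = []
    for cid in sorted(result.members):
        cells = result.members[cid]
        row = {"cluster_id": cid, "label": result.labels.get(cid, ""), "size": len(cells)}
        for g in group_names:
            count = sum(1 for c in cells if groups_by_cell[c] == g)
            row[f"n_{g}"] = count
            row[f"pct_{g}"] = 100.0 * count / totals[g] if totals[g] else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_pipeline(
    feature_matrix: FeatureMatrix,
    protocol: StimulusProtocol,
    r_threshold: float = R_EDGE_THRESHOLD,
    params: MclParams | None = None,
    centroid_r_threshold: float = CENTROID_MERGE_R,
    merge_map: Optional[Mapping[int, int]] = None,
) -> tuple[ClusterResult, nx.Graph, MclResult]:
    """Graph -> MCL -> size filter -> merge -> label, in one call."""
    params = params or MclParams()
    graph = build_correlation_graph(feature_matrix, r_threshold)
    if graph.number_of_nodes() == 0:
        raise ValidationError("correlation graph is empty: no supra-threshold edges")
    raw = mcl(graph, params)
    if not raw.converged:
        log.warning("MCL did not converge within %d iterations", params.max_iter)
    kept, unclustered = filter_small_clusters(raw.clusters, params.min_cluster_size)
    if not kept:
        raise ValidationError("all clusters fell below the minimum size")
    result = merge_clusters(
        kept,
        feature_matrix,
        centroid_r_threshold=centroid_r_threshold,
        unclustered=unclustered,
        merge_map=merge_map,
    )
    return label_clusters(result, protocol), graph, raw
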