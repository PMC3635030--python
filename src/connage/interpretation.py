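"""Consensus features, aggregated weights, node importance, BrainNet export.

After subject-grouped LOOCV, the features selected in *every* fold are the
consensus features.  Each consensus feature's reported weight is the mean
over folds of the linear model's coefficient for it (signed; the magnitude
column is its absolute value).  A node's (ROI's) importance is proportional
to the sum of the weights of its incident consensus features; the
proportionality constant is 1/2:

    node_weight(roi) = | sum of signed incident feature weights | / 2

Only linear models are interpretable this way; RBF models are refused.
Nodes with no incident consensus feature are omitted from the table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import ROIAtlas, feature_to_pair


class InterpretationError(ValueError):
    pass


@dataclass
class FeatureReport:
    """Consensus-feature table: one row per feature with its ROI pair and
    fold-mean signed weight."""

    table: pd.DataFrame  # feature_number, roi_i, roi_j, (names,) weight,
                         # weight_magnitude

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class NodeWeightTable:
    table: pd.DataFrame  # roi_index, (roi_name,) weight

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def consensus_features(per_fold_selections) -> np.ndarray:
    """Sorted feature numbers present in every fold's selection."""
    selections = list(per_fold_selections)
    if not selections:
        raise InterpretationError("no folds given")
    sets = []
    for sel in selections:
        chosen = np.asarray(getattr(sel, "selected", sel), dtype=int)
        if chosen.size == 0:
            raise InterpretationError("a fold selected no features")
        sets.append(set(chosen.tolist()))
    common = set.intersection(*sets)
    return np.array(sorted(common), dtype=int)


def aggregate_feature_weights(folds, consensus, n_rois: int,
                              atlas: ROIAtlas | None = None
                              ) -> FeatureReport:
    """Fold-mean signed weight of each consensus feature.

    ``folds`` are FoldResult records whose ``w`` is the linear weight
    vector over that fold's selected features (fold order); RBF folds have
    ``w`` None and are rejected.
    """
    consensus = np.asarray(consensus, dtype=int)
    rows = {f: [] for f in consensus}
    for fold in folds:
        if fold.w is None:
            raise InterpretationError(
                "fold has no linear weight vector; RBF weights are not "
                "interpretable")
        pos = {f: i for i, f in enumerate(fold.selection.selected)}
        for f in consensus:
            if f not in pos:
                raise InterpretationError(
                    f"feature {f} missing from a fold's selection")
            rows[f].append(fold.w[pos[f]])
    feats = consensus
    weights = np.array([np.mean(rows[f]) for f in feats])
    i1 = np.empty(len(feats), dtype=int)
    j1 = np.empty(len(feats), dtype=int)
    for idx, f in enumerate(feats):
        i1[idx], j1[idx] = feature_to_pair(int(f), n_rois)
    table = pd.DataFrame({
        "feature_number": feats,
        "roi_i": i1,
        "roi_j": j1,
        "weight": weights,
        "weight_magnitude": np.abs(weights),
    })
    if atlas is not None:
        names = atlas.names
        table.insert(2, "roi_i_name", [names[i - 1] for i in i1])
        table.insert(4, "roi_j_name", [names[j - 1] for j in j1])
    return FeatureReport(table)


def node_weights(report: FeatureReport, n_rois: int,
                 atlas: ROIAtlas | None = None) -> NodeWeightTable:
    """Half the absolute signed sum of each ROI's incident feature weights.

    The 1/2 constant makes a node incident to features w_1..w_m carry
    weight |w_1 + ... + w_m| / 2; ROIs with no incident feature are left
    out of the table entirely.
    """
    if report.table.empty:
        raise InterpretationError("feature report is empty")
    sums = np.zeros(n_rois)
    incident = np.zeros(n_rois, dtype=bool)
    for _, row in report.table.iterrows():
        for roi in (int(row["roi_i"]), int(row["roi_j"])):
            sums[roi - 1] += row["weight"]
            incident[roi - 1] = True
    idx = np.flatnonzero(incident) + 1
    table = pd.DataFrame({
        "roi_index": idx,
        "weight": np.abs(sums[idx - 1]) / 2.0,
    })
    if atlas is not None:
        names = atlas.names
        table.insert(1, "roi_name", [names[i - 1] for i in idx])
    return NodeWeightTable(table)


def export_brainnet(nodes: NodeWeightTable, report: FeatureReport,
                    atlas: ROIAtlas, node_path, edge_path) -> None:
    """Write BrainNet Viewer .node and .edge text files.

    .node: one line per atlas ROI, whitespace-delimited
    ``x y z color size label`` with size = node weight (0 for ROIs absent
    from the table).  .edge: full symmetric n_rois x n_rois matrix of
    consensus-feature weight magnitudes, zero elsewhere.
    """
    known = set(atlas.table["index"].tolist())
    for roi in nodes.table["roi_index"]:
        if int(roi) not in known:
            raise InterpretationError(f"ROI {roi} not present in the atlas")
    for col in ("roi_i", "roi_j"):
        for roi in report.table[col]:
            if int(roi) not in known:
                raise InterpretationError(
                    f"ROI {roi} not present in the atlas")

    size = np.zeros(atlas.n_rois)
    for _, row in nodes.table.iterrows():
        size[int(row["roi_index"]) - 1] = row["weight"]
    with open(node_path, "w") as fh:
        for (_, roi), s in zip(atlas.table.iterrows(), size):
            label = str(roi["name"]).replace(" ", "_")
            fh.write(f"{roi['x']:.3f}\t{roi['y']:.3f}\t{roi['z']:.3f}\t"
                     f"1\t{s:.6f}\t{label}\n")

    n = atlas.n_rois
    edge = np.zeros((n, n))
    for _, row in report.table.iterrows():
        i, j = int(row["roi_i"]) - 1, int(row["roi_j"]) - 1
        edge[i, j] = edge[j, i] = row["weight_magnitude"]
    np.savetxt(edge_path, edge, fmt="%.6f", delimiter="\t")


def parse_brainnet(node_path, edge_path):
    """Round-trip reader for the files written by :func:`export_brainnet`."""
    node = pd.read_csv(node_path, sep="\t", header=None,
                       names=["x", "y", "z", "color", "size", "label"])
    edge = np.loadtxt(edge_path, delimiter="\t")
    return node, np.atleast_2d(edge)
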