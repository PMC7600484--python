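"""PPI network construction and isolated-TF classification.

The global protein-protein interaction network is read from a STRING-style
edge list (node, node, combined score), thresholded at medium confidence
(score >= 0.4), and the TF-to-TF subnetwork is induced on a supplied TF
list.  TFs split into a single *large component* — the largest connected
component of the TF-to-TF graph — and *isolated* TFs: TFs that do interact
with other proteins but sit outside that component (tiny TF-TF components
and TFs whose partners are all non-TFs).  TFs with no interactions at all
are excluded from both classes and reported separately.

Class summaries (size, lethal-mutation share, absence in a comparator
species, global degree) and the relative-difference statistic used for
cross-species interaction-count comparisons live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "load_edges",
    "build_graph",
    "classify_tf_components",
    "summarize_classes",
    "relative_difference",
    "TFClassification",
]

logger = logging.getLogger(__name__)


def load_edges(path, min_score: float = 0.4) -> pd.DataFrame:
    """Load a STRING-dialect edge list, thresholded at ``min_score``.

    Accepts space- or tab-separated files with or without the
    ``protein1 protein2 combined_score`` header.  Integer scores on the
    0-1000 STRING scale are auto-rescaled to [0, 1]; the threshold is
    inclusive.  Self-loops are dropped (logged) and reciprocal duplicates
    collapsed.  Malformed lines raise with their line number.
    """
    if not 0 <= min_score <= 1:
        raise ValueError(f"min_score must be in [0, 1], got {min_score}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace("\t", " ").split()
            if lineno == 1 and parts[-1].lower() in ("combined_score", "score"):
                continue
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError as err:
                raise ValueError(f"line {lineno}: bad score {parts[2]!r}") from err
            rows.append((parts[0], parts[1], score))
    if not rows:
        logger.warning("edge file %s is empty", path)
        return pd.DataFrame(columns=["node_a", "node_b", "score"])
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    smax = df["score"].max()
    if smax > 1.0:
        if smax > 1000:
            raise ValueError(f"unknown score scale (max {smax}); expected [0,1] or 0-1000")
        df["score"] = df["score"] / 1000.0
    self_loops = df["node_a"] == df["node_b"]
    if self_loops.any():
        logger.info("dropping %d self-loop(s)", int(self_loops.sum()))
        df = df[~self_loops]
    df = df[df["score"] >= min_score].copy()
    key = np.where(df["node_a"] < df["node_b"],
                   df["node_a"] + "\x00" + df["node_b"],
                   df["node_b"] + "\x00" + df["node_a"])
    df = df.loc[~pd.Index(key).duplicated()]
    a = np.where(df["node_a"] <= df["node_b"], df["node_a"], df["node_b"])
    b = np.where(df["node_a"] <= df["node_b"], df["node_b"], df["node_a"])
    return pd.DataFrame({"node_a": a, "node_b": b,
                         "score": df["score"].values}).reset_index(drop=True)


def build_graph(edges: pd.DataFrame) -> nx.Graph:
    """Undirected graph from a loaded edge table (scores as edge weights)."""
    g = nx.Graph()
    g.add_weighted_edges_from(
        edges[["node_a", "node_b", "score"]].itertuples(index=False, name=None)
    )
    return g


@dataclass
class TFClassification:
    """Partition of a TF list against the interaction network."""

    table: pd.DataFrame  #: per networked TF: class, component id, degrees
    no_interaction: list  #: TFs absent from the network entirely
    n_components: int  #: TF-TF components among networked TFs

    @property
    def large_component(self) -> list:
        t = self.table
        return sorted(t.index[t["tf_class"] == "large_component"])

    @property
    def isolated(self) -> list:
        t = self.table
        return sorted(t.index[t["tf_class"] == "isolated"])


def classify_tf_components(
    edges: pd.DataFrame | nx.Graph,
    tf_list,
    tie_break: str = "error",
) -> TFClassification:
    """Split TFs into the large TF-TF component vs isolated TFs.

    The TF-to-TF subgraph is induced on ``tf_list``; TFs in its single
    largest connected component are ``large_component``; every other TF
    that has at least one interaction of any kind is ``isolated`` (this
    covers small TF-TF components and TFs whose partners are all non-TFs).
    TFs with no interactions at all go in ``no_interaction``.

    If two TF-TF components tie for largest, the default is to raise;
    ``tie_break='lexicographic'`` picks the component containing the
    smallest node label.
    """
    tfs = list(dict.fromkeys(tf_list))
    if not tfs:
        raise ValueError("tf_list is empty")
    g = edges if isinstance(edges, nx.Graph) else build_graph(edges)
    networked = [t for t in tfs if t in g and g.degree(t) > 0]
    no_interaction = sorted(set(tfs) - set(networked))
    if no_interaction:
        logger.info("%d TF(s) with no interactions excluded from both classes",
                    len(no_interaction))
    tt = g.subgraph(networked)
    components = sorted(nx.connected_components(tt),
                        key=lambda c: (-len(c), min(c)))
    if len(components) >= 2 and len(components[0]) == len(components[1]):
        if tie_break == "error":
            raise ValueError(
                "two TF-TF components tie for largest "
                f"(size {len(components[0])}); pass tie_break='lexicographic' "
                "to choose deterministically"
            )
    comp_id = {}
    for i, comp in enumerate(components):
        for node in comp:
            comp_id[node] = i
    large = components[0] if components else set()
    rows = {}
    for t in networked:
        rows[t] = {
            "tf_class": "large_component" if t in large else "isolated",
            "component": comp_id[t],
            "degree_tf": tt.degree(t),
            "degree_global": g.degree(t),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "tf"
    return TFClassification(table=table, no_interaction=no_interaction,
                            n_components=len(components))


def summarize_classes(
    classification: TFClassification,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Class summary table: n, lethal %, absent-in-comparator %, degree.

    ``annotations`` is indexed by gene with optional boolean (or tri-state,
    NA = unknown) columns ``lethal`` and ``absent_in_comparator``; unknowns
    are excluded from both numerator and denominator (counts logged).
    Percentages are reported to one decimal; degree is mean ± sd (sample sd)
    of the global-network degree.  Empty classes get a row with n = 0 and
    blank statistics.
    """
    t = classification.table
    rows = {}
    for cls in ("large_component", "isolated"):
        sub = t[t["tf_class"] == cls]
        row: dict = {"n": len(sub)}
        if len(sub) == 0:
            rows[cls] = row
            continue
        for col, out in (("lethal", "lethal"), ("absent_in_comparator", "absent")):
            if annotations is None or col not in annotations.columns:
                continue
            flags = annotations.reindex(sub.index)[col]
            known = flags.notna()
            if (~known).any():
                logger.info("%s: %d TF(s) with unknown %r excluded",
                            cls, int((~known).sum()), col)
            k = flags[known].astype(bool)
            row[f"{out}_n"] = int(k.sum())
            row[f"{out}_pct"] = (
                round(100.0 * k.sum() / len(k), 1) if len(k) else float("nan")
            )
        deg = sub["degree_global"]
        row["degree_mean"] = round(float(deg.mean()), 1)
        row["degree_sd"] = round(float(deg.std(ddof=1)), 1) if len(deg) > 1 else 0.0
        rows[cls] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "tf_class"
    return out


def relative_difference(count_a, count_b) -> tuple[np.ndarray, float, float]:
    """Relative difference 100·|a − b| / mean(a, b), elementwise.

    Vectorized over paired per-gene counts in two species; pairs with both
    counts zero are undefined and excluded (logged).  Returns the per-pair
    percentages plus their mean and sample standard deviation.  The measure
    is bounded by 200% (attained when one count is zero).
    """
    a = np.asarray(count_a, dtype=float)
    b = np.asarray(count_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have matching shapes")
    both_zero = (a == 0) & (b == 0)
    if both_zero.any():
        logger.info("excluding %d pair(s) with both counts zero", int(both_zero.sum()))
    a, b = a[~both_zero], b[~both_zero]
    if a.size == 0:
        raise ValueError("no pairs with a nonzero count")
    rel = 100.0 * np.abs(a - b) / ((a + b) / 2.0)
    sd = float(np.std(rel, ddof=1)) if rel.size > 1 else 0.0
    return rel, float(np.mean(rel)), sd
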