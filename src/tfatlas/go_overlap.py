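"""Cross-species overlap of per-GO-term TF sets.

For every GO term annotated in two species, the TF sets A and B (mapped
through a shared ortholog namespace) are compared by the intersection
proportion relative to the average set size,

    q = |A ∩ B| / ((|A| + |B|) / 2),

which is algebraically the Sørensen–Dice coefficient 2|A∩B| / (|A|+|B|).
The trend of q against set size is summarized by local polynomial
(degree-2, tricube-weighted) regression of q on log average size — the
classic loess smoother — revealing whether terms regulated by many TFs are
regulated by the same TFs in both species.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "load_term_sets",
    "overlap_proportion",
    "overlap_table",
    "loess",
    "smooth_overlap",
    "count_comparison",
]

logger = logging.getLogger(__name__)


def load_term_sets(
    annot_a: pd.DataFrame,
    annot_b: pd.DataFrame,
    ortholog_map: dict | None = None,
) -> dict[str, tuple[set, set]]:
    """Per-term TF sets for two species from long annotation tables.

    Tables need columns ``term`` and ``tf``.  ``ortholog_map`` translates
    species-B TF identifiers into species-A (shared) identifiers; TFs
    without a mapping keep their own identifier, so they count toward set
    sizes but can never intersect (conservative; the unmapped count is
    logged).  Terms annotated in only one species get an empty set for the
    other.
    """
    sets_a: dict[str, set] = {}
    sets_b: dict[str, set] = {}
    for term, tf in annot_a[["term", "tf"]].itertuples(index=False):
        sets_a.setdefault(term, set()).add(tf)
    unmapped = 0
    for term, tf in annot_b[["term", "tf"]].itertuples(index=False):
        if ortholog_map is not None:
            if tf in ortholog_map:
                tf = ortholog_map[tf]
            else:
                unmapped += 1
        sets_b.setdefault(term, set()).add(tf)
    if ortholog_map is not None and unmapped:
        logger.info("%d species-B annotations had no ortholog mapping", unmapped)
    return {
        t: (sets_a.get(t, set()), sets_b.get(t, set()))
        for t in sorted(set(sets_a) | set(sets_b))
    }


def overlap_proportion(set_a, set_b) -> tuple[float, float]:
    """Average set size and intersection proportion q for one term.

    Returns ``(mean_size, q)`` with q = |A∩B| / mean size.  Raises if both
    sets are empty (the term carries no information).
    """
    a, b = set(set_a), set(set_b)
    mean_size = (len(a) + len(b)) / 2.0
    if mean_size == 0:
        raise ValueError("both TF sets are empty")
    return mean_size, len(a & b) / mean_size


def overlap_table(term_sets: dict[str, tuple[set, set]]) -> pd.DataFrame:
    """Per-term (size_a, size_b, mean_size, q) table; empty terms skipped."""
    rows = []
    skipped = 0
    for term, (a, b) in term_sets.items():
        if not a and not b:
            skipped += 1
            continue
        mean_size, q = overlap_proportion(a, b)
        rows.append((term, len(a), len(b), mean_size, q))
    if skipped:
        logger.info("skipped %d term(s) with empty sets in both species", skipped)
    return pd.DataFrame(
        rows, columns=["term", "size_a", "size_b", "mean_size", "q"]
    ).set_index("term")


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray | None = None,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each evaluation point the ``ceil(span * n)`` nearest observations
    are fit by weighted least squares of the given degree, with tricube
    weights on the scaled distances.  Deterministic and invariant to the
    ordering of the input points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d arrays")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = len(x)
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise ValueError(
            f"window of {k} point(s) cannot support a degree-{degree} local "
            "fit; increase the span"
        )
    if x_eval is None:
        x_eval = x
    x_eval = np.asarray(x_eval, dtype=float)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    out = np.empty(len(x_eval))
    for j, x0 in enumerate(x_eval):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:  # all window points coincide with x0
            out[j] = ys[idx].mean()
            continue
        w = (1.0 - np.minimum(d[idx] / dmax, 1.0) ** 3) ** 3
        # guard against an all-zero weight window (dmax point only)
        w = np.maximum(w, 1e-12)
        V = np.vander(xs[idx] - x0, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], ys[idx] * sw, rcond=None)
        out[j] = coef[0]
    return out


def smooth_overlap(
    table: pd.DataFrame,
    span: float = 0.75,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Smooth q against log mean set size with degree-2 loess.

    ``table`` comes from :func:`overlap_table` (needs ``mean_size`` and
    ``q``).  Returns a grid of (mean_size, q_hat) with predictions clipped
    to [0, 1].  Requires at least 10 terms.
    """
    if len(table) < 10:
        raise ValueError(f"need >= 10 terms to smooth, got {len(table)}")
    x = np.log(table["mean_size"].to_numpy(dtype=float))
    y = table["q"].to_numpy(dtype=float)
    grid = np.linspace(x.min(), x.max(), n_grid)
    q_hat = np.clip(loess(x, y, x_eval=grid, span=span, degree=2), 0.0, 1.0)
    return pd.DataFrame({"mean_size": np.exp(grid), "q_hat": q_hat})


def count_comparison(term_sets: dict[str, tuple[set, set]]) -> pd.DataFrame:
    """Per-term set-size scatter table (|A| vs |B|) with the identity line.

    The ``on_diagonal`` column marks terms with equal set sizes; the
    identity-line reference is just size_a == size_b.
    """
    rows = [(t, len(a), len(b), len(a) == len(b)) for t, (a, b) in term_sets.items()]
    return pd.DataFrame(
        rows, columns=["term", "size_a", "size_b", "on_diagonal"]
    ).set_index("term")
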