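"""TF census from DNA-binding-domain hit tables.

A transcription factor is identified by a profile-HMM hit of a DNA-binding
domain (DBD) on one of its protein products.  This module turns per-protein
domain hits into per-species TF catalogs: hits are filtered on E-value,
collapsed to one record per (gene, family) keeping the best-scoring isoform,
counted per family, standardized so each family averages 1 across species,
and screened for cross-family correlation of repertoire size.

A gene carrying DBDs of several families is counted once in each family;
such shared-DBD genes are the main source of strong cross-family count
correlations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "HIT_COLUMNS",
    "read_hits",
    "filter_hits",
    "dedup_isoforms",
    "build_catalog",
    "count_families",
    "standardize_counts",
    "family_correlations",
]

logger = logging.getLogger(__name__)

#: canonical columns of the portable 6-column hit table
HIT_COLUMNS = ["protein_id", "gene_name", "species", "family", "e_value", "bit_score"]

#: column layout of HMMER's per-domain tabular output (--domtblout)
_DOMTBL_FIELDS = 23


def read_hits(path, species: str | None = None) -> pd.DataFrame:
    """Read a domain-hit table (6-column TSV or hmmscan --domtblout).

    The dialect is sniffed from the first non-blank line: lines starting
    with ``#`` and whitespace-separated records with >= 23 fields are
    treated as hmmscan per-domain output (query = protein, target = family
    model, full-sequence E-value and score).  For domtblout input the gene
    name is taken as the protein id stripped of a trailing isoform suffix
    (``.1``, ``-201`` etc.) and ``species`` must be supplied.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if first.startswith("#") or len(first.split()) >= _DOMTBL_FIELDS:
        if species is None:
            raise ValueError("species must be given for hmmscan domtblout input")
        return _read_domtblout(path, species)
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return df[HIT_COLUMNS].copy()


def _read_domtblout(path, species: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            # domtblout: target name, accession, tlen, query name, accession,
            # qlen, full E-value, full score, ...
            family, protein = f[0], f[3]
            gene = protein.rsplit(".", 1)[0] if "." in protein else protein
            rows.append((protein, gene, species, family, float(f[6]), float(f[7])))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def filter_hits(hits: pd.DataFrame, e_threshold: float = 1e-4) -> pd.DataFrame:
    """Keep hits with ``e_value <= e_threshold`` (inclusive), preserving order.

    The boundary is inclusive, matching the usual reporting-threshold
    semantics of profile-HMM search tools.
    """
    if e_threshold <= 0:
        raise ValueError(f"e_threshold must be > 0, got {e_threshold}")
    return hits.loc[hits["e_value"] <= e_threshold].copy()


def dedup_isoforms(hits: pd.DataFrame) -> pd.DataFrame:
    """Collapse isoforms: one hit per (gene, species, family), best score kept.

    Ties on ``bit_score`` are broken by the lexicographically smallest
    ``protein_id``.  Hits with a missing gene name are kept, keyed by their
    protein id (each such protein is treated as its own gene); their number
    is logged.
    """
    if hits.empty:
        return hits.copy()
    work = hits.copy()
    missing = work["gene_name"].isna() | (work["gene_name"] == "")
    if missing.any():
        logger.warning("%d hits lack a gene name; keyed by protein_id", missing.sum())
        work.loc[missing, "gene_name"] = work.loc[missing, "protein_id"]
    work = work.sort_values(
        ["gene_name", "species", "family", "bit_score", "protein_id"],
        ascending=[True, True, True, False, True],
        kind="stable",
    )
    out = work.drop_duplicates(["gene_name", "species", "family"], keep="first")
    return out.sort_index()


def build_catalog(hits: pd.DataFrame) -> dict[str, dict[str, set[str]]]:
    """Catalog ``species -> gene -> set of families`` from deduplicated hits."""
    catalog: dict[str, dict[str, set[str]]] = {}
    for sp, gene, fam in hits[["species", "gene_name", "family"]].itertuples(index=False):
        catalog.setdefault(sp, {}).setdefault(gene, set()).add(fam)
    return catalog


def count_families(catalog: dict[str, dict[str, set[str]]]) -> pd.DataFrame:
    """Species x family table of TF gene counts.

    A gene appears once per family it carries, so the table total equals the
    number of distinct (gene, family) pairs.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    rows = []
    for sp, genes in catalog.items():
        for gene, fams in genes.items():
            for fam in fams:
                rows.append((sp, fam))
    df = pd.DataFrame(rows, columns=["species", "family"])
    mat = df.value_counts().unstack(fill_value=0)
    return mat.sort_index().sort_index(axis=1)


def standardize_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each family column by its cross-species mean (column means -> 1).

    All-zero families carry no signal and are dropped with a warning.
    """
    means = matrix.mean(axis=0)
    zero = means[means == 0].index
    if len(zero):
        logger.warning("dropping %d all-zero family column(s): %s",
                       len(zero), list(zero))
    kept = matrix.drop(columns=zero)
    return kept / kept.mean(axis=0)


def family_correlations(
    matrix: pd.DataFrame, r_threshold: float = 0.5
) -> tuple[pd.DataFrame, float]:
    """Pearson correlation of family sizes across species.

    Returns the family x family correlation table and the percentage of
    unordered family pairs with ``r < r_threshold`` (one decimal).  Pairs
    involving a zero-variance family are undefined and excluded from both
    numerator and denominator; correlation is computed on the raw counts
    (per-column standardization leaves Pearson r unchanged).
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 species rows for correlations")
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    var = matrix.var(axis=0)
    degenerate = var[var == 0].index
    if len(degenerate):
        logger.warning("%d zero-variance family column(s) excluded from pair "
                       "fraction: %s", len(degenerate), list(degenerate))
    corr = matrix.corr(method="pearson")
    usable = [f for f in matrix.columns if f not in set(degenerate)]
    sub = corr.loc[usable, usable].to_numpy()
    iu = np.triu_indices(len(usable), k=1)
    pair_r = sub[iu]
    if len(pair_r) == 0:
        return corr, float("nan")
    frac = 100.0 * float(np.mean(pair_r < r_threshold))
    return corr, round(frac, 1)
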