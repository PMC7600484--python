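"""Negative-binomial expression contrasts over TF-interaction gene types.

Orthologous genes are assigned to five types by the TFs they interact with
in the two species' networks: (1) no TF partners — the reference, (2) only
orthologous TF partners, (3) both species-A- and species-B-specific TF
partners, (4) A-specific partners only, (5) B-specific partners only (for
the human/mouse comparison: orth_TF, spec_TF_HM, spec_TF_H, spec_TF_M).

Per organ and species, expression (TPM, rounded to counts) is modelled as
negative binomial with log E[expression | type = C_k] = alpha + beta_k:
beta_k is the log mean expression of type k relative to the reference, and
the dispersion is estimated by maximum likelihood (NB2 parameterization,
variance mu + alpha_disp * mu^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GENE_TYPES",
    "assign_gene_types",
    "tpm_normalize",
    "fit_nb_contrast",
    "contrast_profile",
    "NBFit",
]

logger = logging.getLogger(__name__)

#: the five TF-interaction gene types; the first is the regression reference
GENE_TYPES = ["no_TF_interaction", "orth_TF", "spec_TF_HM", "spec_TF_H", "spec_TF_M"]


def assign_gene_types(
    partners_a: dict,
    partners_b: dict,
    orthologous_tfs,
    genes=None,
) -> pd.Series:
    """Assign each gene a TF-interaction type from its partner profiles.

    ``partners_a`` / ``partners_b`` map gene -> set of interacting TFs in
    the two species' networks (TF identifiers in a shared ortholog
    namespace); ``orthologous_tfs`` is the set of TFs present in both
    species.  A partner not in that set is species-specific.

    Precedence for mixed profiles: both-species-specific partners win over
    single-species-specific, which wins over all-orthologous.  A gene absent
    from both partner maps is the reference type (logged).
    """
    orth = set(orthologous_tfs)
    if genes is None:
        genes = sorted(set(partners_a) | set(partners_b))
    out = {}
    n_absent = 0
    for g in genes:
        pa = set(partners_a.get(g, ()))
        pb = set(partners_b.get(g, ()))
        if g not in partners_a and g not in partners_b:
            n_absent += 1
        spec_a = pa - orth
        spec_b = pb - orth
        if not pa and not pb:
            out[g] = "no_TF_interaction"
        elif spec_a and spec_b:
            out[g] = "spec_TF_HM"
        elif spec_a:
            out[g] = "spec_TF_H"
        elif spec_b:
            out[g] = "spec_TF_M"
        else:
            out[g] = "orth_TF"
    if n_absent:
        logger.info("%d gene(s) absent from both networks -> reference type",
                    n_absent)
    return pd.Series(out, name="gene_type")


def tpm_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Rescale each column (sample) to sum to 1e6 (TPM convention)."""
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("cannot TPM-normalize a sample with non-positive total")
    return values * (1e6 / sums)


@dataclass
class NBFit:
    """One NB regression: intercept, per-type contrasts, dispersion."""

    organ: str
    species: str
    alpha: float  #: intercept = log mean of the reference type
    alpha_se: float
    beta: pd.Series  #: log mean relative to reference, per non-reference type
    beta_se: pd.Series
    theta: float  #: NB size parameter (1 / NB2 alpha)
    llf: float
    n: int


def fit_nb_contrast(
    expr: pd.DataFrame,
    organ: str,
    species: str,
    nb_input: str = "rounded",
) -> NBFit:
    """Fit the NB regression of expression on gene type for one stratum.

    ``expr`` is long-format with columns gene, gene_type, organ, species,
    tpm.  TPM values are rounded to the nearest integer for the count
    likelihood (``nb_input='rounded'``, the default) or must already be
    integers (``nb_input='raw-counts'``).  The model has the gene type as
    its only covariate with ``no_TF_interaction`` as reference; dispersion
    is estimated jointly by maximum likelihood.
    """
    sub = expr[(expr["organ"] == organ) & (expr["species"] == species)]
    if sub.empty:
        raise ValueError(f"no rows for organ={organ!r}, species={species!r}")
    types_present = [t for t in GENE_TYPES if t in set(sub["gene_type"])]
    unknown = set(sub["gene_type"]) - set(GENE_TYPES)
    if unknown:
        raise ValueError(f"unknown gene types: {sorted(unknown)}")
    if (sub["gene_type"].value_counts() < 2).any():
        raise ValueError("every gene type present needs >= 2 genes")
    if "no_TF_interaction" not in types_present:
        raise ValueError("reference type 'no_TF_interaction' absent from data")
    y = sub["tpm"].to_numpy(dtype=float)
    if nb_input == "rounded":
        y = np.rint(y)
    elif nb_input == "raw-counts":
        if not np.allclose(y, np.rint(y)):
            raise ValueError("raw-counts input contains non-integer values")
    else:
        raise ValueError("nb_input must be 'rounded' or 'raw-counts'")
    dummies = pd.get_dummies(
        pd.Categorical(sub["gene_type"], categories=types_present),
        drop_first=True, dtype=float,
    )
    X = sm.add_constant(dummies.to_numpy())
    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    res = model.fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):  # pragma: no cover
        logger.warning("NB fit did not fully converge for %s/%s", organ, species)
    names = ["alpha"] + list(dummies.columns) + ["nb2_alpha"]
    params = pd.Series(res.params, index=names)
    ses = pd.Series(res.bse, index=names)
    contrast_names = list(dummies.columns)
    return NBFit(
        organ=organ,
        species=species,
        alpha=float(params["alpha"]),
        alpha_se=float(ses["alpha"]),
        beta=params[contrast_names].rename("beta"),
        beta_se=ses[contrast_names].rename("se"),
        theta=float(1.0 / params["nb2_alpha"]),
        llf=float(res.llf),
        n=len(y),
    )


def contrast_profile(fits: list[NBFit], include_reference: bool = False) -> pd.DataFrame:
    """Tidy (organ, species, gene_type, beta, se) table from a set of fits.

    With ``include_reference`` the reference type is emitted with beta = 0
    and se = NaN, which is convenient for bar rendering.
    """
    rows = []
    for fit in fits:
        if include_reference:
            rows.append((fit.organ, fit.species, "no_TF_interaction", 0.0, float("nan")))
        for t in fit.beta.index:
            rows.append((fit.organ, fit.species, t, float(fit.beta[t]),
                         float(fit.beta_se[t])))
    return pd.DataFrame(rows, columns=["organ", "species", "gene_type", "beta", "se"])
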