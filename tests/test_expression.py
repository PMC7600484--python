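"""Gene-type assignment and NB regression of expression contrasts."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from tfatlas import expression as E
from tfatlas import simulate as S

ORTH = {"TF_O1", "TF_O2"}


class TestAssignGeneTypes:
    def assign(self, pa, pb, genes=None):
        return E.assign_gene_types(pa, pb, ORTH, genes=genes)

    def test_orthologous_partners_only(self):
        out = self.assign({"g": {"TF_O1"}}, {"g": {"TF_O1", "TF_O2"}})
        assert out["g"] == "orth_TF"

    def test_both_species_specific(self):
        out = self.assign({"g": {"TF_H1"}}, {"g": {"TF_M1"}})
        assert out["g"] == "spec_TF_HM"

    def test_no_partners_is_reference(self):
        out = self.assign({"g": set()}, {"g": set()})
        assert out["g"] == "no_TF_interaction"

    def test_single_species_specific(self):
        out = self.assign({"g": {"TF_H1", "TF_O1"}}, {"g": {"TF_O1"}})
        assert out["g"] == "spec_TF_H"
        out = self.assign({"g": {"TF_O1"}}, {"g": {"TF_M9"}})
        assert out["g"] == "spec_TF_M"

    def test_precedence_mixed_profile(self):
        # specific partners in both species win over single-species-specific
        out = self.assign({"g": {"TF_H1", "TF_O1"}}, {"g": {"TF_M1", "TF_O2"}})
        assert out["g"] == "spec_TF_HM"

    def test_gene_absent_from_networks_logged_as_reference(self, caplog):
        with caplog.at_level("INFO"):
            out = self.assign({}, {}, genes=["lonely"])
        assert out["lonely"] == "no_TF_interaction"
        assert "absent" in caplog.text

    def test_types_partition_the_gene_set(self):
        rng = np.random.default_rng(0)
        tfs = [f"TF_O{i}" for i in range(5)] + [f"TF_X{i}" for i in range(5)]
        pa = {f"g{i}": set(rng.choice(tfs, rng.integers(0, 4), replace=False))
              for i in range(50)}
        pb = {f"g{i}": set(rng.choice(tfs, rng.integers(0, 4), replace=False))
              for i in range(50)}
        out = E.assign_gene_types(pa, pb, {t for t in tfs if "O" in t})
        assert set(out.index) == set(pa)
        assert set(out.unique()) <= set(E.GENE_TYPES)


def test_tpm_normalization_sums_to_million():
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(rng.gamma(2.0, 50.0, size=(300, 4)))
    out = E.tpm_normalize(mat)
    assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-6)
    with pytest.raises(ValueError):
        E.tpm_normalize(pd.DataFrame({"a": [0.0, 0.0]}))


class TestFitNB:
    def test_intercept_only_recovers_log_mean(self):
        rng = np.random.default_rng(2)
        mu, theta = 80.0, 3.0
        y = rng.negative_binomial(theta, theta / (theta + mu), size=4000)
        expr = pd.DataFrame({"gene": range(len(y)),
                             "gene_type": "no_TF_interaction",
                             "organ": "heart", "species": "human",
                             "tpm": y.astype(float)})
        fit = E.fit_nb_contrast(expr, "heart", "human")
        assert fit.alpha == pytest.approx(np.log(y.mean()), abs=1e-3)
        assert len(fit.beta) == 0

    def test_null_betas_within_two_se(self):
        cfg = S.SimConfig(seed=3, beta_k=(0.0, 0.0, 0.0, 0.0),
                          n_genes_per_type=800, organs=("liver",))
        expr, _ = S.simulate_expression(cfg)
        fit = E.fit_nb_contrast(expr, "liver", "mouse")
        assert (fit.beta.abs() < 3 * fit.beta_se).all()

    def test_recovery_on_simulated_contrasts(self):
        cfg = S.SimConfig(seed=4, n_genes_per_type=1000, organs=("heart",))
        expr, truth = S.simulate_expression(cfg)
        fit = E.fit_nb_contrast(expr, "heart", "human")
        for t, b in truth["beta"].items():
            assert fit.beta[t] == pytest.approx(b, abs=0.15)
        assert fit.theta == pytest.approx(cfg.theta, rel=0.2)

    def test_reference_relabel_shifts_betas_by_constant(self):
        cfg = S.SimConfig(seed=5, n_genes_per_type=600, organs=("heart",))
        expr, _ = S.simulate_expression(cfg)
        fit = E.fit_nb_contrast(expr, "heart", "human")
        # swap the reference with orth_TF by renaming the two types
        swapped = expr.replace({"gene_type": {"no_TF_interaction": "orth_TF",
                                              "orth_TF": "no_TF_interaction"}})
        fit2 = E.fit_nb_contrast(swapped, "heart", "human")
        shift = fit.beta["orth_TF"]
        assert fit2.alpha == pytest.approx(fit.alpha + shift, abs=5e-3)
        assert fit2.beta["orth_TF"] == pytest.approx(-shift, abs=5e-3)
        for t in ("spec_TF_HM", "spec_TF_H", "spec_TF_M"):
            assert fit2.beta[t] == pytest.approx(fit.beta[t] - shift, abs=5e-3)

    def test_bias_decreases_with_sample_size(self):
        biases = []
        for n in (200, 2000):
            errs = []
            for seed in range(3):
                cfg = S.SimConfig(seed=100 + seed, n_genes_per_type=n,
                                  organs=("heart",))
                expr, truth = S.simulate_expression(cfg)
                fit = E.fit_nb_contrast(expr, "heart", "mouse")
                errs.append(np.mean([abs(fit.beta[t] - b)
                                     for t, b in truth["beta"].items()]))
            biases.append(np.mean(errs))
        assert biases[1] < biases[0]

    def test_missing_reference_rejected(self):
        expr = pd.DataFrame({"gene": range(4), "gene_type": "orth_TF",
                             "organ": "heart", "species": "human",
                             "tpm": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="reference"):
            E.fit_nb_contrast(expr, "heart", "human")

    def test_raw_counts_input_validated(self):
        expr = pd.DataFrame({"gene": range(4),
                             "gene_type": ["no_TF_interaction"] * 4,
                             "organ": "h", "species": "s",
                             "tpm": [1.5, 2, 3, 4]})
        with pytest.raises(ValueError, match="non-integer"):
            E.fit_nb_contrast(expr, "h", "s", nb_input="raw-counts")

    def test_glm_nb_oracle_agreement(self, tmp_path):
        """Independent cross-check against R's glm.nb on the same data."""
        pytest.importorskip("shutil")
        import shutil
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        cfg = S.SimConfig(seed=6, n_genes_per_type=300, organs=("heart",))
        expr, _ = S.simulate_expression(cfg)
        sub = expr[(expr.organ == "heart") & (expr.species == "human")].copy()
        sub["tpm"] = np.rint(sub["tpm"])
        csv = tmp_path / "expr.csv"
        sub.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(MASS))\n"
            f"d <- read.csv('{csv}')\n"
            "d$gene_type <- relevel(factor(d$gene_type), 'no_TF_interaction')\n"
            "m <- glm.nb(tpm ~ gene_type, data = d)\n"
            "co <- coef(m)\n"
            "cat(sprintf('%.6f\\n', co))\n"
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        r_coefs = [float(x) for x in res.stdout.split()]
        fit = E.fit_nb_contrast(expr, "heart", "human")
        mine = [fit.alpha] + [fit.beta[t] for t in
                              ["orth_TF", "spec_TF_H", "spec_TF_HM", "spec_TF_M"]]
        # R orders levels alphabetically after the reference
        assert np.allclose(sorted(mine[1:]), sorted(r_coefs[1:]), atol=2e-3)
        assert mine[0] == pytest.approx(r_coefs[0], abs=2e-3)


def test_contrast_profile_shape_and_round_trip():
    fits = []
    for organ in ("a", "b", "c", "d", "e"):
        for species in ("human", "mouse"):
            beta = pd.Series({"orth_TF": 0.1, "spec_TF_HM": 0.2,
                              "spec_TF_H": 0.3, "spec_TF_M": 0.4})
            fits.append(E.NBFit(organ=organ, species=species, alpha=1.0,
                                alpha_se=0.1, beta=beta, beta_se=beta * 0,
                                theta=2.0, llf=0.0, n=10))
    out = E.contrast_profile(fits)
    assert len(out) == 40  # 5 organs x 2 species x 4 non-reference types
    withref = E.contrast_profile(fits, include_reference=True)
    assert len(withref) == 50
    ref = withref[withref.gene_type == "no_TF_interaction"]
    assert (ref.beta == 0).all()
    # round trip: the rendered rows equal the fit coefficients
    row = out[(out.organ == "a") & (out.species == "human")
              & (out.gene_type == "spec_TF_M")]
    assert row.beta.iloc[0] == 0.4
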