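import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from proteodpe.containers import SampleTable
from proteodpe.dpe import (
    ModeratedLinearModel,
    adjust_bh,
    fit_moderated,
    overlap_analysis,
    severity_model,
    subset_bonferroni,
)
from .conftest import make_matrix


def _fixture(p=20, n=12, seed=8):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "age": rng.normal(size=n),
            "group": rng.permutation([0.0] * (n // 2) + [1.0] * (n - n // 2)),
        }
    )
    Y = rng.normal(size=(p, n)) * rng.uniform(0.5, 2.0, size=(p, 1))
    Y[: p // 4] += 1.0 * X["group"].to_numpy()[None, :]
    return X, Y


class TestModeratedLimits:
    def test_d0_zero_matches_independent_per_protein_ols(self):
        """With the prior off, every moderated t must equal the t of a
        separate OLS fit per protein (statsmodels as the independent
        route), to 1e-10."""
        import statsmodels.api as sm

        X, Y = _fixture()
        model = ModeratedLinearModel(prior_df=0).fit(X, Y)
        _, t_mod, p_mod = model.t_table(["group"])["group"]
        for g in range(Y.shape[0]):
            fit = sm.OLS(Y[g], X.to_numpy()).fit()
            assert abs(t_mod[g] - fit.tvalues[2]) < 1e-10
            assert abs(p_mod[g] - fit.pvalues[2]) < 1e-10

    def test_d0_infinite_matches_pooled_variance_t(self):
        X, Y = _fixture()
        model = ModeratedLinearModel(prior_df=np.inf).fit(X, Y)
        coef, t_mod, _ = model.t_table(["group"])["group"]
        s0 = model.params_.s0_sq
        cjj = np.linalg.inv(X.to_numpy().T @ X.to_numpy())[2, 2]
        expected = coef / np.sqrt(s0 * cjj)
        assert np.allclose(t_mod, expected, atol=1e-12)

    def test_shrinkage_monotonicity(self):
        X, Y = _fixture(p=100)
        model = ModeratedLinearModel().fit(X, Y)
        s2 = model.params_.sigma_sq
        s0 = model.params_.s0_sq
        post = model.posterior_var_
        lo = np.minimum(s2, s0) - 1e-12
        hi = np.maximum(s2, s0) + 1e-12
        assert np.all((post >= lo) & (post <= hi))

    def test_matches_reference_ebayes_implementation(self, tmp_path):
        """Cross-check hyperparameters and moderated statistics against the
        Bioconductor reference implementation on a tiny fixture."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; reference cross-check cannot run")
        X, Y = _fixture(p=60, n=16, seed=42)
        model = ModeratedLinearModel().fit(X, Y)
        _, t_mod, p_mod = model.t_table(["group"])["group"]
        np.savetxt(tmp_path / "Y.tsv", Y, delimiter="\t")
        X.to_csv(tmp_path / "X.tsv", sep="\t", index=False)
        (tmp_path / "cmp.R").write_text(
            'suppressMessages(library(limma))\n'
            'Y <- as.matrix(read.delim("Y.tsv", header=FALSE))\n'
            'X <- as.matrix(read.delim("X.tsv"))\n'
            'fit <- eBayes(lmFit(Y, X))\n'
            'write.table(data.frame(t=fit$t[,"group"], p=fit$p.value[,"group"],'
            ' d0=fit$df.prior, s0=fit$s2.prior), "out.tsv", sep="\\t",'
            ' row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", "cmp.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        assert model.params_.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert model.params_.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-6)
        assert np.allclose(t_mod, ref["t"].to_numpy(), atol=1e-8)
        assert np.allclose(p_mod, ref["p"].to_numpy(), atol=1e-8)

    def test_too_few_samples_rejected(self):
        X, Y = _fixture(n=4)
        with pytest.raises(ValueError, match="samples"):
            ModeratedLinearModel().fit(X, Y)


class TestAdjustBh:
    def test_hand_stepped_example(self):
        """p = (0.01, 0.02, 0.03, 0.04), m = 4: p*m/i = (0.04, 0.04, 0.04,
        0.04); the cumulative minimum from the top leaves all at 0.04."""
        adj = adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert adjust_bh(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_constant_vector_unchanged(self):
        assert np.allclose(adjust_bh(np.full(7, 0.2)), 0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.1, np.nan]))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        ours = adjust_bh(p)
        _, theirs, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, theirs, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                 max_size=60)
    )
    def test_properties(self, p):
        p = np.asarray(p)
        adj = adjust_bh(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSeverityModel:
    def _severity_cohort(self, slope=0.1, seed=0, permute=False):
        rng = np.random.default_rng(seed)
        n, p = 60, 600
        sev_true = rng.integers(0, 7, size=n).astype(float)
        batch = np.array([f"pool{j % 3 + 1}" for j in range(n)])
        Y = rng.normal(0, 0.3, size=(p, n))
        Y[:30] += slope * sev_true[None, :]
        # the metadata stage is permuted AFTER the signal is planted, so a
        # permuted analysis sees severity unrelated to expression
        sev = rng.permutation(sev_true) if permute else sev_true
        # a mild batch factor so the PC substitution path engages
        offsets = rng.normal(0, 0.4, size=(p, 3))
        for b in range(3):
            Y[:, batch == f"pool{b + 1}"] += offsets[:, [b]]
        m = make_matrix(Y)
        samples = SampleTable(
            pd.DataFrame(
                {
                    "diagnosis": "disease_1",
                    "age": rng.normal(75, 8, n),
                    "sex": rng.choice(["F", "M"], n),
                    "batch": batch,
                    "severity": sev,
                },
                index=pd.Index([f"S{j}" for j in range(n)], name="sample_id"),
            )
        )
        return m, samples

    def test_recovers_planted_slopes(self):
        m, samples = self._severity_cohort(slope=0.1, seed=1)
        table, info = severity_model(m, samples)
        assert info["batch_pc"] is not None
        got = table.set_index("accession")["logFC"].iloc[:30]
        assert np.abs(got - 0.1).mean() < 0.03
        assert np.abs(got - 0.1).max() < 0.12

    def test_permuted_severity_yields_no_discoveries(self):
        m, samples = self._severity_cohort(slope=0.1, seed=2, permute=True)
        table, _ = severity_model(m, samples)
        assert int((table["adj_p_value"] < 0.05).sum()) <= 2

    def test_no_batch_structure_falls_back_to_indicators(self, caplog):
        rng = np.random.default_rng(3)
        n, p = 40, 300
        Y = rng.normal(size=(p, n))
        m = make_matrix(Y)
        samples = SampleTable(
            pd.DataFrame(
                {
                    "diagnosis": "disease_1",
                    "age": rng.normal(75, 8, n),
                    "sex": rng.choice(["F", "M"], n),
                    "batch": [f"pool{j % 2 + 1}" for j in range(n)],
                    "severity": rng.integers(0, 7, n).astype(float),
                },
                index=pd.Index([f"S{j}" for j in range(n)], name="sample_id"),
            )
        )
        table, info = severity_model(m, samples)
        assert info["batch_pc"] is None
        assert "indicator" in caplog.text


class TestSubsetBonferroni:
    def _table(self, pvals, symbols):
        return pd.DataFrame(
            {
                "accession": [f"P{i}" for i in range(len(pvals))],
                "gene_symbol": symbols,
                "contrast": "diagnosis[disease_1]",
                "logFC": 0.1,
                "t": 1.0,
                "p_value": pvals,
                "adj_p_value": pvals,
            }
        )

    def test_six_selected_scales_p_by_six(self):
        symbols = [f"MRP{i}" for i in range(6)] + ["OTHER"]
        table = self._table([0.008, 0.01, 0.02, 0.03, 0.04, 0.049, 0.001],
                            symbols)
        out = subset_bonferroni(table, [f"MRP{i}" for i in range(6)])
        assert len(out) == 6
        by_acc = out.set_index("accession")["bonferroni_p"]
        assert by_acc["P0"] == pytest.approx(0.048)
        assert by_acc["P4"] == pytest.approx(0.24)

    def test_single_selection_unchanged(self):
        table = self._table([0.02, 0.8], ["A", "B"])
        out = subset_bonferroni(table, ["A", "B"])
        assert out["bonferroni_p"].iloc[0] == pytest.approx(0.02)

    def test_empty_selection_warns(self, caplog):
        table = self._table([0.5, 0.8], ["A", "B"])
        out = subset_bonferroni(table, ["A"])
        assert out.empty
        assert "nominal" in caplog.text


class TestOverlap:
    def _table(self, sig, universe, flip=None):
        rows = []
        for i, acc in enumerate(universe):
            p = 0.001 if acc in sig else 0.5
            lfc = 0.3 + 0.05 * i if acc not in (flip or ()) else -(0.3 + 0.05 * i)
            rows.append(
                {"accession": acc, "gene_symbol": acc, "contrast": "c",
                 "logFC": lfc, "t": 1.0, "p_value": p, "adj_p_value": p}
            )
        return pd.DataFrame(rows)

    def test_identical_tables_fully_concordant(self):
        uni = [f"P{i}" for i in range(10)]
        t = self._table({"P1", "P2"}, uni)
        report = overlap_analysis({"a": t, "b": t.copy()})
        assert report.fdr_intersections[("a", "b")] == {"P1", "P2"}
        assert report.logfc_correlation.loc["a", "b"] == pytest.approx(1.0)
        assert report.discordant[("a", "b")] == []

    def test_three_way_set_arithmetic(self):
        uni = [f"p{i}" for i in range(1, 6)]
        tables = {
            "A": self._table({"p1", "p2", "p3"}, uni),
            "B": self._table({"p2", "p3", "p4"}, uni),
            "C": self._table({"p3"}, uni),
        }
        report = overlap_analysis(tables)
        assert report.fdr_intersections[("A", "B", "C")] == {"p3"}
        assert report.fdr_intersections[("A", "B")] == {"p2", "p3"}

    def test_sign_flip_lands_in_discordant_list(self):
        uni = [f"P{i}" for i in range(6)]
        a = self._table({"P0", "P1"}, uni)
        b = self._table({"P0", "P1"}, uni, flip={"P1"})
        report = overlap_analysis({"a": a, "b": b})
        assert "P1" in report.discordant[("a", "b")]

    def test_fdr_nested_in_nominal(self, small_imputed, small_cells):
        imputed, samples, _, _, _ = small_imputed
        from proteodpe.design import DesignSpec, build_design_matrix

        X = build_design_matrix(
            DesignSpec(covariates=("age", "sex", "batch", "neurons")),
            samples, small_cells,
        )
        contrasts = [c for c in X.columns if c.startswith("diagnosis[")]
        table, _ = fit_moderated(imputed, X, contrasts)
        by = {c: table[table["contrast"] == c] for c in contrasts}
        report = overlap_analysis(by)
        for combo, fdr_set in report.fdr_intersections.items():
            assert fdr_set <= report.nominal_intersections[combo]

    def test_disjoint_universes_rejected(self):
        a = self._table({"P0"}, ["P0", "P1"])
        b = self._table({"Q0"}, ["Q0", "Q1"])
        with pytest.raises(ValueError, match="disjoint"):
            overlap_analysis({"a": a, "b": b})
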