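"""2^-ddCt fold changes: hand-checked values, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest

from regscreen import CtTable, delta_delta_ct, fold_change_report
from regscreen.expression_quant import CtTableError, significance_stars
from regscreen.synthetic_data import CtSimSpec, simulate_ct


def _table(rows):
    return CtTable(pd.DataFrame(rows, columns=["strain", "gene", "replicate", "Ct"]))


def _uniform_table(ct_map, replicates=3, jitter=None):
    """ct_map: {(strain, gene): Ct}; optional per-replicate jitter array."""
    rows = []
    for (strain, gene), ct in ct_map.items():
        for rep in range(1, replicates + 1):
            eps = 0.0 if jitter is None else jitter[rep - 1]
            rows.append((strain, gene, rep, ct + eps))
    return _table(rows)


class TestDeltaDeltaCt:
    def test_hand_calculated_fold_of_four(self):
        # gene 2 cycles earlier in test with constant reference: ddCt = -2, fold 4
        table = _uniform_table(
            {("WT", "g"): 20.0, ("WT", "hrdB"): 15.0, ("M", "g"): 18.0, ("M", "hrdB"): 15.0}
        )
        fc = delta_delta_ct(table, "g", test="M")
        assert fc.ddct_mean == pytest.approx(-2.0)
        assert fc.fold == pytest.approx(4.0)
        control = delta_delta_ct(table, "g", test="WT")
        assert control.fold == pytest.approx(1.0)

    def test_identity_when_test_equals_control(self):
        table = _uniform_table(
            {("WT", "g"): 21.3, ("WT", "hrdB"): 16.1, ("M", "g"): 21.3, ("M", "hrdB"): 16.1},
            jitter=[0.1, -0.2, 0.05],
        )
        fc = delta_delta_ct(table, "g", test="M")
        assert fc.ddct_mean == pytest.approx(0.0)
        assert fc.fold == pytest.approx(1.0)

    def test_reciprocal_folds_multiply_to_one(self):
        table = _uniform_table(
            {("WT", "g"): 20.0, ("WT", "hrdB"): 15.0, ("M", "g"): 17.5, ("M", "hrdB"): 15.2}
        )
        f1 = delta_delta_ct(table, "g", test="M", control="WT").fold
        f2 = delta_delta_ct(table, "g", test="WT", control="M").fold
        assert f1 * f2 == pytest.approx(1.0)

    def test_strainwide_ct_shift_leaves_fold_unchanged(self):
        base = {("WT", "g"): 20.0, ("WT", "hrdB"): 15.0, ("M", "g"): 18.0, ("M", "hrdB"): 15.0}
        shifted = {k: v + (3.7 if k[0] == "M" else 0.0) for k, v in base.items()}
        f1 = delta_delta_ct(_uniform_table(base), "g", test="M").fold
        f2 = delta_delta_ct(_uniform_table(shifted), "g", test="M").fold
        assert f1 == pytest.approx(f2)

    def test_fold_range_straddles_fold(self):
        rng = np.random.default_rng(3)
        table = _uniform_table(
            {("WT", "g"): 20.0, ("WT", "hrdB"): 15.0, ("M", "g"): 18.0, ("M", "hrdB"): 15.0},
            jitter=rng.normal(0, 0.2, 3),
        )
        fc = delta_delta_ct(table, "g", test="M")
        lo, hi = fc.fold_sd_range
        assert lo < fc.fold < hi

    def test_missing_reference_raises(self):
        table = _uniform_table({("WT", "g"): 20.0, ("M", "g"): 18.0, ("WT", "hrdB"): 15.0})
        with pytest.raises(CtTableError, match="hrdB"):
            delta_delta_ct(table, "g", test="M")

    def test_single_replicate_raises(self):
        table = _uniform_table(
            {("WT", "g"): 20.0, ("WT", "hrdB"): 15.0, ("M", "g"): 18.0, ("M", "hrdB"): 15.0},
            replicates=1,
        )
        with pytest.raises(CtTableError, match="replicate"):
            delta_delta_ct(table, "g", test="M")

    def test_reference_as_target_warns_and_returns_one(self):
        table = _uniform_table({("WT", "hrdB"): 15.0, ("M", "hrdB"): 15.0})
        with pytest.warns(UserWarning, match="reference"):
            fc = delta_delta_ct(table, "hrdB", test="M")
        assert fc.fold == pytest.approx(1.0)


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,stars", [(0.2, ""), (0.04, "*"), (0.004, "**"), (0.0004, "***")]
    )
    def test_mapping(self, p, stars):
        assert significance_stars(p) == stars


class TestFoldChangeReport:
    def test_one_row_per_gene_strain(self):
        spec = CtSimSpec(
            genes=["lmbA", "lmbW"],
            strains=["WT", "M"],
            true_folds={("M", "lmbA"): 3.7, ("M", "lmbW"): 13.0},
            noise_sd=0.05,
            seed=5,
        )
        report = fold_change_report(simulate_ct(spec), ["lmbA", "lmbW"], ["M"])
        assert len(report) == 2
        assert set(report.columns) >= {"gene", "fold", "p_value", "significance"}

    def test_missing_gene_skipped_with_warning(self):
        spec = CtSimSpec(genes=["lmbA"], strains=["WT", "M"], noise_sd=0.1, seed=5)
        table = simulate_ct(spec)
        with pytest.warns(UserWarning, match="lmbK"):
            report = fold_change_report(table, ["lmbA", "lmbK"], ["M"])
        assert list(report["gene"]) == ["lmbA"]


class TestRecovery:
    def test_noiseless_inversion_exact(self):
        spec = CtSimSpec(
            genes=["g"], strains=["WT", "M"], true_folds={("M", "g"): 4.0},
            noise_sd=0.0, seed=0,
        )
        fc = delta_delta_ct(simulate_ct(spec), "g", test="M")
        assert fc.fold == pytest.approx(4.0)

    def test_median_fold_recovery_over_grid(self):
        # true folds spanning repression to strong induction, two noise levels
        for true_fold in (0.1, 1.0, 3.7, 13.0):
            for sd in (0.1, 0.3):
                estimates = []
                for seed in range(150):
                    spec = CtSimSpec(
                        genes=["g"], strains=["WT", "M"],
                        true_folds={("M", "g"): true_fold},
                        noise_sd=sd, seed=seed,
                    )
                    estimates.append(delta_delta_ct(simulate_ct(spec), "g", test="M").fold)
                med = float(np.median(estimates))
                assert abs(med - true_fold) / true_fold < 0.10, (true_fold, sd, med)
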