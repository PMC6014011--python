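import numpy as np
import pandas as pd
import pytest

from sfpevol.quant import (
    NormalizationError,
    classify_variation,
    coefficient_of_variation,
    filter_technical_cv,
    normalize_by_standards,
    nsaf,
    protein_mean_ria,
)


def make_quant(rows):
    return pd.DataFrame(
        rows,
        columns=["species", "individual", "run", "peptide", "protein",
                 "is_standard", "ria"],
    )


class TestNormalization:
    def test_two_run_factors_hand_computed(self):
        """Standard geometric means 6 and 24 give factors 0.5 and 2.0
        against the reference sqrt(6 * 24) = 12."""
        df = make_quant([
            ("h", "i1", "r1", "s1", "STD", True, 4.0),
            ("h", "i1", "r1", "s2", "STD", True, 9.0),
            ("h", "i1", "r1", "p1", "P1", False, 10.0),
            ("h", "i1", "r2", "s1", "STD", True, 16.0),
            ("h", "i1", "r2", "s2", "STD", True, 36.0),
            ("h", "i1", "r2", "p1", "P1", False, 10.0),
        ])
        out, factors, excluded = normalize_by_standards(df)
        f = factors.set_index("run")["factor"]
        assert f["r1"] == pytest.approx(0.5)
        assert f["r2"] == pytest.approx(2.0)
        assert factors["reference"].iloc[0] == pytest.approx(12.0)
        v = out.set_index(["run", "peptide"])["ria"]
        assert v[("r1", "p1")] == pytest.approx(20.0)
        assert v[("r2", "p1")] == pytest.approx(5.0)
        assert excluded == []

    def test_single_run_self_reference_identity(self):
        df = make_quant([
            ("h", "i1", "r1", "s1", "STD", True, 4.0),
            ("h", "i1", "r1", "s2", "STD", True, 9.0),
            ("h", "i1", "r1", "p1", "P1", False, 7.0),
        ])
        out, factors, _ = normalize_by_standards(df)
        assert factors["factor"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out["peptide"] == "p1", "ria"].iloc[0] == pytest.approx(7.0)

    def test_scaled_run_normalizes_to_unscaled_values(self):
        base = [
            ("h", "i1", "r1", "s1", "STD", True, 5.0),
            ("h", "i1", "r1", "p1", "P1", False, 50.0),
            ("h", "i1", "r1", "p2", "P1", False, 2.0),
        ]
        scaled = [(sp, ind, "r2", pep, prot, std, ria * 1e3)
                  for sp, ind, _, pep, prot, std, ria in base]
        out, _, _ = normalize_by_standards(make_quant(base + scaled))
        v = out.set_index(["run", "peptide"])["ria"]
        for pep in ("p1", "p2"):
            assert v[("r2", pep)] == pytest.approx(v[("r1", pep)], rel=1e-12)

    def test_run_without_standards_excluded_and_reported(self):
        df = make_quant([
            ("h", "i1", "r1", "s1", "STD", True, 5.0),
            ("h", "i1", "r1", "p1", "P1", False, 50.0),
            ("h", "i2", "r1", "p1", "P1", False, 50.0),  # no standards
        ])
        out, factors, excluded = normalize_by_standards(df)
        assert ("h", "i2", "r1") in excluded
        assert not ((out["species"] == "h") & (out["individual"] == "i2")).any()

    def test_no_standards_anywhere_is_hard_error(self):
        df = make_quant([("h", "i1", "r1", "p1", "P1", False, 5.0)])
        with pytest.raises(NormalizationError):
            normalize_by_standards(df)

    @pytest.mark.parametrize("c", [1e-3, 1.0, 1e3])
    def test_scale_invariance_with_fixed_reference(self, c):
        """Multiplying one run's raw values (standards included) by c leaves
        its normalized non-standard values untouched to 1e-12 once the
        reference is pinned; each run's standards then equal the reference."""
        rng = np.random.default_rng(0)
        rows = []
        for run in ("r1", "r2", "r3"):
            for k in range(3):
                rows.append(("h", "i1", run, f"s{k}", "STD", True,
                             float(rng.lognormal(2, 0.4))))
            for k in range(5):
                rows.append(("h", "i1", run, f"p{k}", "P1", False,
                             float(rng.lognormal(5, 1.0))))
        df = make_quant(rows)
        out0, factors0, _ = normalize_by_standards(df)
        ref = float(factors0["reference"].iloc[0])
        perturbed = df.copy()
        sel = perturbed["run"] == "r2"
        perturbed.loc[sel, "ria"] *= c
        out1, factors1, _ = normalize_by_standards(perturbed, reference=ref)
        a = out0.set_index(["run", "peptide"])["ria"].sort_index()
        b = out1.set_index(["run", "peptide"])["ria"].sort_index()
        assert np.allclose(a, b, rtol=1e-12)
        # per-run standard geometric mean equals the global reference
        stds = out1[out1["is_standard"]]
        for _, g in stds.groupby("run"):
            geo = np.exp(np.mean(np.log(g["ria"])))
            assert geo == pytest.approx(ref, rel=1e-12)


class TestCV:
    def test_constant_input(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0

    def test_hand_values(self):
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(50.0)
        assert coefficient_of_variation([10, 20]) == pytest.approx(
            100 * (10 / np.sqrt(2)) / 15
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([5.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestTechnicalFilter:
    def test_reasons_and_retention(self):
        df = make_quant([
            ("h", "i1", "r1", "solo", "P1", False, 10.0),
            ("h", "i1", "r1", "noisy", "P1", False, 10.0),
            ("h", "i1", "r2", "noisy", "P1", False, 20.0),   # CV ~ 47% > 25
            ("h", "i1", "r1", "good", "P1", False, 100.0),
            ("h", "i1", "r2", "good", "P1", False, 100.0),
            ("h", "i1", "r3", "good", "P1", False, 100.0),
        ])
        t = filter_technical_cv(df).set_index("peptide")
        assert not t.loc["solo", "included"]
        assert t.loc["solo", "reason"] == "single_replicate"
        assert not t.loc["noisy", "included"]
        assert t.loc["noisy", "reason"] == "cv_exceeds"
        assert t.loc["good", "included"]
        assert t.loc["good", "mean_ria"] == 100.0
        assert t.loc["good", "cv_pct"] == 0.0

    def test_boundary_cv_exactly_25_retained(self):
        # mean 100, sd 25 -> CV exactly 25%: "CV <= 25%" keeps it
        vals = [100 - 25 / np.sqrt(2), 100 + 25 / np.sqrt(2)]
        df = make_quant([
            ("h", "i1", "r1", "edge", "P1", False, vals[0]),
            ("h", "i1", "r2", "edge", "P1", False, vals[1]),
        ])
        t = filter_technical_cv(df).set_index("peptide")
        assert t.loc["edge", "cv_pct"] == pytest.approx(25.0)
        assert t.loc["edge", "included"]

    def test_ten_percent_cv_passes_filter(self):
        """At 10% technical CV, >= 99% of 1000 peptides with 3 replicates
        clear the 25% cutoff."""
        rng = np.random.default_rng(42)
        sigma = np.sqrt(np.log1p(0.01))
        rows = []
        for k in range(1000):
            for rep in range(3):
                rows.append(("h", "i1", f"r{rep}", f"pep{k:04d}", "P1", False,
                             1000 * rng.lognormal(0.0, sigma)))
        t = filter_technical_cv(make_quant(rows))
        assert t["included"].mean() >= 0.99


class TestClassification:
    @pytest.mark.parametrize("cv,label", [
        (21.0, "conserved"),      # QSOX1-like low variability
        (80.0, "high"),           # rhesus PSAP-like high variability
        (50.0, "intermediate"),
        (25.0, "intermediate"),   # boundary handling is fixed
        (75.0, "intermediate"),
        (0.0, "conserved"),
    ])
    def test_labels(self, cv, label):
        assert classify_variation(cv) == label

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            classify_variation(-1.0)


class TestProteinRollup:
    def _table(self, peptide_means, protein="P1"):
        rows = []
        for k, m in enumerate(peptide_means):
            rows.append(("h", "i1", f"pep{k}", protein, False, m, 5.0, 3,
                         True, ""))
        return pd.DataFrame(rows, columns=[
            "species", "individual", "peptide", "protein", "is_standard",
            "mean_ria", "cv_pct", "n_replicates", "included", "reason"])

    def test_arithmetic_mean(self):
        table, omitted = protein_mean_ria(self._table([2.0, 4.0, 6.0]))
        assert table["mean_ria"].iloc[0] == pytest.approx(4.0)
        assert table["n_peptides"].iloc[0] == 3

    def test_two_peptides_omitted(self):
        table, omitted = protein_mean_ria(self._table([2.0, 4.0]))
        assert table.empty
        assert omitted["reason"].iloc[0] == "fewer_than_min_peptides"

    def test_idempotent_on_identical_peptides(self):
        table, _ = protein_mean_ria(self._table([7.0, 7.0, 7.0]))
        assert table["mean_ria"].iloc[0] == pytest.approx(7.0)


class TestNSAF:
    def test_single_protein(self):
        assert nsaf([17], [100])["nsaf"].iloc[0] == pytest.approx(1.0)

    def test_equal_length_normalized_counts(self):
        out = nsaf([10, 30], [100, 300])
        assert np.allclose(out["nsaf"], [0.5, 0.5])

    def test_hand_computation(self):
        out = nsaf([10, 10], [100, 300])
        assert np.allclose(out["nsaf"], [0.75, 0.25])

    def test_sums_to_one(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 500, 40)
        counts[0] = 3
        lengths = rng.integers(50, 2000, 40)
        assert nsaf(counts, lengths)["nsaf"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            nsaf([0, 0], [100, 100])
        with pytest.raises(ValueError):
            nsaf([1, 2], [100, 0])
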