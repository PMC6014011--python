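import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from sfpevol.compare import (
    match_identical_peptides,
    mating_system_scan,
    peptide_concordance,
    species_pair_scan,
    wilcoxon_rank_sum,
)


def qc_table(species, rows):
    """rows: (peptide, protein, individual, mean_ria)"""
    return pd.DataFrame(
        [(species, ind, pep, prot, False, v, 5.0, 3, True, "")
         for pep, prot, ind, v in rows],
        columns=["species", "individual", "peptide", "protein", "is_standard",
                 "mean_ria", "cv_pct", "n_replicates", "included", "reason"],
    )


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


class TestMatching:
    def test_shared_and_specific(self):
        tables = {
            "h": qc_table("h", [("AAK", "P1", "i1", 1.0), ("CCK", "P2", "i1", 2.0)]),
            "m": qc_table("m", [("AAK", "P1", "i1", 3.0), ("DDK", "P3", "i1", 4.0)]),
        }
        m = match_identical_peptides(tables)
        assert m.shared_peptides == ["AAK"]
        assert m.specific_counts == {"h": 1, "m": 1}

    def test_single_residue_difference_not_matched(self):
        tables = {
            "h": qc_table("h", [("PEPTIDEK", "P1", "i1", 1.0)]),
            "m": qc_table("m", [("PEPTIDER", "P1", "i1", 1.0)]),
        }
        m = match_identical_peptides(tables)
        assert m.shared_peptides == []

    def test_disjoint_sets_empty_shared(self):
        tables = {
            "h": qc_table("h", [("AAK", "P1", "i1", 1.0)]),
            "m": qc_table("m", [("BBK", "P2", "i1", 1.0)]),
        }
        assert match_identical_peptides(tables).shared_peptides == []

    def test_absent_species_raises(self):
        tables = {"h": qc_table("h", [("AAK", "P1", "i1", 1.0)])}
        with pytest.raises(KeyError):
            match_identical_peptides(tables, ["h", "zz"])


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def enumerate_rank_sum_p(x, y, alternative):
    """Independent oracle: full enumeration of rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n)]
    sums = np.array(sums)
    if alternative == "less":
        return np.mean(sums <= obs)
    if alternative == "greater":
        return np.mean(sums >= obs)
    return min(1.0, 2 * min(np.mean(sums <= obs), np.mean(sums >= obs)))


class TestWilcoxon:
    def test_separated_samples_exact_one_twentieth(self):
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "less")
        assert r.method == "exact"
        assert r.p == pytest.approx(1 / 20)

    def test_identical_multisets_two_sided_p_one(self):
        r = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], "two_sided")
        assert r.method == "asymptotic"  # ties force the midrank approximation
        assert r.p == 1.0

    @given(st.integers(0, 10_000))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        m = int(rng.integers(1, 11 - n)) if n < 10 else 1
        vals = rng.permutation(np.arange(20, dtype=float))[: n + m]
        x, y = vals[:n], vals[n:]
        for alt in ("less", "greater", "two_sided"):
            got = wilcoxon_rank_sum(x, y, alt)
            assert got.method == "exact"
            assert got.p == pytest.approx(enumerate_rank_sum_p(x, y, alt))

    def test_exact_close_to_asymptotic_at_n8(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.permutation(np.arange(100, dtype=float))[:16]
            x, y = vals[:8], vals[8:]
            exact = wilcoxon_rank_sum(x, y, "two_sided").p
            mw = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic")
            mg = sps.mannwhitneyu(x, y, alternative="greater",
                                  method="asymptotic")
            approx = min(1.0, 2 * min(mw.pvalue, mg.pvalue))
            assert abs(exact - approx) < 0.02

    @given(st.integers(0, 5_000))
    def test_two_sided_at_least_one_sided(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(2, 8))
        y = rng.normal(size=rng.integers(2, 8))
        two = wilcoxon_rank_sum(x, y, "two_sided").p
        less = wilcoxon_rank_sum(x, y, "less").p
        greater = wilcoxon_rank_sum(x, y, "greater").p
        assert two >= min(less, greater) - 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def matched_from(tables, labels):
    return match_identical_peptides(tables), labels


class TestMatingScan:
    def _tables(self, shift=0.0, n=8, seed=0):
        rng = np.random.default_rng(seed)
        rows_h = [("AAK", "P1", f"i{k}", float(rng.lognormal(3, 0.3)))
                  for k in range(n)]
        rows_m = [("AAK", "P1", f"i{k}", float(rng.lognormal(3 + shift, 0.3)))
                  for k in range(n)]
        return {"h": qc_table("h", rows_h), "m": qc_table("m", rows_m)}

    def test_responsive_peptide_detected_with_direction(self):
        """A 2-fold multi shift with 8 vs 8 individuals is detected as
        multi_higher with power > 0.8 (Monte Carlo over 50 replicates)."""
        labels = {"h": "uni", "m": "multi"}
        hits = 0
        for seed in range(50):
            m = match_identical_peptides(self._tables(np.log(2), seed=seed))
            res, _ = mating_system_scan(m, labels)
            row = res.iloc[0]
            hits += bool(row["significant"]) and row["direction"] == "multi_higher"
        assert hits / 50 > 0.8

    def test_alpha_zero_flags_nothing(self):
        labels = {"h": "uni", "m": "multi"}
        m = match_identical_peptides(self._tables(np.log(4)))
        res, summary = mating_system_scan(m, labels, alpha=0.0)
        assert summary["n_significant"] == 0
        assert (res["direction"] == "none").all()

    def test_scan_invariant_to_row_order(self):
        labels = {"h": "uni", "m": "multi"}
        tables = self._tables(np.log(2))
        m1 = match_identical_peptides(tables)
        shuffled = {k: v.sample(frac=1, random_state=1).reset_index(drop=True)
                    for k, v in tables.items()}
        m2 = match_identical_peptides(shuffled)
        r1, _ = mating_system_scan(m1, labels)
        r2, _ = mating_system_scan(m2, labels)
        pd.testing.assert_frame_equal(r1, r2)

    def test_missing_group_raises(self):
        m = match_identical_peptides(self._tables())
        with pytest.raises(ValueError):
            mating_system_scan(m, {"h": "uni", "m": "uni"})


class TestSpeciesPairScan:
    def test_identical_tables_not_significant(self):
        rows = [("AAK", "P1", f"i{k}", float(v))
                for k, v in enumerate([1, 2, 3, 4, 5, 6])]
        a = qc_table("h", rows)
        b = qc_table("m", rows)
        res = species_pair_scan(a, b)
        assert not res["significant"].any()

    def test_elevated_first_species_direction(self):
        rng = np.random.default_rng(1)
        rows_a = [("AAK", "P1", f"i{k}", float(rng.lognormal(4, 0.2)))
                  for k in range(8)]
        rows_b = [("AAK", "P1", f"i{k}", float(rng.lognormal(2, 0.2)))
                  for k in range(8)]
        res = species_pair_scan(qc_table("h", rows_a), qc_table("m", rows_b))
        assert res["significant"].iloc[0]
        assert res["direction"].iloc[0] == "a_higher"

    def test_single_species_peptide_skipped(self):
        a = qc_table("h", [("AAK", "P1", "i1", 1.0), ("ONLYK", "P2", "i1", 2.0)])
        b = qc_table("m", [("AAK", "P1", "i1", 1.0)])
        res = species_pair_scan(a, b).set_index("peptide")
        assert res.loc["ONLYK", "skipped"] == "absent_in_one_species"


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


class TestConcordance:
    def test_identical_profiles(self):
        m = pd.DataFrame([[1, 2, 3, 4], [1, 2, 3, 4]],
                         index=["pepA", "pepB"]).astype(float)
        r2, mean_r2 = peptide_concordance(m, log10=False)
        assert r2.loc["pepA", "pepB"] == pytest.approx(1.0)
        assert mean_r2 == pytest.approx(1.0)

    def test_log_negation_still_r2_one(self):
        base = np.array([1.0, 2.0, 5.0, 10.0])
        m = pd.DataFrame([base, 100.0 / base], index=["up", "down"])
        r2, _ = peptide_concordance(m, log10=True)
        assert r2.loc["up", "down"] == pytest.approx(1.0)

    def test_hand_pearson_value(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 7.0])
        want = float(np.corrcoef(x, y)[0, 1] ** 2)
        m = pd.DataFrame([x, y], index=["a", "b"])
        r2, _ = peptide_concordance(m, log10=False)
        assert r2.loc["a", "b"] == pytest.approx(want)
        assert want == pytest.approx(0.9868, abs=1e-4)

    def test_constant_profile_reported_missing(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["c", "v"])
        r2, mean_r2 = peptide_concordance(m, log10=False)
        assert np.isnan(r2.loc["c", "v"])

    def test_too_few_shared_samples_omitted(self):
        m = pd.DataFrame([[1.0, 2.0, np.nan], [1.0, np.nan, 3.0]],
                         index=["a", "b"])
        r2, _ = peptide_concordance(m, log10=False)
        assert np.isnan(r2.loc["a", "b"])

    def test_needs_two_peptides(self):
        with pytest.raises(ValueError):
            peptide_concordance(pd.DataFrame([[1.0, 2.0]]), log10=False)
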