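"""Cross-species peptide matching and rank-sum abundance comparisons.

Only peptides with exactly identical sequences are compared across species,
because modifications and ionization differences make RIA values of
non-identical peptides incomparable; a single residue difference excludes a
peptide.  Group differences use the Wilcoxon rank-sum (Mann-Whitney) test:
two-sided for significance, one-sided pairs for direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchedPeptideTable",
    "match_identical_peptides",
    "WilcoxonResult",
    "wilcoxon_rank_sum",
    "mating_system_scan",
    "species_pair_scan",
    "peptide_concordance",
]

EXACT_LIMIT = 16  # exact null enumeration when n + m <= this and no ties


@dataclass
class MatchedPeptideTable:
    """Identical peptides matched across species.

    ``values`` is long format: peptide, protein, species, individual,
    mean RIA.  ``shared_peptides`` are present in every requested species;
    ``specific_counts`` counts peptides seen in exactly one species.
    """

    values: pd.DataFrame
    species: list[str]
    shared_peptides: list[str]
    specific_counts: dict

    @property
    def peptides(self) -> list[str]:
        return sorted(self.values["peptide"].unique())


def match_identical_peptides(tables: dict, species_subset=None) -> MatchedPeptideTable:
    """Match peptides by exact sequence across per-species quant tables.

    ``tables`` maps species name to a normalized quant table (the output of
    :func:`sfpevol.quant.filter_technical_cv`); only included, non-standard
    rows participate.  Raises ``KeyError`` for a requested species with no
    table.
    """
    if species_subset is None:
        species_subset = sorted(tables)
    if len(species_subset) < 2:
        raise ValueError("need at least two species to match")
    missing = [s for s in species_subset if s not in tables]
    if missing:
        raise KeyError(f"species absent from input: {missing}")
    frames = []
    for sp in species_subset:
        t = tables[sp]
        t = t[t["included"] & ~t["is_standard"].astype(bool)]
        frames.append(t[["peptide", "protein", "species", "individual", "mean_ria"]])
    values = pd.concat(frames, ignore_index=True)
    by_pep = values.groupby("peptide")["species"].nunique()
    shared = sorted(by_pep[by_pep == len(species_subset)].index)
    specific = by_pep[by_pep == 1].index
    counts = (
        values[values["peptide"].isin(specific)]
        .groupby("species")["peptide"].nunique().to_dict()
    )
    return MatchedPeptideTable(values, list(species_subset), shared, counts)


@dataclass
class WilcoxonResult:
    statistic: float  # Mann-Whitney U of the first sample
    p: float
    method: str  # "exact" | "asymptotic"
    low_power: bool  # min(n, m) < 3


def _has_ties(x, y) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> WilcoxonResult:
    """Wilcoxon rank-sum test of two independent samples.

    Exact null enumeration when ``n + m <= 16`` with no ties, otherwise a
    midrank normal approximation with continuity correction.  The two-sided
    p is ``min(1, 2 * min(one-sided p's))``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    exact = (x.size + y.size) <= EXACT_LIMIT and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"

    def one_sided(alt):
        res = stats.mannwhitneyu(x, y, alternative=alt, method=method)
        return float(res.statistic), float(res.pvalue)

    u_less, p_less = one_sided("less")
    _, p_greater = one_sided("greater")
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return WilcoxonResult(u_less, p, method, min(x.size, y.size) < 3)


def _group_scan(per_peptide, name_a, name_b, alpha, bh):
    rows = []
    for pep, protein, a, b, skip_reason in per_peptide:
        if skip_reason:
            rows.append({
                "peptide": pep, "protein": protein, f"n_{name_a}": len(a),
                f"n_{name_b}": len(b), "p_two_sided": np.nan, "p_greater": np.nan,
                "p_less": np.nan, "direction": "none", "significant": False,
                "skipped": skip_reason,
            })
            continue
        two = wilcoxon_rank_sum(a, b, "two_sided")
        greater = wilcoxon_rank_sum(a, b, "greater").p
        less = wilcoxon_rank_sum(a, b, "less").p
        rows.append({
            "peptide": pep, "protein": protein, f"n_{name_a}": len(a),
            f"n_{name_b}": len(b),
            f"median_{name_a}": float(np.median(a)),
            f"median_{name_b}": float(np.median(b)),
            "p_two_sided": two.p, "p_greater": greater, "p_less": less,
            "low_power": two.low_power, "skipped": "",
        })
    results = pd.DataFrame(rows)
    if results.empty:
        results["significant"] = []
        return results
    tested = results["skipped"] == ""
    if bh and tested.any():
        from statsmodels.stats.multitest import multipletests

        adj = np.full(len(results), np.nan)
        rej = np.zeros(len(results), bool)
        rej_t, adj_t, _, _ = multipletests(
            results.loc[tested, "p_two_sided"], alpha=alpha, method="fdr_bh"
        )
        adj[tested.to_numpy()] = adj_t
        rej[tested.to_numpy()] = rej_t
        results["p_adjusted"] = adj
        results["significant"] = rej
    else:
        results["significant"] = tested & (results["p_two_sided"] < alpha)
    direction = np.where(
        ~results["significant"], "none",
        np.where(results["p_greater"] < results["p_less"],
                 f"{name_a}_higher", f"{name_b}_higher"),
    )
    results["direction"] = direction
    return results


def mating_system_scan(matched: MatchedPeptideTable, labels: dict,
                       alpha: float = 0.05, bh: bool = False):
    """Scan matched peptides for abundance differences between uni-male and
    multi-male mating systems.

    Individuals are pooled within mating group across species.  Returns
    ``(results, summary)`` with per-peptide two-sided/one-sided p-values,
    a direction call at ``alpha``, and summary counts.
    """
    for sp in matched.species:
        if sp not in labels:
            raise KeyError(f"no mating label for species {sp!r}")
    groups = {sp: labels[sp] for sp in matched.species}
    if len(set(groups.values())) < 2:
        raise ValueError("both mating groups must be represented")
    per_peptide = []
    for (pep, protein), g in matched.values.groupby(["peptide", "protein"], sort=True):
        uni = g.loc[[groups[s] == "uni" for s in g["species"]], "mean_ria"].to_numpy()
        multi = g.loc[[groups[s] == "multi" for s in g["species"]], "mean_ria"].to_numpy()
        skip = "" if (uni.size and multi.size) else "group_missing"
        per_peptide.append((pep, protein, uni, multi, skip))
    results = _group_scan(per_peptide, "uni", "multi", alpha, bh)
    tested = results[results["skipped"] == ""] if not results.empty else results
    summary = {
        "n_peptides": int(len(results)),
        "n_tested": int(len(tested)),
        "n_significant": int(results["significant"].sum()) if len(results) else 0,
        "n_uni_higher": int((results.get("direction", pd.Series(dtype=str)) == "uni_higher").sum()),
        "n_multi_higher": int((results.get("direction", pd.Series(dtype=str)) == "multi_higher").sum()),
        "alpha": alpha,
    }
    return results, summary


def species_pair_scan(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      alpha: float = 0.05, bh: bool = False):
    """Per-peptide rank-sum comparison between two species' quant tables.

    Peptides observed in only one species are skipped with a reason.
    Direction ``a_higher`` means the first species has larger abundances.
    """
    def prep(t):
        t = t[t["included"] & ~t["is_standard"].astype(bool)]
        return t
    a, b = prep(table_a), prep(table_b)
    prot = pd.concat([a, b]).groupby("peptide")["protein"].first()
    per_peptide = []
    for pep in sorted(set(a["peptide"]).union(b["peptide"])):
        va = a.loc[a["peptide"] == pep, "mean_ria"].to_numpy()
        vb = b.loc[b["peptide"] == pep, "mean_ria"].to_numpy()
        skip = "" if (va.size and vb.size) else "absent_in_one_species"
        per_peptide.append((pep, prot[pep], va, vb, skip))
    return _group_scan(per_peptide, "a", "b", alpha, bh)


def peptide_concordance(values: pd.DataFrame, log10: bool = True,
                        min_shared: int = 3):
    """Pairwise squared Pearson correlation between peptides of one protein.

    ``values`` is a peptide x sample matrix (DataFrame) of abundances; NaN
    marks unobserved samples.  Correlations use log10 abundances by default
    and require ``min_shared`` complete samples per pair; pairs with fewer,
    or with a constant profile, are reported as missing.  Returns
    ``(r2_matrix, mean_r2)``.
    """
    if values.shape[0] < 2:
        raise ValueError("need at least two peptides")
    M = values.to_numpy(float)
    if log10:
        with np.errstate(divide="ignore", invalid="ignore"):
            M = np.where(M > 0, np.log10(M), np.nan)
    n = M.shape[0]
    R2 = np.full((n, n), np.nan)
    np.fill_diagonal(R2, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(M[i]) & np.isfinite(M[j])
            if ok.sum() < min_shared:
                continue
            xi, xj = M[i, ok], M[j, ok]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue  # constant vector: correlation undefined
            r = np.corrcoef(xi, xj)[0, 1]
            R2[i, j] = R2[j, i] = r * r
    r2 = pd.DataFrame(R2, index=values.index, columns=values.index)
    off = R2[np.triu_indices(n, 1)]
    mean_r2 = float(np.nanmean(off)) if np.isfinite(off).any() else np.nan
    return r2, mean_r2
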