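"""Normalization, QC and rollup of peptide relative-isotope-abundance values.

The workflow mirrors clinical label-free practice: per-run scale removal via
the geometric mean of spiked internal standards, a technical-replicate
CV <= 25% inclusion filter, arithmetic rollup to proteins with at least
three retained peptides, a conserved/intermediate/high variability
classification, and NSAF spectral-count abundances.

Geometric means are computed in log space; missing or non-positive RIA
values are treated as missing, never as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationError",
    "normalize_by_standards",
    "coefficient_of_variation",
    "filter_technical_cv",
    "classify_variation",
    "protein_mean_ria",
    "nsaf",
]

RUN_KEY = ["species", "individual", "run"]


class NormalizationError(ValueError):
    pass


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def normalize_by_standards(dataset: pd.DataFrame, reference: float | None = None):
    """Remove run-level scale using the spiked internal standards.

    Each MS run (a ``species, individual, run`` triple) gets a factor equal
    to the geometric mean of its standard-peptide RIAs divided by a global
    reference; every RIA in the run is divided by that factor.  By default
    the reference is the geometric mean of the per-run standard geometric
    means computed from this dataset; passing a fixed ``reference`` pins the
    output scale to an external calibration instead.  Runs with no detected
    standards are excluded and reported.

    Returns ``(normalized, factors, excluded_runs)`` where ``factors`` has
    one row per retained run and ``excluded_runs`` lists dropped run keys.
    Raises :class:`NormalizationError` if no run contains a standard.
    """
    df = dataset.copy()
    valid = df["ria"].notna() & (df["ria"] > 0)
    df = df[valid]
    stds = df[df["is_standard"].astype(bool)]
    if stds.empty:
        raise NormalizationError("dataset contains no internal-standard peptides")
    run_geo = (
        stds.groupby(RUN_KEY)["ria"].apply(lambda v: _geomean(v.to_numpy()))
        .rename("standard_geomean").reset_index()
    )
    if reference is None:
        reference = _geomean(run_geo["standard_geomean"].to_numpy())
    run_geo["factor"] = run_geo["standard_geomean"] / reference

    all_runs = df[RUN_KEY].drop_duplicates()
    merged = all_runs.merge(run_geo, on=RUN_KEY, how="left")
    excluded = merged[merged["factor"].isna()][RUN_KEY].to_records(index=False)
    excluded = [tuple(r) for r in excluded]

    out = df.merge(run_geo[RUN_KEY + ["factor"]], on=RUN_KEY, how="inner")
    out["ria"] = out["ria"] / out["factor"]
    out = out.drop(columns=["factor"])
    factors = run_geo.assign(reference=reference)
    return out, factors, excluded


def coefficient_of_variation(values) -> float:
    """CV percent: 100 * sample standard deviation (n-1) / mean.

    Requires at least two values and a positive mean.
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


def filter_technical_cv(normalized: pd.DataFrame, cv_max: float = 25.0) -> pd.DataFrame:
    """Per biological sample per peptide: keep the technical-replicate mean
    iff >= 2 replicates are present and their CV <= ``cv_max`` percent.

    Returns the long "normalized quant table": one row per (species,
    individual, peptide) with mean RIA, CV, replicate count, an inclusion
    flag, and a machine-readable exclusion reason (``single_replicate`` or
    ``cv_exceeds``).  Standard peptides are passed through with their own
    flag so downstream stages can drop them.
    """
    grp = normalized.groupby(["species", "individual", "peptide"], sort=True)
    rows = []
    for (sp, ind, pep), g in grp:
        v = g["ria"].to_numpy(float)
        protein = g["protein"].iloc[0]
        is_std = bool(g["is_standard"].iloc[0])
        n = v.size
        if n < 2:
            rows.append((sp, ind, pep, protein, is_std, float(v.mean()), np.nan,
                         n, False, "single_replicate"))
            continue
        cv = coefficient_of_variation(v)
        if cv > cv_max:
            rows.append((sp, ind, pep, protein, is_std, float(v.mean()), cv,
                         n, False, "cv_exceeds"))
        else:
            rows.append((sp, ind, pep, protein, is_std, float(v.mean()), cv,
                         n, True, ""))
    return pd.DataFrame(
        rows,
        columns=["species", "individual", "peptide", "protein", "is_standard",
                 "mean_ria", "cv_pct", "n_replicates", "included", "reason"],
    )


def classify_variation(cv: float, conserved_max: float = 25.0,
                       high_min: float = 75.0) -> str:
    """Label a CV percent: < 25 conserved, > 75 high, otherwise intermediate.

    Values exactly at either cutoff are intermediate.
    """
    if cv < 0 or not np.isfinite(cv):
        raise ValueError("CV must be a non-negative finite percent")
    if cv < conserved_max:
        return "conserved"
    if cv > high_min:
        return "high"
    return "intermediate"


def protein_mean_ria(table: pd.DataFrame, min_peptides: int = 3):
    """Arithmetic mean RIA over retained peptides per (species, individual,
    protein); proteins with fewer than ``min_peptides`` retained peptides are
    omitted with a reason.

    Returns ``(protein_table, omitted)``.
    """
    kept = table[table["included"] & ~table["is_standard"].astype(bool)]
    rows, omitted = [], []
    for (sp, ind, prot), g in kept.groupby(["species", "individual", "protein"]):
        n = len(g)
        if n >= min_peptides:
            rows.append((sp, ind, prot, float(g["mean_ria"].mean()), n))
        else:
            omitted.append((sp, ind, prot, n, "fewer_than_min_peptides"))
    protein_table = pd.DataFrame(
        rows, columns=["species", "individual", "protein", "mean_ria", "n_peptides"]
    )
    omitted = pd.DataFrame(
        omitted, columns=["species", "individual", "protein", "n_peptides", "reason"]
    )
    return protein_table, omitted


def nsaf(counts, lengths, proteins=None) -> pd.DataFrame:
    """Normalized spectral abundance factor within one sample.

    ``NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)`` for spectral counts SpC
    and protein lengths L (amino acids).  Values sum to one.
    """
    counts = np.asarray(counts, float)
    lengths = np.asarray(lengths, float)
    if counts.shape != lengths.shape or counts.ndim != 1:
        raise ValueError("counts and lengths must be 1-d and the same length")
    if np.any(lengths <= 0):
        raise ValueError("protein lengths must be positive")
    if np.any(counts < 0) or counts.sum() == 0:
        raise ValueError("spectral counts must be non-negative with at least one > 0")
    saf = counts / lengths
    values = saf / saf.sum()
    if proteins is None:
        proteins = [f"protein_{i}" for i in range(counts.size)]
    return pd.DataFrame(
        {"protein": list(proteins), "spectral_count": counts.astype(int),
         "length": lengths.astype(int), "nsaf": values}
    )
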