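"""End-to-end orchestration and evidence integration.

Runs the full analysis on synthetic or file-based inputs: simulate ->
normalize -> QC -> match -> abundance scans -> codon selection tests ->
trait-rate correlation -> candidate-table integration.  Every stage writes
a TSV plus a structured log; a failure in one gene's evolutionary fit flags
that gene instead of aborting the scan.  The candidate table follows the
summary semantics of the source study: per gene, the high-confidence
posterior probability per sexual character (or ``ns``), an ``x`` for a
significant branch-site test, and an ``x`` for a peptide-level abundance
difference between mating systems.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, correlate, quant, selection, synthetic
from .io import read_quant_table, write_json, write_tsv
from .trees import Phylogeny

__all__ = ["PipelineConfig", "integrate_evidence", "run_full_pipeline"]

ALL_STAGES = ("simulate", "normalize", "qc", "match", "scan", "selection",
              "coevol", "integrate")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serializable to YAML."""

    seed: int = 1
    stages: tuple = ALL_STAGES
    design: dict = field(default_factory=dict)  # SimulationDesign overrides
    n_genes: int = 10
    n_selected_genes: int = 5
    n_codons: int = 300
    kappa: float = 2.0
    selected_model: dict = field(default_factory=lambda: {
        "model": "M8", "p0": 0.9, "p": 2.0, "q": 5.0, "omega_s": 4.0})
    null_model: dict = field(default_factory=lambda: {
        "model": "M8a", "p0": 0.9, "p": 2.0, "q": 5.0})
    cv_max: float = 25.0
    conserved_max: float = 25.0
    high_min: float = 75.0
    alpha: float = 0.05
    sites_fdr: float = 0.01
    branch_site_alpha: float = 0.01
    coevol_positive: float = 0.975
    coevol_negative: float = 0.025
    coevol_mcmc: dict = field(default_factory=lambda: {
        "n_iter": 6000, "burnin_frac": 0.25, "thin": 5})
    char_corr: float = 0.3
    char_var: float = 0.4

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _derived_seed(seed: int, k: int) -> int:
    return int((seed * 9973 + k) % (2**31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# evidence integration
# ---------------------------------------------------------------------------


def integrate_evidence(
    coevol_calls: pd.DataFrame | None,
    branch_site: pd.DataFrame | None,
    abundance: pd.DataFrame | None,
    protein_gene_map: pd.DataFrame,
    *,
    positive: float = 0.975,
    negative: float = 0.025,
) -> tuple[pd.DataFrame, dict]:
    """Merge the three evidence streams into a candidate-gene table.

    * ``coevol_calls``: gene, character, pp (posterior probability of a
      positive rate-character correlation).  A pp is reported only when it
      clears the high-confidence cutoffs; otherwise the field is ``ns``.
    * ``branch_site``: gene, significant (bool).
    * ``abundance``: peptide-level scan with ``protein`` and ``significant``;
      a protein is abundance-flagged iff any of its peptides is significant,
      and genes come from ``protein_gene_map`` (protein, gene, transcript).

    Returns ``(table, report)``; ``report`` carries per-category and union
    counts plus any unmappable peptides (reported, never dropped silently).
    """
    pmap = protein_gene_map.set_index("protein")
    characters: list[str] = []
    coevol_genes: dict[str, dict] = {}
    if coevol_calls is not None and len(coevol_calls):
        characters = list(dict.fromkeys(coevol_calls["character"]))
        for gene, g in coevol_calls.groupby("gene"):
            row = {}
            called = False
            for _, r in g.iterrows():
                pp = float(r["pp"])
                if pp >= positive or pp <= negative:
                    row[r["character"]] = f"{pp:.3f}"
                    called = True
                else:
                    row[r["character"]] = "ns"
            if called:
                coevol_genes[gene] = row
    bs_genes = set()
    if branch_site is not None and len(branch_site):
        bs_genes = set(branch_site.loc[branch_site["significant"], "gene"])
    abund_genes: set[str] = set()
    unmapped: list[str] = []
    if abundance is not None and len(abundance):
        sig = abundance[abundance["significant"]]
        for prot in sig["protein"].unique():
            if prot in pmap.index:
                abund_genes.add(pmap.loc[prot, "gene"])
            else:
                unmapped.append(prot)
    genes = sorted(set(coevol_genes) | bs_genes | abund_genes)
    rows = []
    for gene in genes:
        hit = pmap[pmap["gene"] == gene]
        transcript = hit["transcript"].iloc[0] if ("transcript" in pmap and len(hit)) else ""
        row = {"gene": gene, "transcript": transcript}
        for c in characters:
            row[c] = coevol_genes.get(gene, {}).get(c, "ns")
        row["branch_site"] = "x" if gene in bs_genes else "ns"
        row["abundance"] = "x" if gene in abund_genes else "ns"
        rows.append(row)
    table = pd.DataFrame(rows)
    co = set(coevol_genes)
    report = {
        "n_genes": len(genes),
        "n_coevol": len(co),
        "n_branch_site": len(bs_genes),
        "n_abundance": len(abund_genes),
        "n_coevol_only": len(co - bs_genes - abund_genes),
        "n_branch_site_only": len(bs_genes - co - abund_genes),
        "n_abundance_only": len(abund_genes - co - bs_genes),
        "n_multiple_evidence": len(
            (co & bs_genes) | (co & abund_genes) | (bs_genes & abund_genes)
        ),
        "unmapped_proteins": sorted(set(unmapped)),
    }
    return table, report


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


def _simulate_inputs(config: PipelineConfig, out: Path, log: list):
    tree = synthetic.fixed_primate_tree()
    design_kwargs = dict(config.design)
    design_kwargs.setdefault("seed", _derived_seed(config.seed, 1))
    design_kwargs.setdefault("peptides_per_protein", 5)
    design_kwargs.setdefault("fraction_shared", 0.4)
    design = synthetic.SimulationDesign(**design_kwargs)
    dataset, truth = synthetic.simulate_quant_dataset(design)

    k = 1 + 5
    R = np.full((k, k), config.char_corr)
    np.fill_diagonal(R, 1.0)
    cov = R * config.char_var
    root = np.array([np.log(0.2), 0, 0, 0, 0, 0])
    chars, branch_rates, _ = synthetic.simulate_characters(
        tree, cov, root, seed=_derived_seed(config.seed, 2)
    )

    genes, selected = [], []
    proteins = sorted(truth["true_abundance"]["protein"].unique())
    for i in range(config.n_genes):
        gene = f"G{i:03d}"
        sel = i < config.n_selected_genes
        spec = dict(config.selected_model if sel else config.null_model)
        model = spec.pop("model")
        aln = synthetic.simulate_codon_alignment(
            tree, model, config.n_codons, seed=_derived_seed(config.seed, 100 + i),
            kappa=config.kappa, **spec,
        )
        genes.append({"gene": gene, "alignment": aln, "selected": sel,
                      "protein": proteins[i]})
        if sel:
            selected.append(gene)
    pmap = pd.DataFrame({
        "protein": proteins,
        "gene": [f"G{i:03d}" if i < config.n_genes else f"G{i:03d}x"
                 for i in range(len(proteins))],
        "transcript": [f"T{i:04d}" for i in range(len(proteins))],
    })

    (out / "alignments").mkdir(parents=True, exist_ok=True)
    for g in genes:
        g["alignment"].to_fasta(out / "alignments" / f"{g['gene']}.fasta")
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    write_tsv(chars.reset_index(), out / "characters.tsv")
    from .io import write_quant_table
    write_quant_table(dataset, out / "quant_raw.tsv")
    write_tsv(truth["true_abundance"], out / "truth_abundance.tsv")
    write_tsv(truth["run_factors"], out / "truth_run_factors.tsv")
    write_tsv(pmap, out / "protein_gene_map.tsv")
    log.append({"stage": "simulate", "rows": int(len(dataset)),
                "n_genes": config.n_genes, "n_selected": len(selected)})
    return {"tree": tree, "dataset": dataset, "truth": truth, "chars": chars,
            "genes": genes, "selected_genes": selected, "pmap": pmap}


def run_full_pipeline(config: PipelineConfig, out_dir, resume: bool = False) -> dict:
    """Execute the configured stages; returns a result bundle.

    Outputs are written as TSV/JSON under ``out_dir``; reruns with the same
    config and seed are byte-identical.  With ``resume=True`` the simulated
    inputs are read back from an existing ``out_dir`` instead of being
    regenerated.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    result: dict = {"config": config}
    stages = tuple(config.stages)

    if "simulate" in stages:
        if resume and (out / "quant_raw.tsv").exists():
            dataset, bad = read_quant_table(out / "quant_raw.tsv")
            tree = Phylogeny.from_newick((out / "tree.nwk").read_text(),
                                         mating=dict(synthetic.PRIMATE_MATING))
            sim = {"tree": tree, "dataset": dataset, "truth": None,
                   "chars": None, "genes": [], "selected_genes": None,
                   "pmap": pd.read_csv(out / "protein_gene_map.tsv", sep="\t",
                                       comment="#")}
            from .io import read_characters
            sim["chars"] = read_characters(out / "characters.tsv")
            from .alignment import CodonAlignment
            for f in sorted((out / "alignments").glob("*.fasta")):
                sim["genes"].append({"gene": f.stem,
                                     "alignment": CodonAlignment.from_fasta(f),
                                     "selected": None, "protein": None})
            log.append({"stage": "simulate", "resumed": True})
        else:
            sim = _simulate_inputs(config, out, log)
        result.update(sim)
    else:
        write_json({"config": asdict(config)}, out / "manifest.json")
        result["log"] = log
        return result

    tree = result["tree"]
    labels = tree.mating

    normalized = factors = None
    if "normalize" in stages:
        normalized, factors, excluded = quant.normalize_by_standards(
            result["dataset"]
        )
        write_tsv(normalized, out / "quant_normalized.tsv")
        write_tsv(factors, out / "norm_factors.tsv")
        log.append({"stage": "normalize", "rows": int(len(normalized)),
                    "excluded_runs": [list(e) for e in excluded]})

    qc_table = None
    if "qc" in stages and normalized is not None:
        qc_table = quant.filter_technical_cv(normalized, cv_max=config.cv_max)
        protein_table, omitted = quant.protein_mean_ria(qc_table)
        write_tsv(qc_table, out / "qc_table.tsv",
                  {"cv_max": config.cv_max})
        write_tsv(protein_table, out / "protein_abundance.tsv")
        log.append({"stage": "qc", "cv_max": config.cv_max,
                    "included": int(qc_table["included"].sum()),
                    "excluded": int((~qc_table["included"]).sum())})

    matched = None
    if "match" in stages and qc_table is not None:
        tables = {sp: g for sp, g in qc_table.groupby("species")}
        matched = compare.match_identical_peptides(tables)
        write_tsv(matched.values, out / "matched_peptides.tsv")
        log.append({"stage": "match", "species": matched.species,
                    "n_shared": len(matched.shared_peptides)})

    scan_results = scan_summary = None
    if "scan" in stages and matched is not None:
        scan_results, scan_summary = compare.mating_system_scan(
            matched, labels, alpha=config.alpha
        )
        write_tsv(scan_results, out / "scan_mating.tsv",
                  {"alpha": config.alpha})
        log.append({"stage": "scan", **scan_summary})
    result.update(matched=matched, scan_results=scan_results,
                  scan_summary=scan_summary)

    sites_df = bs_df = None
    if "selection" in stages and result["genes"]:
        srows, brows = [], []
        for g in result["genes"]:
            try:
                r = selection.sites_lrt(g["alignment"], tree, ("M8a", "M8"),
                                        seed=_derived_seed(config.seed, 7))
                srows.append({"gene": g["gene"], "model_null": "M8a",
                              "model_alt": "M8", "lnl_null": r["null_fit"].lnl,
                              "lnl_alt": r["alt_fit"].lnl, "stat": r["stat"],
                              "p": r["p"], "error": ""})
            except Exception as exc:  # failure isolation per gene
                srows.append({"gene": g["gene"], "model_null": "M8a",
                              "model_alt": "M8", "lnl_null": np.nan,
                              "lnl_alt": np.nan, "stat": np.nan, "p": np.nan,
                              "error": str(exc)})
            try:
                b = selection.branch_site_test(
                    g["alignment"], tree, foreground="multi",
                    seed=_derived_seed(config.seed, 8))
                brows.append({"gene": g["gene"], "stat": b.stat, "p": b.p,
                              "omega2": b.omega2, "error": ""})
            except Exception as exc:
                brows.append({"gene": g["gene"], "stat": np.nan, "p": np.nan,
                              "omega2": np.nan, "error": str(exc)})
        sites_df = pd.DataFrame(srows)
        ok = sites_df["p"].notna()
        qv = np.full(len(sites_df), np.nan)
        sigv = np.zeros(len(sites_df), bool)
        if ok.any():
            q, sig = selection.qvalue_fdr(sites_df.loc[ok, "p"],
                                          threshold=config.sites_fdr)
            qv[ok.to_numpy()] = q
            sigv[ok.to_numpy()] = sig
        sites_df["q"] = qv
        sites_df["significant"] = sigv
        bs_df = pd.DataFrame(brows)
        bs_df["significant"] = bs_df["p"] < config.branch_site_alpha
        write_tsv(sites_df, out / "sites_tests.tsv", {"fdr": config.sites_fdr})
        write_tsv(bs_df, out / "branch_site.tsv",
                  {"alpha": config.branch_site_alpha})
        log.append({"stage": "selection",
                    "sites_significant": int(sites_df["significant"].sum()),
                    "branch_site_significant": int(bs_df["significant"].sum()),
                    "errors": int((sites_df["error"] != "").sum()
                                  + (bs_df["error"] != "").sum())})
    result.update(sites_tests=sites_df, branch_site=bs_df)

    coevol_calls = None
    if "coevol" in stages and result["genes"] and result["chars"] is not None:
        crows = []
        mcmc = dict(config.coevol_mcmc)
        for gi, g in enumerate(result["genes"]):
            try:
                brates = correlate.estimate_branch_omega(g["alignment"], tree)
                post = correlate.fit_brownian_correlation(
                    tree, brates, result["chars"],
                    seed=_derived_seed(config.seed, 300 + gi), **mcmc,
                )
                for char in post.characters:
                    crows.append({"gene": g["gene"], "character": char,
                                  "pp": post.pp[char],
                                  "mean_r": post.mean_corr[char],
                                  "call": post.calls[char], "error": ""})
            except Exception as exc:
                crows.append({"gene": g["gene"], "character": "", "pp": np.nan,
                              "mean_r": np.nan, "call": "error",
                              "error": str(exc)})
        coevol_calls = pd.DataFrame(crows)
        write_tsv(coevol_calls, out / "coevol_calls.tsv",
                  {"positive": config.coevol_positive,
                   "negative": config.coevol_negative})
        log.append({"stage": "coevol",
                    "n_calls": int((coevol_calls["call"] != "ns").sum())})
    result["coevol_calls"] = coevol_calls

    candidate = report = None
    if "integrate" in stages:
        candidate, report = integrate_evidence(
            coevol_calls, bs_df, scan_results, result["pmap"],
            positive=config.coevol_positive, negative=config.coevol_negative,
        )
        write_tsv(candidate, out / "candidate_table.tsv")
        log.append({"stage": "integrate", **{k: v for k, v in report.items()
                                             if k != "unmapped_proteins"}})
    result.update(candidate_table=candidate, integration_report=report)

    # recovery metrics against planted truth (available when simulated fresh)
    summary: dict = {"stages": list(stages)}
    if scan_summary:
        summary["abundance_scan"] = scan_summary
    if result.get("truth") and scan_results is not None:
        responsive = set(result["truth"]["responsive_proteins"])
        flagged = set(scan_results.loc[scan_results["significant"], "protein"])
        summary["abundance_recovery"] = {
            "n_responsive": len(responsive),
            "n_recovered": len(responsive & flagged),
            "false_flags": len(flagged - responsive),
        }
    if result.get("selected_genes") is not None and sites_df is not None:
        planted = set(result["selected_genes"])
        flagged = set(sites_df.loc[sites_df["significant"], "gene"])
        summary["selection_recovery"] = {
            "n_planted": len(planted),
            "n_recovered": len(planted & flagged),
            "false_flags": len(flagged - planted),
        }
    if report:
        summary["integration"] = {k: v for k, v in report.items()
                                  if k != "unmapped_proteins"}
    result["summary"] = summary
    result["log"] = log

    manifest = {
        "config": asdict(config),
        "log": log,
        "summary": summary,
        "inputs": {f.name: _sha256(f) for f in sorted(out.glob("*.tsv"))},
    }
    write_json(manifest, out / "manifest.json")
    write_json(summary, out / "summary.json")
    return result
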