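"""Synthetic-data generation for every pipeline input.

The generator emulates the statistical structure of a cross-species
label-free seminal-fluid proteomics study together with its evolutionary
substrate: peptide RIA tables with spike-in standards, run-level scale
factors, lognormal biological variation and technical noise; in-frame codon
alignments evolved under site or branch-site omega mixtures on a fixed
primate phylogeny; and sexual characters co-evolving with log dN/dS as a
multivariate Brownian motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .codon import N_STATES, Propagator, decode_codons, uniform_frequencies
from .selection import SiteMixture, _branch_site_table, _branch_site_weights, site_mixture
from .trees import MULTI, UNI, Phylogeny

__all__ = [
    "fixed_primate_tree",
    "PROTEOMIC_SPECIES",
    "STANDARD_PROTEINS",
    "simulate_codon_alignment",
    "simulate_characters",
    "SimulationDesign",
    "simulate_quant_dataset",
]

# ---------------------------------------------------------------------------
# fixed primate phylogeny
# ---------------------------------------------------------------------------

# 13 primate taxa: 5 apes, 6 Old World monkeys, 1 New World monkey, 1
# strepsirrhine.  Branch lengths are plausible defaults in expected
# substitutions per codon site (they are configuration, not inference).
_PRIMATE_NEWICK = (
    "((((((human:0.013,chimpanzee:0.014):0.009,gorilla:0.019):0.008,"
    "orangutan:0.033):0.007,gibbon:0.041):0.012,"
    "((((rhesus_macaque:0.008,cynomolgus_macaque:0.008):0.013,"
    "(baboon:0.012,drill:0.013):0.008):0.012,vervet:0.030):0.008,"
    "colobus:0.036):0.025):0.055,marmoset:0.125,mouse_lemur:0.275);"
)

#: mating-system designation per tip (uni-male vs multi-male)
PRIMATE_MATING = {
    "human": UNI,
    "chimpanzee": MULTI,
    "gorilla": UNI,
    "orangutan": UNI,
    "gibbon": UNI,
    "rhesus_macaque": MULTI,
    "cynomolgus_macaque": MULTI,
    "baboon": MULTI,
    "drill": UNI,
    "vervet": MULTI,
    "colobus": MULTI,
    "marmoset": UNI,
    "mouse_lemur": MULTI,
}

#: the species with quantitative peptide data (complete internal standards)
PROTEOMIC_SPECIES = ("human", "rhesus_macaque", "cynomolgus_macaque", "drill", "vervet")

#: reserved protein ids for the spiked internal standards
STANDARD_PROTEINS = ("STD_MYOGLOBIN", "STD_TRYPSIN")


def fixed_primate_tree() -> Phylogeny:
    """The 13-tip primate phylogeny with uni/multi mating labels attached."""
    return Phylogeny.from_newick(_PRIMATE_NEWICK, mating=dict(PRIMATE_MATING))


# ---------------------------------------------------------------------------
# codon alignment simulation
# ---------------------------------------------------------------------------


def simulate_codon_alignment(
    tree: Phylogeny,
    model: str | SiteMixture = "M0",
    n_codons: int = 300,
    seed: int = 0,
    *,
    kappa: float = 2.0,
    pi=None,
    K: int = 10,
    foreground: str | None = None,
    return_truth: bool = False,
    **params,
):
    """Simulate an in-frame codon alignment under a named codon model.

    ``model`` is one of M0/M1a/M2a/M7/M8/M8a (with the parameters of
    :func:`sfpevol.selection.site_mixture`), a :class:`SiteMixture`, or
    ``"branch-site"`` (parameters ``p0, p1, omega0, omega2`` and a
    ``foreground`` mating label).  Each site draws an omega class from the
    mixture, the root codon comes from the stationary frequencies, and
    states evolve along branches under the GY94 process, scaled so branch
    lengths are expected substitutions per codon at the mixture mean.
    """
    if n_codons <= 0:
        raise ValueError("n_codons must be positive")
    rng = np.random.default_rng(seed)
    pi = uniform_frequencies() if pi is None else np.asarray(pi, float)

    branch_site = isinstance(model, str) and model.lower() in (
        "branch-site", "branch_site", "branch-site a", "bsa"
    )
    if branch_site:
        fgmask = tree.foreground_mask(foreground or MULTI)
        omega0 = params.get("omega0", 0.2)
        omega2 = params.get("omega2", 1.0)
        weights = _branch_site_weights(params.get("p0", 0.75), params.get("p1", 0.85))
        table = _branch_site_table(omega0, omega2, fgmask)
        name = "branch-site"
    else:
        mix = model if isinstance(model, SiteMixture) else site_mixture(
            model, K=K, **params
        )
        weights = mix.weights
        table = np.repeat(mix.omegas[:, None], tree.n_nodes, axis=1)
        name = mix.name

    C = weights.size
    uniq, inv = np.unique(np.round(table, 14), return_inverse=True)
    inv = inv.reshape(table.shape)
    props = [Propagator(kappa, w, pi) for w in uniq]
    rates = np.array([p.rate for p in props])
    if branch_site:
        # branch lengths are defined on the background rate scale, so a
        # foreground class with omega2 > 1 genuinely adds substitutions on
        # foreground lineages (what the branch-site LRT detects)
        bg = np.array([omega0, 1.0, omega0, 1.0])
        bg_rates = np.array(
            [Propagator(kappa, w, pi).rate for w in np.unique(bg)]
        )
        rho_scalar = float(weights @ bg_rates[
            np.unique(bg, return_inverse=True)[1]])
        rho = np.full(tree.n_nodes, rho_scalar)
    else:
        rho = weights @ rates[inv]  # mixture-mean rate (same on all branches)
    # transition matrices per (class, node)
    P = np.empty((C, tree.n_nodes, N_STATES, N_STATES))
    for u, prop in enumerate(props):
        sel = np.nonzero(inv == u)
        teff = tree.blen[sel[1]] / rho[sel[1]]
        P[sel] = prop.matrices(teff)

    class_of_site = rng.choice(C, size=n_codons, p=weights / weights.sum())
    root_states = rng.choice(N_STATES, size=n_codons, p=pi / pi.sum())
    states = np.empty((tree.n_nodes, n_codons), dtype=np.int16)
    states[tree.root] = root_states
    for v in range(tree.n_nodes - 2, -1, -1):
        par = states[tree.parent[v]]
        cur = np.empty_like(par)
        for c in range(C):
            sel = class_of_site == c
            if not sel.any():
                continue
            cum = np.cumsum(P[c, v][par[sel]], axis=1)
            cum[:, -1] = 1.0
            u = rng.random(int(sel.sum()))
            cur[sel] = (cum < u[:, None]).sum(axis=1)
        states[v] = cur
    seqs = {
        tree.names[v]: decode_codons(states[v]) for v in tree.tip_ids
    }
    aln = CodonAlignment.from_strings(seqs)
    if return_truth:
        truth = {
            "model": name,
            "class_of_site": class_of_site,
            "omega_table": table,
            "weights": weights,
            "kappa": kappa,
        }
        return aln, truth
    return aln


# ---------------------------------------------------------------------------
# character simulation (multivariate Brownian motion)
# ---------------------------------------------------------------------------

DEFAULT_CHARACTERS = (
    "mating_latent",
    "relative_testis_size",
    "sexual_size_dimorphism",
    "semen_coagulation_rating",
    "mean_partners",
)


def simulate_characters(
    tree: Phylogeny,
    covariance: np.ndarray,
    root_state: np.ndarray,
    seed: int = 0,
    *,
    char_names: tuple[str, ...] | None = None,
    mating_char: str = "mating_latent",
    branch_noise: bool = True,
):
    """Multivariate Brownian motion of (log omega, characters) on the tree.

    Dimension 0 of ``covariance`` is log dN/dS; the remaining dimensions are
    latent continuous characters.  Returns ``(characters, branch_rates,
    latent)``:

    * ``characters`` — per-tip DataFrame: ``mating_type`` (0/1 by median
      split of the designated latent character), positive characters
      ``exp(latent)``, and ``semen_coagulation_rating`` as an ordinal 1-4
      quartile binning of its latent value.
    * ``branch_rates`` — per-branch DataFrame with the true branch-average
      ``log_omega`` (Brownian-bridge average: midpoint plus N(0, t*S00/12)
      when ``branch_noise``) keyed by child node.
    * ``latent`` — the raw tip values of the latent process.

    The median-split rule for the binary mating label is recorded in
    ``characters.attrs``.
    """
    cov = np.asarray(covariance, float)
    p = cov.shape[0]
    if cov.shape != (p, p) or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    if p >= 2:
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10 * max(1.0, eig.max()):
            raise ValueError("covariance must be positive semi-definite")
    root_state = np.asarray(root_state, float)
    if root_state.shape != (p,):
        raise ValueError("root_state dimension mismatch")
    if char_names is None:
        char_names = DEFAULT_CHARACTERS[: p - 1]
    if len(char_names) != p - 1:
        raise ValueError("need one name per non-rate dimension")
    rng = np.random.default_rng(seed)
    # matrix square root tolerant of singular covariances
    w, V = np.linalg.eigh(cov)
    L = V * np.sqrt(np.clip(w, 0, None))[None, :]
    X = np.empty((tree.n_nodes, p))
    X[tree.root] = root_state
    for v in range(tree.n_nodes - 2, -1, -1):
        t = tree.blen[v]
        X[v] = X[tree.parent[v]] + np.sqrt(t) * (L @ rng.standard_normal(p))

    # branch-average log omega
    rows = []
    for v in range(tree.n_nodes - 1):
        t = tree.blen[v]
        mid = 0.5 * (X[v, 0] + X[tree.parent[v], 0])
        if branch_noise and cov[0, 0] > 0:
            mid += rng.normal(0.0, np.sqrt(t * cov[0, 0] / 12.0))
        rows.append({"child": v, "name": tree.node_label(v), "length": t,
                     "log_omega": mid})
    branch_rates = pd.DataFrame(rows)

    tips = tree.tip_names
    latent = pd.DataFrame(
        {name: X[tree.tip_ids, j + 1] for j, name in enumerate(char_names)},
        index=pd.Index(tips, name="species"),
    )
    chars = pd.DataFrame(index=latent.index)
    if mating_char in latent:
        med = latent[mating_char].median()
        chars["mating_type"] = (latent[mating_char] > med).astype(int)
    for name in char_names:
        if name == mating_char:
            continue
        if name == "semen_coagulation_rating":
            # ordinal 1-4 by latent quartile
            chars[name] = (
                pd.qcut(latent[name], 4, labels=False, duplicates="drop") + 1
            ).astype(int)
        else:
            chars[name] = np.exp(latent[name])
    chars.attrs["mating_rule"] = (
        f"mating_type = 1 iff latent {mating_char!r} above its tip median"
    )
    return chars, branch_rates, latent


# ---------------------------------------------------------------------------
# peptide quantification simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationDesign:
    """Design of a synthetic peptide-quantification experiment.

    Defaults mirror the study layout: five proteomic species, eight
    biological individuals for human and rhesus macaque and two elsewhere,
    three randomized technical replicates per biological sample, spiked
    internal standards in every run, multiplicative run scale factors, and
    lognormal biological/technical variation (CVs parameterize the sigma of
    the log).
    """

    species: tuple[str, ...] = PROTEOMIC_SPECIES
    mating: dict = field(default_factory=lambda: dict(PRIMATE_MATING))
    individuals: dict = field(default_factory=lambda: {"human": 8, "rhesus_macaque": 8})
    default_individuals: int = 2
    technical_replicates: int = 3
    n_proteins: int = 100
    peptides_per_protein: int = 4
    fraction_shared: float = 0.35
    n_standard_peptides: int = 6
    standard_ria: float = 2.0e4
    run_scale_sigma: float = 0.5
    biological_cv: float = 0.50
    technical_cv: float = 0.10
    peptide_ionization_sigma: float = 0.5
    mating_effect: float = float(np.log(3.0))
    n_responsive: int = 10
    effect_direction: str = "multi_higher"
    missing_rate: float = 0.05
    base_log10_mean: float = 5.5
    base_log10_sd: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        for name in ("run_scale_sigma", "biological_cv", "technical_cv",
                     "peptide_ionization_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fraction_shared", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_responsive > self.n_proteins:
            raise ValueError("more responsive proteins than proteins")
        missing = [s for s in self.species if s not in self.mating]
        if missing:
            raise ValueError(f"species without mating label: {missing}")
        if self.effect_direction not in ("multi_higher", "uni_higher"):
            raise ValueError("effect_direction must be multi_higher or uni_higher")
        systems = {self.mating[s] for s in self.species}
        if systems != {UNI, MULTI}:
            raise ValueError("design must include both uni- and multi-male species")

    def n_individuals(self, species: str) -> int:
        return int(self.individuals.get(species, self.default_individuals))


def _cv_to_sigma(cv: float) -> float:
    """Sigma of the log for a lognormal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv * cv)))


_AA = "ACDEFGHILMNPQSTVWY"


def _peptide_sequences(rng, n: int, length: int = 9) -> list[str]:
    """Random tryptic-like peptide strings (unique, K/R terminated)."""
    out = set()
    while len(out) < n:
        core = "".join(rng.choice(list(_AA), size=length))
        out.add(core + rng.choice(["K", "R"]))
    return sorted(out)


def simulate_quant_dataset(design: SimulationDesign):
    """Simulate a long-format peptide RIA table plus ground truth.

    Returns ``(dataset, truth)`` where ``dataset`` has columns
    (species, individual, run, peptide, protein, is_standard, ria) and
    ``truth`` carries the true per-(species, protein) abundances, the
    responsive protein ids, the per-run scale factors, and each peptide's
    species-presence set.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n_pep = design.n_proteins * design.peptides_per_protein
    proteins = [f"P{i:04d}" for i in range(design.n_proteins)]
    peptides = _peptide_sequences(rng, n_pep)
    pep_protein = {pep: proteins[i // design.peptides_per_protein]
                   for i, pep in enumerate(peptides)}
    responsive = sorted(rng.choice(proteins, size=design.n_responsive, replace=False))
    species = list(design.species)
    # species presence per peptide: identical sequence shared across all
    # species with probability fraction_shared, otherwise a single species
    # (sequence divergence breaks exact peptide identity)
    presence = {}
    for pep in peptides:
        if rng.random() < design.fraction_shared:
            presence[pep] = tuple(species)
        else:
            presence[pep] = (species[rng.integers(len(species))],)

    sigma_bio = _cv_to_sigma(design.biological_cv)
    sigma_tech = _cv_to_sigma(design.technical_cv)
    sign = 1.0 if design.effect_direction == "multi_higher" else -1.0

    base = 10 ** rng.normal(design.base_log10_mean, design.base_log10_sd,
                            size=design.n_proteins)
    protein_base = dict(zip(proteins, base))
    pep_ion = {pep: rng.lognormal(0.0, design.peptide_ionization_sigma)
               for pep in peptides}

    true_rows = []
    true_abund = {}
    for sp in species:
        shift = sign * design.mating_effect if design.mating[sp] == MULTI else 0.0
        for prot in proteins:
            a = protein_base[prot] * (np.exp(shift) if prot in responsive else 1.0)
            true_abund[(sp, prot)] = a
            true_rows.append({"species": sp, "protein": prot, "true_abundance": a,
                              "responsive": prot in responsive})

    std_peps = [f"STDPEP{k}{'K' if k % 2 else 'R'}" for k in range(design.n_standard_peptides)]
    std_protein = {pep: STANDARD_PROTEINS[k % len(STANDARD_PROTEINS)]
                   for k, pep in enumerate(std_peps)}
    std_level = {pep: design.standard_ria * rng.lognormal(0.0, 0.2)
                 for pep in std_peps}

    rows = []
    run_rows = []
    for sp in species:
        for ind in range(1, design.n_individuals(sp) + 1):
            ind_id = f"{sp}_{ind}"
            pep_ind = {}
            for pep in peptides:
                if sp not in presence[pep]:
                    continue
                prot = pep_protein[pep]
                pep_ind[pep] = (true_abund[(sp, prot)] * pep_ion[pep]
                                * rng.lognormal(0.0, sigma_bio))
            for rep in range(1, design.technical_replicates + 1):
                run_id = f"r{rep}"
                factor = rng.lognormal(0.0, design.run_scale_sigma)
                run_rows.append({"species": sp, "individual": ind_id,
                                 "run": run_id, "scale_factor": factor})
                for pep, level in pep_ind.items():
                    if design.missing_rate and rng.random() < design.missing_rate:
                        continue
                    ria = level * factor * rng.lognormal(0.0, sigma_tech)
                    rows.append((sp, ind_id, run_id, pep, pep_protein[pep],
                                 False, ria))
                for pep in std_peps:
                    if design.missing_rate and rng.random() < design.missing_rate:
                        continue
                    ria = std_level[pep] * factor * rng.lognormal(0.0, sigma_tech)
                    rows.append((sp, ind_id, run_id, pep, std_protein[pep],
                                 True, ria))
    dataset = pd.DataFrame(
        rows,
        columns=["species", "individual", "run", "peptide", "protein",
                 "is_standard", "ria"],
    )
    truth = {
        "true_abundance": pd.DataFrame(true_rows),
        "responsive_proteins": list(responsive),
        "run_factors": pd.DataFrame(run_rows),
        "peptide_species": pd.DataFrame(
            [{"peptide": p, "protein": pep_protein[p],
              "species_set": ";".join(presence[p])} for p in peptides]
        ),
        "design": asdict(design),
    }
    return dataset, truth
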