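"""Phylogenetic correlation between evolutionary rate and sexual characters.

A two-stage, coevol-style analysis.  Stage one estimates a per-branch
dN/dS (omega) by one-omega-per-branch maximum likelihood with branch
lengths and kappa fixed from an M0 fit, lightly penalized toward the gene's
global omega so branches with no inferred events stay finite.  Stage two
places a latent multivariate Brownian motion over (log omega, characters)
on the tree: characters are observed at the tips, branch log omega is
observed as the branch-average of the latent rate coordinate plus Gaussian
noise whose variance scales inversely with a per-branch weight.  A Gibbs
sampler draws node states (conditional Gaussians), the Brownian covariance
(conjugate inverse-Wishart) and the observation noise scale (conjugate
inverse-gamma); marginal correlations and their posterior probabilities
Pr(r > 0) come from the covariance samples.  Calls use the strict
0.975 / 0.025 posterior-probability cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .alignment import CodonAlignment
from .selection import CodonLikelihood, SiteModelFit, fit_site_model
from .trees import Phylogeny

__all__ = [
    "estimate_branch_omega",
    "CorrelationPosterior",
    "fit_brownian_correlation",
    "classify_correlation",
    "DEFAULT_TRANSFORMS",
]

#: how each standard sexual character enters the Brownian model
DEFAULT_TRANSFORMS = {
    "mating_type": "identity",            # binary 0/1 covariate
    "relative_testis_size": "log",
    "sexual_size_dimorphism": "log",
    "semen_coagulation_rating": "identity",  # ordinal 1-4
    "mean_partners": "log",
}

POSITIVE_CUTOFF = 0.975
NEGATIVE_CUTOFF = 0.025


# ---------------------------------------------------------------------------
# stage one: per-branch omega
# ---------------------------------------------------------------------------


def estimate_branch_omega(
    alignment: CodonAlignment,
    tree: Phylogeny,
    *,
    pi=None,
    base: SiteModelFit | None = None,
    penalty_sd: float = 2.0,
    sweeps: int = 2,
    omega_bounds: tuple[float, float] = (1e-3, 20.0),
) -> pd.DataFrame:
    """Free-ratio-lite: one maximum-likelihood omega per branch.

    Branch lengths and kappa are fixed from an M0 fit; omegas are optimized
    one branch at a time (coordinate sweeps) with a weak Gaussian penalty on
    log omega centred at the M0 estimate (sd ``penalty_sd``), which acts as
    a pseudocount for branches carrying no informative substitutions.
    Zero-length branches and alignments without substitutions yield missing
    omegas.  The per-branch uncertainty weight is branch length times
    alignment length in codons.
    """
    engine = CodonLikelihood(alignment, tree, pi=pi)
    rows = []
    if alignment.is_constant():
        for v in range(tree.n_nodes - 1):
            rows.append({"child": v, "name": tree.node_label(v),
                         "length": tree.blen[v], "omega": np.nan,
                         "log_omega": np.nan, "weight": 0.0,
                         "method": "no_substitutions"})
        return pd.DataFrame(rows)
    if base is None:
        base = fit_site_model(alignment, tree, "M0", pi=pi, engine=engine)
    kappa, blens = base.kappa, base.blens
    center = np.log(np.clip(base.params["omega"], *omega_bounds))
    n = tree.n_nodes
    log_omegas = np.full(n, center)
    weights = np.ones(1)
    lo, hi = np.log(omega_bounds[0]), np.log(omega_bounds[1])
    usable = np.array([tree.blen[v] > 1e-9 for v in range(n - 1)] + [False])

    def neg_pen_lnl(lw, b):
        trial = log_omegas.copy()
        trial[b] = lw
        table = np.exp(trial)[None, :]
        return (-engine.lnl(kappa, weights, table, blens)
                + (lw - center) ** 2 / (2 * penalty_sd**2))

    for _ in range(sweeps):
        for b in range(n - 1):
            if not usable[b]:
                continue
            r = optimize.minimize_scalar(
                neg_pen_lnl, args=(b,), bounds=(lo, hi), method="bounded",
                options={"xatol": 5e-3},
            )
            log_omegas[b] = r.x
    for v in range(n - 1):
        ok = usable[v]
        rows.append({
            "child": v, "name": tree.node_label(v), "length": tree.blen[v],
            "omega": float(np.exp(log_omegas[v])) if ok else np.nan,
            "log_omega": float(log_omegas[v]) if ok else np.nan,
            "weight": float(tree.blen[v] * alignment.n_codons) if ok else 0.0,
            "method": "free_ratio_lite" if ok else "zero_length",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage two: Brownian covariance MCMC
# ---------------------------------------------------------------------------


@dataclass
class CorrelationPosterior:
    """Posterior over the Brownian covariance of (log omega, characters)."""

    characters: list[str]
    sigma_samples: np.ndarray  # (S, p, p)
    corr_samples: np.ndarray   # (S, p, p)
    noise_samples: np.ndarray  # (S,)
    pp: pd.Series              # per character: Pr(corr(log omega, char) > 0)
    mean_corr: pd.Series
    ess: pd.Series
    calls: pd.Series = field(default=None)

    def pair_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "character": self.characters,
            "posterior_mean_r": self.mean_corr.to_numpy(),
            "pp": self.pp.to_numpy(),
            "call": [classify_correlation(v) for v in self.pp],
            "ess": self.ess.to_numpy(),
        })


def _simple_ess(x: np.ndarray) -> float:
    """Effective sample size via the initial positive autocorrelation sum."""
    n = x.size
    if n < 10 or np.ptp(x) == 0:
        return float(n)
    from statsmodels.tsa.stattools import acf

    nlags = min(n // 3, 200)
    rho = acf(x, nlags=nlags, fft=True)[1:]
    s = 0.0
    for r in rho:
        if r <= 0:
            break
        s += r
    return float(n / (1 + 2 * s))


def fit_brownian_correlation(
    tree: Phylogeny,
    branch_log_omega: pd.DataFrame,
    characters: pd.DataFrame,
    *,
    transforms: dict | None = None,
    n_iter: int = 20000,
    burnin_frac: float = 0.25,
    thin: int = 10,
    seed: int = 0,
    prior_df: int | None = None,
    prior_scale: np.ndarray | None = None,
    noise_prior: tuple[float, float] = (2.0, 0.05),
    noise_floor: float = 1e-4,
) -> CorrelationPosterior:
    """Gibbs sampler for the Brownian covariance of (log omega, characters).

    ``branch_log_omega`` needs columns ``child`` (node index), ``log_omega``
    and optionally ``weight``; rows with missing log omega are ignored.
    ``characters`` is indexed by tip name; positive-scaled characters are
    log-transformed according to ``transforms`` (default
    :data:`DEFAULT_TRANSFORMS`); missing entries are marginalized as latent
    Gaussian coordinates.  Priors: inverse-Wishart(I, dim + 2) on the
    covariance, inverse-gamma on the observation-noise scale.
    """
    if n_iter < 200:
        raise ValueError("chain too short")
    chars = characters.copy()
    extra = set(chars.index) - set(tree.tip_names)
    if extra:
        raise ValueError(f"characters for unknown tips: {sorted(extra)}")
    if len(chars.index) < 4:
        raise ValueError("need character data for at least 4 tips")
    transforms = {**DEFAULT_TRANSFORMS, **(transforms or {})}
    char_names = list(chars.columns)
    for c in char_names:
        if transforms.get(c, "identity") == "log":
            vals = chars[c].astype(float)
            if (vals <= 0).any():
                raise ValueError(f"character {c} must be positive for log transform")
            chars[c] = np.log(vals)
    p = 1 + len(char_names)
    n = tree.n_nodes
    root = tree.root
    blen = np.maximum(tree.blen, 1e-8)

    obs = branch_log_omega.dropna(subset=["log_omega"])
    obs_child = obs["child"].to_numpy(int)
    obs_y = obs["log_omega"].to_numpy(float)
    obs_w = (obs["weight"].to_numpy(float)
             if "weight" in obs else np.ones(obs_y.size))
    obs_w = np.clip(obs_w / max(obs_w.mean(), 1e-12), 1e-3, None)
    if obs_y.size < 3:
        raise ValueError("need branch log omega on at least 3 branches")
    # per node: indices into obs arrays of observations on adjacent edges
    node_obs: list[list[int]] = [[] for _ in range(n)]
    for k, c in enumerate(obs_child):
        node_obs[c].append(k)
        node_obs[tree.parent[c]].append(k)

    # observed (clamped) coordinate masks at tips: characters only
    X = np.zeros((n, p))
    fixed = np.zeros((n, p), bool)
    col_means = np.nanmean(chars.to_numpy(float), axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    for v in range(n):
        X[v, 1:] = col_means
    X[:, 0] = obs_y.mean()
    for tipname, row in chars.iterrows():
        v = tree.tip_index[tipname]
        for j, c in enumerate(char_names):
            val = row[c]
            if np.isfinite(val):
                X[v, j + 1] = float(val)
                fixed[v, j + 1] = True

    nu0 = prior_df if prior_df is not None else p + 2
    Psi0 = np.eye(p) if prior_scale is None else np.asarray(prior_scale, float)
    if np.any(np.linalg.eigvalsh(Psi0) <= 0):
        raise ValueError("prior scale must be positive-definite")
    a0, b0 = noise_prior
    rng = np.random.default_rng(seed)

    Sigma = Psi0 / nu0 + np.eye(p) * 0.1
    s2 = 0.05
    edges = np.arange(n - 1)
    epar = tree.parent[edges]

    burn = int(n_iter * burnin_frac)
    keep = max((n_iter - burn) // thin, 1)
    sig_samples = np.empty((keep, p, p))
    noise_samples = np.empty(keep)
    kcount = 0

    order = [v for v in range(n) if not fixed[v].all()]
    latent_idx = {v: np.nonzero(~fixed[v])[0] for v in order}
    fixed_idx = {v: np.nonzero(fixed[v])[0] for v in order}
    inv_t = 1.0 / blen

    for it in range(n_iter):
        Lam0 = np.linalg.inv(Sigma)
        for v in order:
            a = 0.0
            h = np.zeros(p)
            if v != root:
                a += inv_t[v]
                h += inv_t[v] * X[tree.parent[v]]
            for c in tree.children[v]:
                a += inv_t[c]
                h += inv_t[c] * X[c]
            Lam = Lam0 * a
            h = Lam0 @ h
            for k in node_obs[v]:
                c = obs_child[k]
                other = tree.parent[c] if c == v else c
                pr = obs_w[k] / (4.0 * s2)
                Lam[0, 0] += pr
                h[0] += (obs_w[k] / (2.0 * s2)) * (obs_y[k] - 0.5 * X[other, 0])
            L = latent_idx[v]
            F = fixed_idx[v]
            hL = h[L]
            if F.size:
                hL = hL - Lam[np.ix_(L, F)] @ X[v, F]
            LamLL = Lam[np.ix_(L, L)]
            cf = np.linalg.cholesky(LamLL)
            mean = np.linalg.solve(LamLL, hL)
            z = rng.standard_normal(L.size)
            X[v, L] = mean + np.linalg.solve(cf.T, z)
        # covariance update
        D = (X[edges] - X[epar]) / np.sqrt(blen[edges])[:, None]
        S = Psi0 + D.T @ D
        Sigma = stats.invwishart.rvs(df=nu0 + edges.size, scale=S, random_state=rng)
        Sigma = np.atleast_2d(Sigma)
        # noise-scale update (conjugate inverse-gamma)
        resid = obs_y - 0.5 * (X[obs_child, 0] + X[tree.parent[obs_child], 0])
        shape = a0 + obs_y.size / 2.0
        rate = b0 + 0.5 * np.sum(obs_w * resid**2)
        s2 = max(rate / rng.gamma(shape), noise_floor)
        if it >= burn and (it - burn) % thin == 0 and kcount < keep:
            sig_samples[kcount] = Sigma
            noise_samples[kcount] = s2
            kcount += 1
    sig_samples = sig_samples[:kcount]
    noise_samples = noise_samples[:kcount]
    d = np.sqrt(np.einsum("sii->si", sig_samples))
    corr = sig_samples / (d[:, :, None] * d[:, None, :])
    pp = pd.Series(
        [(corr[:, 0, j + 1] > 0).mean() for j in range(p - 1)], index=char_names
    )
    mean_corr = pd.Series(corr[:, 0, 1:].mean(axis=0), index=char_names)
    ess = pd.Series(
        [_simple_ess(corr[:, 0, j + 1]) for j in range(p - 1)], index=char_names
    )
    post = CorrelationPosterior(
        char_names, sig_samples, corr, noise_samples, pp, mean_corr, ess
    )
    post.calls = pd.Series([classify_correlation(v) for v in pp], index=char_names)
    return post


def classify_correlation(pp: float, positive: float = POSITIVE_CUTOFF,
                         negative: float = NEGATIVE_CUTOFF) -> str:
    """Three-way call from the posterior probability of a positive
    correlation: ``positive`` (pp >= 0.975), ``negative`` (pp <= 0.025),
    else ``ns``."""
    if not 0 <= pp <= 1:
        raise ValueError("posterior probability must lie in [0, 1]")
    if pp >= positive:
        return "positive"
    if pp <= negative:
        return "negative"
    return "ns"
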