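"""Detection of positive selection with GY94 codon models.

Implements Felsenstein-pruning likelihoods for site-mixture codon models
(M0, M1a, M2a, M7, M8, M8a), likelihood-ratio tests between nested pairs,
Storey q-value FDR control, and the branch-site test of positive selection
on designated foreground lineages (here: multi-male mating lineages).

Fitting protocol: branch lengths come from an M0 fit (optionally
re-estimated branch by branch); the richer models share the M0 branch
lengths up to one re-optimized scale factor and the M0 kappa.  Mixture
parameters are optimized by bounded quasi-Newton from one or more starts;
when a nested pair is fitted through :func:`sites_lrt` or
:func:`branch_site_test`, the null solution seeds the alternative so the
alternative log-likelihood can never fall below the null beyond optimizer
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .alignment import CodonAlignment
from .codon import (
    N_STATES,
    Propagator,
    codon_rate_matrix,
    f3x4_frequencies,
    uniform_frequencies,
)
from .trees import Phylogeny

__all__ = [
    "SiteMixture",
    "site_mixture",
    "CodonLikelihood",
    "site_log_likelihood",
    "SiteModelFit",
    "fit_site_model",
    "site_model_lrt",
    "sites_lrt",
    "qvalue_fdr",
    "BranchSiteResult",
    "branch_site_test",
]

_MIN_BLEN = 1e-9


class ModelError(ValueError):
    pass


# --------------------------------------------------------------------------
# site mixtures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteMixture:
    """A discrete mixture of omega classes with weights summing to one."""

    name: str
    weights: np.ndarray
    omegas: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        o = np.asarray(self.omegas, float)
        if w.shape != o.shape or w.ndim != 1:
            raise ModelError("weights and omegas must be 1-d and the same length")
        if np.any(w < -1e-12) or not np.isclose(w.sum(), 1.0):
            raise ModelError("class weights must be non-negative and sum to 1")
        if np.any(o < 0):
            raise ModelError("omegas must be non-negative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "omegas", o)


def _beta_classes(p: float, q: float, K: int) -> np.ndarray:
    """K equal-probability beta classes at quantile midpoints."""
    probs = (2.0 * np.arange(K) + 1.0) / (2.0 * K)
    return stats.beta.ppf(probs, p, q)


_ALIASES = {"M1": "M1a", "M2": "M2a"}


def site_mixture(model: str, *, K: int = 10, **params) -> SiteMixture:
    """Construct the omega mixture of a named sites model.

    Parameters by model: M0 ``omega``; M1a ``p0, omega0``; M2a ``p0, p1,
    omega0, omega2``; M7 ``p, q``; M8 ``p0, p, q, omega_s``; M8a ``p0, p, q``
    (omega_s fixed at 1).
    """
    model = _ALIASES.get(model, model)
    try:
        if model == "M0":
            return SiteMixture("M0", np.array([1.0]), np.array([params["omega"]]))
        if model == "M1a":
            p0, w0 = params["p0"], params["omega0"]
            return SiteMixture("M1a", np.array([p0, 1 - p0]), np.array([w0, 1.0]))
        if model == "M2a":
            p0, p1 = params["p0"], params["p1"]
            return SiteMixture(
                "M2a",
                np.array([p0, p1, 1 - p0 - p1]),
                np.array([params["omega0"], 1.0, params["omega2"]]),
            )
        if model == "M7":
            w = _beta_classes(params["p"], params["q"], K)
            return SiteMixture("M7", np.full(K, 1.0 / K), w)
        if model in ("M8", "M8a"):
            p0 = params["p0"]
            omega_s = 1.0 if model == "M8a" else params["omega_s"]
            if omega_s < 1.0:
                raise ModelError("omega_s must be >= 1")
            w = _beta_classes(params["p"], params["q"], K)
            weights = np.append(np.full(K, p0 / K), 1.0 - p0)
            return SiteMixture(model, weights, np.append(w, omega_s))
    except KeyError as exc:
        raise ModelError(f"missing parameter {exc} for model {model}") from exc
    raise ModelError(f"unknown site model {model!r}")


# --------------------------------------------------------------------------
# pruning likelihood engine
# --------------------------------------------------------------------------


class CodonLikelihood:
    """Felsenstein-pruning log-likelihood for codon models on one alignment.

    Site patterns are compressed once at construction.  :meth:`lnl` accepts a
    per-class, per-branch omega table so the same engine serves site
    mixtures, the branch-site model, and one-omega-per-branch fits.  Gaps
    are treated as missing states.  Rate matrices are scaled so that one unit
    of branch length is one expected substitution per codon site at the
    mixture-mean rate.
    """

    def __init__(self, alignment: CodonAlignment, tree: Phylogeny, pi=None):
        missing = set(alignment.names) - set(tree.tip_names)
        if missing:
            raise ModelError(f"alignment names not in tree: {sorted(missing)}")
        self.tree = tree
        self.alignment = alignment
        rows = np.vstack([
            alignment.codon_idx[alignment.index[tree.names[v]]]
            for v in tree.tip_ids
        ])
        pat, counts = np.unique(rows, axis=1, return_counts=True)
        self.patterns = pat  # (n_tips, n_patterns), row order == tree.tip_ids
        self.counts = counts.astype(float)
        self.tip_row = {int(v): k for k, v in enumerate(tree.tip_ids)}
        if pi is None:
            pi = f3x4_frequencies(alignment.codon_idx)
        pi = np.clip(np.asarray(pi, float), 1e-10, None)
        self.pi = pi / pi.sum()
        self.n_codons = alignment.n_codons
        self.n_eval = 0

    # -- core ---------------------------------------------------------------
    def class_site_loglikes(
        self,
        kappa: float,
        omega_table: np.ndarray,
        blens: np.ndarray,
        rho=1.0,
    ) -> np.ndarray:
        """Per-class, per-pattern site log-likelihoods, shape (C, n_patterns).

        ``omega_table`` has shape (n_classes, n_nodes): the omega acting on
        the branch above each node, per class (root column ignored).
        ``blens`` are branch lengths on the unnormalized-generator time scale
        divided by ``rho`` (pass the mixture-mean rate per branch to make
        them expected substitutions per codon; see :meth:`lnl`).
        """
        self.n_eval += 1
        tree = self.tree
        C, n_nodes = omega_table.shape
        uniq, inv = np.unique(np.round(omega_table, 14), return_inverse=True)
        inv = inv.reshape(omega_table.shape)
        props = [Propagator(kappa, w, self.pi) for w in uniq]
        teff = np.maximum(np.asarray(blens, float), _MIN_BLEN)[None, :] / rho
        teff = np.broadcast_to(teff, (C, n_nodes))
        P = np.empty((C, n_nodes, N_STATES, N_STATES))
        for u, prop in enumerate(props):
            sel = np.nonzero(inv == u)
            if sel[0].size:
                P[sel] = prop.matrices(teff[sel])
        npat = self.patterns.shape[1]
        logscale = np.zeros((C, npat))
        partials: list[np.ndarray | None] = [None] * n_nodes
        for v in tree.internal_postorder:
            part = None
            for u in tree.children[v]:
                if not tree.children[u]:  # tip child: gather columns of P
                    cod = self.patterns[self.tip_row[u]]
                    contrib = P[:, u][:, :, np.clip(cod, 0, None)]
                    gap = cod < 0
                    if gap.any():
                        contrib[:, :, gap] = 1.0
                else:
                    contrib = P[:, u] @ partials[u]
                    partials[u] = None
                part = contrib if part is None else part * contrib
            m = part.max(axis=1)
            if (m <= 0).any():
                return np.full((C, npat), -np.inf)
            part /= m[:, None, :]
            logscale += np.log(m)
            partials[v] = part
        root_ll = np.log(np.einsum("i,cip->cp", self.pi, partials[tree.root]))
        return root_ll + logscale

    def mix_loglikes(self, weights: np.ndarray, class_ll: np.ndarray) -> float:
        """Total lnL from per-class site log-likelihoods and class weights."""
        mix = class_ll + np.log(np.clip(weights, 1e-300, None))[:, None]
        top = mix.max(axis=0)
        with np.errstate(invalid="ignore"):
            site_ll = top + np.log(np.exp(mix - top[None, :]).sum(axis=0))
        if not np.all(np.isfinite(site_ll)):
            return -np.inf
        return float(self.counts @ site_ll)

    def lnl(
        self,
        kappa: float,
        weights: np.ndarray,
        omega_table: np.ndarray,
        blens: np.ndarray,
    ) -> float:
        """Mixture log-likelihood with ``blens`` in expected substitutions
        per codon site at the mixture-mean rate (codeml convention)."""
        weights = np.asarray(weights, float)
        uniq, inv = np.unique(np.round(omega_table, 14), return_inverse=True)
        inv = inv.reshape(omega_table.shape)
        rates = np.array(
            [codon_rate_matrix(kappa, w, self.pi, normalize=False)[1]
             for w in uniq]
        )
        rho = weights @ rates[inv]  # mixture-mean rate per branch
        class_ll = self.class_site_loglikes(kappa, omega_table, blens, rho=rho)
        return self.mix_loglikes(weights, class_ll)

    def lnl_mixture(self, kappa, mixture: SiteMixture, blens) -> float:
        table = np.repeat(mixture.omegas[:, None], self.tree.n_nodes, axis=1)
        return self.lnl(kappa, mixture.weights, table, blens)


class _CachedClassLnl:
    """Memoized per-class site log-likelihoods for mixture optimization.

    The shared branch-scale parameter here is the *absolute* scale ``ls`` on
    the unnormalized-generator time axis; because the scale is freely
    optimized, this parameterization reaches exactly the same maximum
    likelihood as the mixture-mean-rate convention while making each class's
    site log-likelihood vector depend only on (class omegas, ls) — so
    forward-difference gradient steps that leave a class untouched reuse its
    cached vector.
    """

    def __init__(self, engine: CodonLikelihood, kappa: float, rel_blens,
                 fg_mask=None):
        self.engine = engine
        self.kappa = kappa
        self.rel = np.asarray(rel_blens, float)
        self.fg = fg_mask
        self.cache: dict = {}

    def _vectors(self, class_specs, ls: float):
        out = [None] * len(class_specs)
        missing = []
        for i, spec in enumerate(class_specs):
            v = self.cache.get((spec, ls))
            if v is None:
                missing.append((i, spec))
            else:
                out[i] = v
        if missing:
            n = self.engine.tree.n_nodes
            table = np.empty((len(missing), n))
            for r, (_, (wbg, wfg)) in enumerate(missing):
                if self.fg is None or wbg == wfg:
                    table[r, :] = wbg
                else:
                    table[r, :] = np.where(self.fg, wfg, wbg)
            ll = self.engine.class_site_loglikes(
                self.kappa, table, self.rel * np.exp(ls)
            )
            for r, (i, spec) in enumerate(missing):
                self.cache[(spec, ls)] = ll[r]
                out[i] = ll[r]
        return np.vstack(out)

    def lnl(self, weights, class_specs, ls: float) -> float:
        return self.engine.mix_loglikes(
            np.asarray(weights, float), self._vectors(class_specs, float(ls))
        )

    def standard_scale(self, weights, class_specs, ls: float) -> float:
        """Convert the absolute scale into the mixture-mean-rate convention
        (branch lengths in expected substitutions per codon site)."""
        rates = {}
        rho = 0.0
        for w, (wbg, _) in zip(weights, class_specs):
            if wbg not in rates:
                rates[wbg] = codon_rate_matrix(
                    self.kappa, wbg, self.engine.pi, normalize=False
                )[1]
            rho += w * rates[wbg]
        return float(np.exp(ls) * rho)


def site_log_likelihood(
    alignment: CodonAlignment,
    tree: Phylogeny,
    mixture: SiteMixture,
    kappa: float = 2.0,
    pi=None,
    blens=None,
) -> float:
    """Log-likelihood of a codon alignment under a site mixture model."""
    engine = CodonLikelihood(alignment, tree, pi=pi)
    if blens is None:
        blens = tree.blen
    return engine.lnl_mixture(kappa, mixture, np.asarray(blens, float))


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------


@dataclass
class SiteModelFit:
    model: str
    lnl: float
    kappa: float
    scale: float
    params: dict
    mixture: SiteMixture
    blens: np.ndarray
    tree: Phylogeny
    converged: bool
    n_eval: int
    pi: np.ndarray = field(repr=False, default=None)

    @property
    def omega(self) -> float | None:
        """Point omega for M0; None for mixtures."""
        return self.params.get("omega")


def _minimize(fun, x0, bounds, maxfun=300):
    # ftol 1e-8 relative stops once lnL moves by < ~1e-4: ample for LRTs,
    # which only need delta-lnL to ~1e-2
    res = optimize.minimize(
        fun,
        np.asarray(x0, float),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxfun": maxfun, "ftol": 1e-8, "gtol": 2e-5},
    )
    return res


def _fit_m0(
    engine: CodonLikelihood,
    blens0: np.ndarray,
    optimize_branch_lengths: bool,
    kappa0: float = 2.0,
    omega0: float = 0.4,
):
    """M0 fit: kappa, omega, a global scale, and optionally per-branch lengths
    by coordinate sweeps."""
    blens = np.maximum(np.asarray(blens0, float).copy(), 1e-4)
    state = {"kappa": kappa0, "omega": omega0}

    def obj(x):
        kappa, omega, s = np.exp(x)
        mix = site_mixture("M0", omega=omega)
        return -engine.lnl_mixture(kappa, mix, blens * s)

    best = np.inf
    converged = False
    for _ in range(4):
        res = _minimize(
            obj,
            np.log([state["kappa"], state["omega"], 1.0]),
            [(-2.5, 3.5), (-9.0, 3.5), (-5.0, 5.0)],
        )
        kappa, omega, s = np.exp(res.x)
        blens *= s
        state.update(kappa=kappa, omega=omega)
        improved = best - res.fun
        best = res.fun
        if optimize_branch_lengths:
            mix = site_mixture("M0", omega=omega)
            for b in range(engine.tree.n_nodes - 1):
                def obj_b(lt, b=b):
                    trial = blens.copy()
                    trial[b] = np.exp(lt)
                    return -engine.lnl_mixture(kappa, mix, trial)

                r = optimize.minimize_scalar(
                    obj_b,
                    bounds=(np.log(1e-8), np.log(8.0)),
                    method="bounded",
                    options={"xatol": 2e-3},
                )
                if r.fun < best:
                    blens[b] = np.exp(r.x)
                    best = r.fun
        if improved < 0.02 and _ > 0:
            converged = True
            break
    if not optimize_branch_lengths:
        converged = True
    return state["kappa"], state["omega"], blens, -best, converged


_MIXTURE_SPECS = {
    # name -> (param names, default init, bounds); "ls" = log scale factor
    "M1a": (["p0", "omega0"], [0.8, 0.2], [(1e-4, 1 - 1e-4), (1e-6, 1.0)]),
    "M2a": (
        ["pa", "pb", "omega0", "omega2"],
        [0.95, 0.85, 0.2, 2.0],
        [(1e-4, 1 - 1e-4), (1e-4, 1 - 1e-4), (1e-6, 1.0), (1.0, 50.0)],
    ),
    "M7": (["lp", "lq"], [0.0, 0.5], [(-5.3, 4.6), (-5.3, 4.6)]),
    "M8": (
        ["p0", "lp", "lq", "omega_s"],
        [0.9, 0.0, 0.5, 2.0],
        [(1e-4, 1 - 1e-4), (-5.3, 4.6), (-5.3, 4.6), (1.0, 50.0)],
    ),
    "M8a": (
        ["p0", "lp", "lq"],
        [0.9, 0.0, 0.5],
        [(1e-4, 1 - 1e-4), (-5.3, 4.6), (-5.3, 4.6)],
    ),
}


def _mixture_from_vector(model: str, x: np.ndarray, K: int) -> tuple[SiteMixture, dict]:
    names = _MIXTURE_SPECS[model][0]
    v = dict(zip(names, x))
    if model == "M1a":
        params = {"p0": v["p0"], "omega0": v["omega0"]}
    elif model == "M2a":
        params = {
            "p0": v["pa"] * v["pb"],
            "p1": v["pa"] * (1 - v["pb"]),
            "omega0": v["omega0"],
            "omega2": v["omega2"],
        }
    elif model == "M7":
        params = {"p": np.exp(v["lp"]), "q": np.exp(v["lq"])}
    elif model == "M8":
        params = {
            "p0": v["p0"],
            "p": np.exp(v["lp"]),
            "q": np.exp(v["lq"]),
            "omega_s": v["omega_s"],
        }
    elif model == "M8a":
        params = {"p0": v["p0"], "p": np.exp(v["lp"]), "q": np.exp(v["lq"])}
    else:  # pragma: no cover
        raise ModelError(model)
    return site_mixture(model, K=K, **params), params


def _vector_from_params(model: str, params: dict) -> np.ndarray:
    if model == "M1a":
        return np.array([params["p0"], params["omega0"]])
    if model == "M2a":
        pa = params["p0"] + params["p1"]
        pb = params["p0"] / pa if pa > 0 else 0.5
        return np.array([pa, pb, params["omega0"], params["omega2"]])
    if model == "M7":
        return np.log([params["p"], params["q"]])
    if model == "M8":
        return np.array(
            [params["p0"], np.log(params["p"]), np.log(params["q"]), params["omega_s"]]
        )
    if model == "M8a":
        return np.array([params["p0"], np.log(params["p"]), np.log(params["q"])])
    raise ModelError(model)


def fit_site_model(
    alignment: CodonAlignment,
    tree: Phylogeny,
    model: str,
    *,
    K: int = 10,
    pi=None,
    base: SiteModelFit | None = None,
    optimize_branch_lengths: bool | None = None,
    n_starts: int = 2,
    seed: int = 0,
    init_params: dict | None = None,
    engine: CodonLikelihood | None = None,
) -> SiteModelFit:
    """Maximum-likelihood fit of a sites model.

    For M0, kappa / omega / branch scale are optimized jointly; individual
    branch lengths are re-estimated by coordinate sweeps when
    ``optimize_branch_lengths`` is True (default: only when the input tree
    carries no usable branch lengths).  Mixture models require an M0 ``base``
    fit (computed on demand): kappa and relative branch lengths are inherited
    and one shared scale is re-optimized together with the mixture
    parameters, from ``n_starts`` jittered starts; the best start is kept.
    ``init_params`` seeds the first start (used to nest null inside
    alternative fits).
    """
    model = _ALIASES.get(model, model)
    if engine is None:
        engine = CodonLikelihood(alignment, tree, pi=pi)
    engine.n_eval = 0
    if model == "M0":
        blens0 = tree.blen.copy()
        has_lengths = np.any(blens0[: tree.root] > 0)
        if optimize_branch_lengths is None:
            optimize_branch_lengths = not has_lengths
        if not has_lengths:
            blens0 = np.full(tree.n_nodes, 0.05)
        kappa, omega, blens, lnl, converged = _fit_m0(
            engine, blens0, optimize_branch_lengths
        )
        mix = site_mixture("M0", omega=omega)
        return SiteModelFit(
            "M0", lnl, kappa, 1.0, {"omega": omega}, mix, blens,
            tree.with_branch_lengths(blens), converged, engine.n_eval, engine.pi,
        )

    if model not in _MIXTURE_SPECS:
        raise ModelError(f"unknown site model {model!r}")
    if base is None:
        base = fit_site_model(
            alignment, tree, "M0", pi=pi, engine=engine,
            optimize_branch_lengths=optimize_branch_lengths,
        )
        engine.n_eval = 0
    kappa = base.kappa
    rel_blens = base.blens
    cached = _CachedClassLnl(engine, kappa, rel_blens)
    # absolute scale that reproduces the M0 branch lengths
    r0 = codon_rate_matrix(kappa, base.params.get("omega", 0.4),
                           engine.pi, normalize=False)[1]
    ls0 = -np.log(r0)

    names, default_init, bounds = _MIXTURE_SPECS[model]
    bounds = list(bounds) + [(ls0 - 4.0, ls0 + 4.0)]

    def obj(x):
        try:
            mix, _ = _mixture_from_vector(model, x[:-1], K)
        except ModelError:
            return 1e12  # infeasible corner of the box (e.g. p0 + p1 > 1)
        specs = tuple((float(w), float(w)) for w in np.round(mix.omegas, 14))
        val = -cached.lnl(mix.weights, specs, x[-1])
        return val if np.isfinite(val) else 1e12

    starts = []
    if init_params is not None:
        ls_init = float(init_params.get("_ls", ls0))
        starts.append(np.append(_vector_from_params(model, init_params), ls_init))
    starts.append(np.append(np.asarray(default_init, float), ls0))
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        jit = starts[-1].copy()
        for i, (lo, hi) in enumerate(bounds):
            jit[i] = np.clip(jit[i] + rng.normal(0, 0.3 * (hi - lo) / 8), lo, hi)
        starts.append(jit)

    best = None
    for x0 in starts[:max(n_starts, len(starts))]:
        res = _minimize(obj, x0, bounds)
        if best is None or res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-9
            and np.linalg.norm(res.x) < np.linalg.norm(best.x)
        ):
            best = res
    mix, params = _mixture_from_vector(model, best.x[:-1], K)
    specs = tuple((float(w), float(w)) for w in np.round(mix.omegas, 14))
    scale = cached.standard_scale(mix.weights, specs, best.x[-1])
    params["_ls"] = float(best.x[-1])
    blens = rel_blens * scale
    return SiteModelFit(
        model, -float(best.fun), kappa, scale, params, mix, blens,
        tree.with_branch_lengths(blens), bool(best.success), engine.n_eval,
        engine.pi,
    )


_NESTED_DF = {("M1a", "M2a"): 2, ("M7", "M8"): 2, ("M8a", "M8"): 1}


def site_model_lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit) -> dict:
    """Chi-squared LRT p-value for a nested model pair.

    2*delta-lnL is clamped at zero.  The chi-squared degrees of freedom is
    the difference in free parameters (M8a-M8 uses plain chi2 with df 1,
    which is conservative at the omega_s = 1 boundary).
    """
    pair = (null_fit.model, alt_fit.model)
    if pair not in _NESTED_DF:
        raise ModelError(f"{pair} is not a supported nested pair")
    df = _NESTED_DF[pair]
    stat = max(0.0, 2.0 * (alt_fit.lnl - null_fit.lnl))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return {"null": pair[0], "alt": pair[1], "stat": stat, "df": df, "p": p}


def sites_lrt(
    alignment: CodonAlignment,
    tree: Phylogeny,
    pair: tuple[str, str] = ("M8a", "M8"),
    *,
    K: int = 10,
    pi=None,
    base: SiteModelFit | None = None,
    n_starts: int = 2,
    seed: int = 0,
) -> dict:
    """Fit a nested sites-model pair and return fits plus the LRT.

    The alternative fit is seeded with the null solution (plus dedicated
    starts for the positive-selection class), which enforces the nesting
    inequality lnL(alt) >= lnL(null) up to optimizer tolerance.
    """
    null_name, alt_name = (_ALIASES.get(m, m) for m in pair)
    engine = CodonLikelihood(alignment, tree, pi=pi)
    if base is None:
        base = fit_site_model(alignment, tree, "M0", pi=pi, engine=engine)
    null_fit = fit_site_model(
        alignment, tree, null_name, K=K, base=base, n_starts=n_starts,
        seed=seed, engine=engine,
    )
    init = dict(null_fit.params)
    if alt_name == "M8":
        init.setdefault("omega_s", 1.0 + 1e-6)
    if alt_name == "M2a" and null_fit.model == "M1a":
        init = {
            "p0": init["p0"] * (1 - 1e-4),
            "p1": (1 - init["p0"]) * (1 - 1e-4),
            "omega0": init["omega0"],
            "omega2": 1.0 + 1e-6,
        }
    alt_fit = fit_site_model(
        alignment, tree, alt_name, K=K, base=base, n_starts=max(n_starts, 2),
        seed=seed + 1, init_params=init, engine=engine,
    )
    if alt_fit.lnl < null_fit.lnl:
        alt_fit.lnl = null_fit.lnl  # boundary solution: alt includes the null
    lrt = site_model_lrt(null_fit, alt_fit)
    return {"base": base, "null_fit": null_fit, "alt_fit": alt_fit, **lrt}


# --------------------------------------------------------------------------
# q-values
# --------------------------------------------------------------------------


def qvalue_fdr(pvals, *, threshold: float = 0.01, pi0: float | None = None):
    """Storey q-values with an FDR significance call.

    ``pi0`` (fraction of true nulls) is estimated on a lambda grid when at
    least 100 p-values are supplied; otherwise (or when the estimate is
    unstable) pi0 falls back to 1, which reduces to Benjamini-Hochberg.
    Returns ``(qvals, significant_mask)``.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.array([]), np.array([], bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m >= 100:
            lambdas = np.arange(0.05, 0.96, 0.05)
            est = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
            pi0 = float(np.mean(est[lambdas >= 0.5]))
            if not (0 < pi0 <= 1):
                pi0 = 1.0
        else:
            pi0 = 1.0
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0, 1)
    qvals = np.empty(m)
    qvals[order] = q
    return qvals, qvals < threshold


# --------------------------------------------------------------------------
# branch-site test
# --------------------------------------------------------------------------


@dataclass
class BranchSiteResult:
    foreground: list[str]
    null_lnl: float
    alt_lnl: float
    stat: float
    p: float
    omega0: float
    omega2: float
    weights: np.ndarray
    kappa: float
    scale: float
    n_eval: int


def _branch_site_table(omega0: float, omega2: float, fg: np.ndarray) -> np.ndarray:
    """Omega table (4 classes x n_nodes) of branch-site model A.

    Classes: 0 purifying everywhere; 1 neutral everywhere; 2a purifying on
    background, omega2 on foreground; 2b neutral on background, omega2 on
    foreground.
    """
    n = fg.size
    table = np.empty((4, n))
    table[0, :] = omega0
    table[1, :] = 1.0
    table[2, :] = np.where(fg, omega2, omega0)
    table[3, :] = np.where(fg, omega2, 1.0)
    return table


def _branch_site_weights(a: float, b: float) -> np.ndarray:
    return np.array([a * b, a * (1 - b), (1 - a) * b, (1 - a) * (1 - b)])


def branch_site_test(
    alignment: CodonAlignment,
    tree: Phylogeny,
    *,
    foreground: str = "multi",
    pi=None,
    base: SiteModelFit | None = None,
    n_starts: int = 2,
    seed: int = 0,
) -> BranchSiteResult:
    """Branch-site test of positive selection on foreground lineages.

    Standard model A: the alternative allows a site class with omega2 >= 1 on
    the foreground branches; the null fixes omega2 = 1.  Foreground branches
    are those whose descendant tips all carry the ``foreground`` mating
    label.  p comes from chi-squared with 1 df on 2*delta-lnL (conservative
    at the boundary).  Swapping ``foreground="uni"`` provides the reversed
    control run.
    """
    fg = tree.foreground_mask(foreground)
    if not fg.any() or fg[np.arange(tree.n_nodes) != tree.root].all():
        raise ModelError("foreground/background partition must be non-trivial")
    engine = CodonLikelihood(alignment, tree, pi=pi)
    if base is None:
        base = fit_site_model(alignment, tree, "M0", pi=pi, engine=engine)
    kappa, rel_blens = base.kappa, base.blens
    engine.n_eval = 0
    cached = _CachedClassLnl(engine, kappa, rel_blens, fg_mask=fg)
    r0 = codon_rate_matrix(kappa, base.params.get("omega", 0.4),
                           engine.pi, normalize=False)[1]
    ls0 = -np.log(r0)

    def make_obj(fix_omega2: bool):
        def obj(x):
            omega0 = float(np.round(x[2], 14))
            omega2 = 1.0 if fix_omega2 else float(np.round(x[3], 14))
            w = _branch_site_weights(x[0], x[1])
            specs = ((omega0, omega0), (1.0, 1.0), (omega0, omega2),
                     (1.0, omega2))
            val = -cached.lnl(w, specs, x[-1])
            return val if np.isfinite(val) else 1e12

        return obj

    wb = [(1e-4, 1 - 1e-4), (1e-4, 1 - 1e-4), (1e-6, 1.0)]
    ls_bounds = (ls0 - 4.0, ls0 + 4.0)
    rng = np.random.default_rng(seed)

    def multi_start(obj, starts, bounds):
        best = None
        for x0 in starts:
            res = _minimize(obj, x0, bounds)
            if best is None or res.fun < best.fun:
                best = res
        return best

    null_starts = [np.array([0.85, 0.7, 0.15, ls0])]
    while len(null_starts) < n_starts:
        j = null_starts[0] + rng.normal(0, 0.08, 4)
        j[:3] = np.clip(j[:3], 1e-3, 1 - 1e-3)
        j[-1] = np.clip(j[-1], *ls_bounds)
        null_starts.append(j)
    null = multi_start(make_obj(True), null_starts, wb + [ls_bounds])

    na, nb, nw0 = null.x[0], null.x[1], null.x[2]
    alt_starts = [
        np.array([na, nb, nw0, 1.0 + 1e-6, null.x[-1]]),
        np.array([na, nb, nw0, 3.0, null.x[-1]]),
    ]
    while len(alt_starts) < n_starts + 1:
        j = alt_starts[1] + rng.normal(0, 0.08, 5)
        j[:3] = np.clip(j[:3], 1e-3, 1 - 1e-3)
        j[3] = np.clip(j[3], 1.0, 20.0)
        j[-1] = np.clip(j[-1], *ls_bounds)
        alt_starts.append(j)
    alt = multi_start(make_obj(False), alt_starts,
                      wb + [(1.0, 50.0), ls_bounds])

    null_lnl, alt_lnl = -float(null.fun), -float(alt.fun)
    if alt_lnl < null_lnl:
        alt_lnl = null_lnl
    stat = max(0.0, 2.0 * (alt_lnl - null_lnl))
    p = float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
    fg_names = [tree.node_label(v) for v in np.nonzero(fg)[0]]
    w_alt = _branch_site_weights(alt.x[0], alt.x[1])
    specs_alt = ((float(alt.x[2]),) * 2, (1.0, 1.0),
                 (float(alt.x[2]), float(alt.x[3])), (1.0, float(alt.x[3])))
    scale = cached.standard_scale(w_alt, specs_alt, alt.x[-1])
    return BranchSiteResult(
        fg_names, null_lnl, alt_lnl, stat, p,
        float(alt.x[2]), float(alt.x[3]), w_alt, kappa, scale, engine.n_eval,
    )
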