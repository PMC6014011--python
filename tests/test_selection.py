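import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm
from scipy.stats import chi2

from sfpevol.alignment import CodonAlignment
from sfpevol.codon import (
    CODONS,
    N_STATES,
    codon_rate_matrix,
    decode_codons,
    uniform_frequencies,
)
from sfpevol.selection import (
    BranchSiteResult,
    CodonLikelihood,
    ModelError,
    SiteModelFit,
    branch_site_test,
    fit_site_model,
    qvalue_fdr,
    site_log_likelihood,
    site_mixture,
    site_model_lrt,
    sites_lrt,
)
from sfpevol.synthetic import simulate_codon_alignment
from sfpevol.trees import Phylogeny

TOPOLOGIES = [
    "(A:{a},B:{b});",
    "((A:{a},B:{b}):{c},C:{d});",
    "((A:{a},B:{b}):{c},(C:{d},D:{e}):{f});",
    "(((A:{a},B:{b}):{c},C:{d}):{e},D:{f});",
]


def brute_force_lnl(aln, tree, kappa, mixture, pi, blens):
    """Oracle: sum over all internal-node state assignments via einsum on
    expm transition matrices (independent of the pruning/eigen path)."""
    letters = "abcdefghijkl"
    axis = {v: letters[i] for i, v in enumerate(tree.internal_postorder)}
    total = 0.0
    for s in range(aln.n_codons):
        site_like = 0.0
        for w, omega in zip(mixture.weights, mixture.omegas):
            Qs = {}
            operands, subs = [], []
            for v in range(tree.n_nodes - 1):
                key = round(float(omega), 12)
                if key not in Qs:
                    Q, _ = codon_rate_matrix(kappa, omega, pi)
                    Qs[key] = Q
                # scale so blens are expected substitutions at the mixture mean
                _, rates = zip(*[codon_rate_matrix(kappa, o, pi, normalize=False)
                                 for o in mixture.omegas])
                rho = float(np.dot(mixture.weights, rates))
                Qu, _ = codon_rate_matrix(kappa, omega, pi, normalize=False)
                P = expm(Qu * max(blens[v], 1e-9) / rho)
                par = axis[int(tree.parent[v])]
                if tree.children[v]:
                    operands.append(P)
                    subs.append(par + axis[v])
                else:
                    row = aln.index[tree.names[v]]
                    cod = aln.codon_idx[row, s]
                    vec = np.ones(N_STATES) if cod < 0 else P[:, cod]
                    operands.append(vec)
                    subs.append(par)
            operands.append(pi)
            subs.append(axis[tree.root])
            expr = ",".join(subs) + "->"
            site_like += w * float(np.einsum(expr, *operands))
        total += np.log(site_like)
    return total


@pytest.mark.parametrize("draw", range(10))
def test_pruning_matches_enumeration(draw):
    """Pruning lnL equals brute-force state enumeration on small trees."""
    rng = np.random.default_rng(draw)
    topo = TOPOLOGIES[draw % len(TOPOLOGIES)]
    lens = {k: rng.uniform(0.02, 0.6) for k in "abcdef"}
    tree = Phylogeny.from_newick(topo.format(**lens))
    pi = rng.dirichlet(np.ones(N_STATES) * 5)
    pi = np.clip(pi, 1e-6, None); pi /= pi.sum()
    kappa = rng.uniform(1.0, 4.0)
    if draw % 3 == 0:
        mix = site_mixture("M0", omega=rng.uniform(0.05, 2.0))
    else:
        mix = site_mixture("M1a", p0=rng.uniform(0.2, 0.9),
                           omega0=rng.uniform(0.01, 0.9))
    n_codons = int(rng.integers(1, 4))
    aln = simulate_codon_alignment(tree, mix, n_codons, seed=100 + draw,
                                   kappa=kappa, pi=pi)
    got = site_log_likelihood(aln, tree, mix, kappa=kappa, pi=pi)
    want = brute_force_lnl(aln, tree, kappa, mix, pi, tree.blen)
    assert got == pytest.approx(want, abs=1e-10)


def test_zero_length_star_tree_closed_form():
    """Identical sequences on a zero-length star tree: lnL = sum log pi."""
    tree = Phylogeny.from_newick("(A:0,B:0,C:0);")
    seq = "ATGAAATGC"
    aln = CodonAlignment.from_strings({n: seq for n in "ABC"})
    pi = uniform_frequencies()
    mix = site_mixture("M0", omega=0.5)
    lnl = site_log_likelihood(aln, tree, mix, kappa=2.0, pi=pi)
    from sfpevol.codon import CODON_INDEX

    want = sum(np.log(pi[CODON_INDEX[seq[i:i + 3]]]) for i in (0, 3, 6))
    assert lnl == pytest.approx(want, abs=1e-6)


def test_duplicating_sites_doubles_lnl(primate_tree, uniform_pi):
    aln = simulate_codon_alignment(primate_tree, "M0", 40, seed=7, omega=0.3)
    doubled = CodonAlignment(
        aln.names, np.concatenate([aln.codon_idx, aln.codon_idx], axis=1)
    )
    mix = site_mixture("M0", omega=0.3)
    l1 = site_log_likelihood(aln, primate_tree, mix, pi=uniform_pi)
    l2 = site_log_likelihood(doubled, primate_tree, mix, pi=uniform_pi)
    assert l2 == pytest.approx(2 * l1, rel=1e-12)


def test_likelihood_invariant_to_rerooting():
    """Same unrooted tree, two root placements: identical lnL (reversible)."""
    t1 = Phylogeny.from_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
    t2 = Phylogeny.from_newick("(A:0.4,(B:1,(C:1,D:1):1.0):0.6);")
    rng = np.random.default_rng(0)
    pi = rng.dirichlet(np.ones(N_STATES) * 10)
    aln = simulate_codon_alignment(t1, "M0", 30, seed=3, kappa=2.5, pi=pi,
                                   omega=0.7)
    mix = site_mixture("M0", omega=0.7)
    l1 = site_log_likelihood(aln, t1, mix, kappa=2.5, pi=pi)
    l2 = site_log_likelihood(aln, t2, mix, kappa=2.5, pi=pi)
    assert l1 == pytest.approx(l2, abs=1e-8)


def test_mixture_weights_validated():
    with pytest.raises(ModelError):
        site_mixture("M2a", p0=0.8, p1=0.5, omega0=0.1, omega2=2.0)
    with pytest.raises(ModelError):
        site_mixture("M9", omega=1.0)


class TestLRT:
    def _fit(self, model, lnl):
        return SiteModelFit(model, lnl, 2.0, 1.0, {}, site_mixture("M0", omega=1),
                            np.zeros(1), None, True, 0)

    def test_zero_delta_gives_p_one(self):
        r = site_model_lrt(self._fit("M8a", -100.0), self._fit("M8", -100.0))
        assert r["p"] == 1.0
        # negative delta (numerical wobble) clamps at zero
        r = site_model_lrt(self._fit("M8a", -100.0), self._fit("M8", -100.001))
        assert r["stat"] == 0.0 and r["p"] == 1.0

    def test_chi2_quantile(self):
        r = site_model_lrt(self._fit("M8a", -100.0),
                           self._fit("M8", -100.0 + 3.841 / 2))
        assert r["p"] == pytest.approx(0.05, abs=2e-4)
        assert r["df"] == 1

    def test_m7_m8_df_two(self):
        r = site_model_lrt(self._fit("M7", -50.0), self._fit("M8", -45.0))
        assert r["df"] == 2
        assert r["p"] == pytest.approx(chi2.sf(10.0, 2))

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ModelError):
            site_model_lrt(self._fit("M8", -50.0), self._fit("M7", -45.0))


class TestQvalues:
    def test_all_ones(self):
        q, sig = qvalue_fdr([1.0, 1.0, 1.0])
        assert np.all(q == 1.0) and not sig.any()

    def test_bh_hand_computation(self):
        q, sig = qvalue_fdr([0.001, 0.5, 0.9], pi0=1.0)
        assert np.allclose(q, [0.003, 0.75, 0.9])
        assert list(sig) == [True, False, False]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_monotone_in_p(self, pvals):
        q, _ = qvalue_fdr(pvals, pi0=1.0)
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            qvalue_fdr([0.5, 1.5])


def test_m8a_lnl_never_exceeds_m8(primate_tree, uniform_pi):
    """Nesting: the M8 fit is at least as good as the M8a fit."""
    aln = simulate_codon_alignment(primate_tree, "M8a", 120, seed=5,
                                   p0=0.9, p=2.0, q=5.0)
    r = sites_lrt(aln, primate_tree, ("M8a", "M8"), pi=uniform_pi)
    assert r["alt_fit"].lnl >= r["null_fit"].lnl
    assert 0 <= r["p"] <= 1


def test_m0_fit_with_branch_length_optimization():
    """Full M0 optimization on a 4-taxon tree recovers omega and lengths."""
    tree = Phylogeny.from_newick("((A:0.15,B:0.2):0.1,(C:0.25,D:0.1):0.1);")
    aln = simulate_codon_alignment(tree, "M0", 400, seed=9, omega=0.4, kappa=2.0)
    # fit from a tree stripped of branch-length information
    bare = tree.with_branch_lengths(np.zeros(tree.n_nodes))
    fit = fit_site_model(aln, bare, "M0", pi=uniform_frequencies())
    assert fit.omega == pytest.approx(0.4, rel=0.35)
    assert fit.blens[: tree.root].sum() == pytest.approx(
        tree.blen[: tree.root].sum(), rel=0.35
    )


def test_branch_site_partition_errors(uniform_pi):
    from sfpevol.trees import MULTI

    mating = {n: MULTI for n in "ABCD"}
    tree = Phylogeny.from_newick("((A:.1,B:.1):.1,(C:.1,D:.1):.1);",
                                 mating=mating)
    aln = simulate_codon_alignment(tree, "M0", 20, seed=1, omega=0.5)
    with pytest.raises(ModelError, match="partition"):
        branch_site_test(aln, tree, foreground="multi", pi=uniform_pi)


def test_branch_site_alt_at_least_null(primate_tree, uniform_pi):
    aln = simulate_codon_alignment(primate_tree, "M0", 100, seed=21, omega=0.4)
    b = branch_site_test(aln, primate_tree, foreground="multi", pi=uniform_pi)
    assert b.alt_lnl >= b.null_lnl
    assert 0 <= b.p <= 1
    assert b.omega2 >= 1.0
    # foreground and background partition the non-root branches
    fg = primate_tree.foreground_mask("multi")
    assert 0 < fg.sum() < primate_tree.n_nodes - 1
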