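"""Tree-mixture (MAST) fitting: reductions, identifiability, posteriors."""
import warnings

import numpy as np
import pytest

from phylomix.fitting import optimize_model
from phylomix.mast import fit_mast, site_assignments
from phylomix.selection import information_criteria
from phylomix.simulate import SimulationConfig, simulate
from phylomix.submodels import MixtureModel, jc
from phylomix.trees import parse_newick, random_tree


def _set_lengths(tree, internal=0.3, terminal=0.1):
    for e in tree.edges():
        e.length = terminal if e.is_leaf else internal
    return tree


@pytest.fixture(scope="module")
def two_topologies():
    rng = np.random.default_rng(77)
    taxa = [f"x{i}" for i in range(6)]
    T1 = _set_lengths(random_tree(taxa, rng, (0.1, 0.3)))
    T2 = _set_lengths(T1.nni_neighbors(T1.nni_edges()[0])[0])
    return T1, T2


def test_single_topology_reduces_to_plain_fit(two_topologies):
    T1, _ = two_topologies
    aln = simulate(SimulationConfig(T1, MixtureModel.single(jc()), 2000,
                                    seed=1))
    fit = fit_mast(aln, [T1], "JC", tol=1e-4)
    direct = optimize_model(T1, aln, "JC", tol=1e-4)
    assert fit.tree_weights.tolist() == [1.0]
    assert fit.lnl == pytest.approx(direct.lnl, abs=1e-4)


def test_identical_topologies_flagged_unidentifiable(two_topologies):
    T1, _ = two_topologies
    aln = simulate(SimulationConfig(T1, MixtureModel.single(jc()), 1500,
                                    seed=2))
    direct = optimize_model(T1, aln, "JC", tol=1e-4)
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        fit = fit_mast(aln, [T1, parse_newick(T1.to_newick())], "JC",
                       tol=1e-3, max_rounds=30)
    assert fit.unidentifiable_groups == [[0, 1]]
    assert any("isomorphic" in str(w.message) for w in rec)
    assert fit.tree_weights.sum() == pytest.approx(1.0)
    # a mixture is never worse than its best component
    assert fit.lnl >= direct.lnl - 1e-6


def test_weight_recovery_and_monotone_trace(two_topologies):
    T1, T2 = two_topologies
    a1 = simulate(SimulationConfig(T1, MixtureModel.single(jc()), 3500,
                                   seed=3))
    a2 = simulate(SimulationConfig(T2, MixtureModel.single(jc()), 1500,
                                   seed=4))
    aln = a1.concat(a2.subset_taxa(a1.taxa))
    fit = fit_mast(aln, [T1, T2], "JC", tol=1e-3, max_rounds=25)
    assert 0.6 <= fit.tree_weights[0] <= 0.8
    assert all(b >= a - 1e-8 for a, b in zip(fit.trace, fit.trace[1:]))
    post = site_assignments(fit)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)
    frac = (post[:3500].argmax(axis=1) == 0).mean()
    assert frac >= 0.7


def test_constant_site_posterior_equals_weights(two_topologies):
    T1, T2 = two_topologies
    a1 = simulate(SimulationConfig(T1, MixtureModel.single(jc()), 2800,
                                   seed=5))
    a2 = simulate(SimulationConfig(T2, MixtureModel.single(jc()), 1200,
                                   seed=6))
    aln = a1.concat(a2.subset_taxa(a1.taxa))
    fit = fit_mast(aln, [T1, T2], "JC", tol=1e-3, max_rounds=15)
    constant = np.nonzero((aln.data == aln.data[0]).all(axis=0))[0]
    post = site_assignments(fit)
    # equal branch lengths would give exactly lambda; fitted lengths
    # differ slightly, so allow a loose band around lambda
    assert np.allclose(post[constant, 0], fit.tree_weights[0], atol=0.12)


def test_synapomorphy_site_assigned_to_its_tree(two_topologies):
    """A site with a clean shared state on one side of T1's extra split
    is assigned to T1 by posterior argmax."""
    T1, T2 = two_topologies
    a1 = simulate(SimulationConfig(T1, MixtureModel.single(jc()), 3000,
                                   seed=7))
    a2 = simulate(SimulationConfig(T2, MixtureModel.single(jc()), 1000,
                                   seed=8))
    aln = a1.concat(a2.subset_taxa(a1.taxa))
    # find the split in T1 absent from T2 and build the synapomorphy
    split = next(iter(T1.splits() - T2.splits()))
    side = min(split, key=len)
    col = np.array(["A" if t in side else "C" for t in aln.taxa])
    aln.data[:, 0] = col
    fit = fit_mast(aln, [T1, T2], "JC", tol=1e-3, max_rounds=15)
    post = site_assignments(fit)
    assert post[0].argmax() == 0


def test_missing_taxon_errors(two_topologies):
    T1, _ = two_topologies
    aln = simulate(SimulationConfig(T1, MixtureModel.single(jc()), 100,
                                    seed=9))
    small = parse_newick("(x0:1,x1:1,x2:1);")
    with pytest.raises(ValueError, match="missing taxon"):
        fit_mast(aln, [small], "JC")


def test_ghost_branch_length_mixture_improves_bic(two_topologies):
    """Two length classes on one topology: the 2-component fit with
    unlinked lengths (GHOST) beats the single-tree BIC."""
    T1, _ = two_topologies
    slow, _ = T1.copy()
    fast, _ = T1.copy()
    for e in fast.edges():
        e.length = e.length * 4.0
    a1 = simulate(SimulationConfig(slow, MixtureModel.single(jc()), 3000,
                                   seed=10))
    a2 = simulate(SimulationConfig(fast, MixtureModel.single(jc()), 3000,
                                   seed=11))
    aln = a1.concat(a2.subset_taxa(a1.taxa))
    single = optimize_model(T1, aln, "JC", tol=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ghost = fit_mast(aln, [T1, parse_newick(T1.to_newick())], "JC",
                         tol=1e-3, max_rounds=30)
    n = aln.n_sites
    bic1 = information_criteria(single.lnl, single.n_free_params, n).bic
    bic2 = information_criteria(ghost.lnl, ghost.n_free_params, n).bic
    assert bic2 < bic1
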