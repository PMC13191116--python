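"""Pruning likelihoods against the brute-force oracle and structural
invariants (pattern compression, pulley principle, partitions)."""
import numpy as np
import pytest

from phylomix.alignment import Alignment, compress_patterns
from phylomix.likelihood import log_likelihood, site_log_likelihoods
from phylomix.ratedist import discrete_gamma_rates
from phylomix.submodels import MixtureModel, gtr, hky, jc, unrest
from phylomix.trees import parse_newick, random_tree

from conftest import brute_force_lnl, random_alignment


def test_zero_branch_identical_sequences():
    t = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
    aln = Alignment(list("ABCD"), np.array([list("ACGT")] * 4))
    lnl = log_likelihood(t, aln, MixtureModel.single(jc()))
    assert lnl == pytest.approx(4 * np.log(0.25), abs=1e-12)


def _random_mixture(rng, which):
    if which == 0:
        return MixtureModel.single(jc())
    if which == 1:
        return MixtureModel.single(
            hky(float(rng.uniform(1, 6)), rng.dirichlet(np.ones(4) * 4)))
    if which == 2:
        return MixtureModel.single(
            gtr(rng.uniform(0.3, 3, 6), rng.dirichlet(np.ones(4) * 4)),
            discrete_gamma_rates(float(rng.uniform(0.3, 2)), 3))
    return MixtureModel(
        [(jc(), None),
         (hky(float(rng.uniform(1, 5))), discrete_gamma_rates(1.0, 2))],
        rng.dirichlet(np.ones(2) * 2))


def test_pruning_matches_brute_force(rng):
    """30 random small instances; the acceptance suite runs 200."""
    for trial in range(30):
        n_taxa = int(rng.integers(3, 6))
        taxa = [chr(65 + i) for i in range(n_taxa)]
        tree = random_tree(taxa, rng, (0.02, 0.9))
        aln = random_alignment(rng, taxa, int(rng.integers(2, 12)))
        mix = _random_mixture(rng, trial % 4)
        a = log_likelihood(tree, aln, mix)
        b = brute_force_lnl(tree, aln, mix)
        assert a == pytest.approx(b, abs=1e-10)


def test_degenerate_mixture_weight_equals_single_class(rng):
    taxa = list("ABCDE")
    tree = random_tree(taxa, rng)
    aln = random_alignment(rng, taxa, 40)
    single = MixtureModel.single(hky(3.0))
    degen = MixtureModel([(hky(3.0), None), (gtr(np.ones(6), [0.25] * 4), None)],
                         [1.0, 0.0])
    assert log_likelihood(tree, aln, degen) == \
        pytest.approx(log_likelihood(tree, aln, single), abs=1e-12)


def test_pattern_compression_invariance(rng):
    taxa = list("ABCDEF")
    tree = random_tree(taxa, rng)
    aln = random_alignment(rng, taxa, 300)
    mix = MixtureModel.single(hky(2.0, rng.dirichlet(np.ones(4) * 5)),
                              discrete_gamma_rates(0.8, 4))
    pal = compress_patterns(aln)
    assert log_likelihood(tree, pal, mix) == \
        pytest.approx(log_likelihood(tree, aln, mix), abs=1e-10)


def test_pulley_principle_reversible(rng):
    tree = random_tree(list("ABCDEFG"), rng)
    aln = random_alignment(rng, list("ABCDEFG"), 60)
    mix = MixtureModel.single(gtr(rng.uniform(0.3, 3, 6),
                                  rng.dirichlet(np.ones(4) * 5)))
    base = log_likelihood(tree, aln, mix)
    for e in tree.edges():
        assert log_likelihood(tree.reroot_on_edge(e.uid), aln, mix) == \
            pytest.approx(base, abs=1e-8)


def test_nonreversible_root_dependence(rng):
    tree = random_tree(list("ABCDE"), rng)
    aln = random_alignment(rng, list("ABCDE"), 80)
    mix = MixtureModel.single(unrest(np.array(
        [3.0, 0.5, 0.2, 0.2, 3.0, 0.5, 0.5, 0.2, 3.0, 3.0, 0.5, 0.2])))
    vals = [log_likelihood(tree.reroot_on_edge(e.uid), aln, mix)
            for e in tree.edges()]
    assert max(vals) - min(vals) > 1e-3


def test_partitioned_lnl_is_sum_of_parts(rng):
    taxa = list("ABCD")
    tree = random_tree(taxa, rng)
    aln = random_alignment(rng, taxa, 100)
    m1 = MixtureModel.single(hky(2.0))
    m2 = MixtureModel.single(hky(5.0))
    part1 = aln.subset_sites(np.arange(0, 60))
    part2 = aln.subset_sites(np.arange(60, 100))
    total = log_likelihood(tree, part1, m1) + log_likelihood(tree, part2, m2)
    manual = (site_log_likelihoods(tree, aln, m1).site_lnl()[:60].sum()
              + site_log_likelihoods(tree, aln, m2).site_lnl()[60:].sum())
    assert total == pytest.approx(manual, abs=1e-10)


def test_missing_taxon_error_names_it(rng):
    tree = random_tree(list("ABCD"), rng)
    aln = random_alignment(rng, list("ABCE"), 10)
    with pytest.raises(ValueError, match="'E'"):
        log_likelihood(tree, aln, MixtureModel.single(jc()))


def test_site_decomposition_consistency(rng):
    """Pattern log-likelihoods weighted by counts reproduce the total,
    and per-site class posteriors sum to one."""
    taxa = list("ABCDE")
    tree = random_tree(taxa, rng)
    aln = random_alignment(rng, taxa, 150)
    mix = MixtureModel([(jc(), None), (hky(4.0), discrete_gamma_rates(0.6, 3))],
                       [0.4, 0.6])
    sl = site_log_likelihoods(tree, aln, mix)
    assert float(sl.weights @ sl.pattern_lnl) == pytest.approx(sl.total, abs=1e-8)
    assert sl.site_lnl().sum() == pytest.approx(sl.total, abs=1e-8)
    post = sl.class_posteriors()
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)


def test_many_taxa_scaling_stays_finite(rng):
    """Per-node rescaling keeps likelihoods finite on 200-taxon trees."""
    taxa = [f"t{i}" for i in range(200)]
    tree = random_tree(taxa, rng, (0.01, 0.2))
    aln = random_alignment(rng, taxa, 5)
    lnl = log_likelihood(tree, aln, MixtureModel.single(jc()))
    assert np.isfinite(lnl)
    assert lnl < 0
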