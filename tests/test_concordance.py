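"""Gene and site concordance factors on hand-built fixtures and
resampling properties."""
import numpy as np
import pytest

from phylomix.alignment import Alignment
from phylomix.concordance import (annotate_tree, gene_concordance,
                                  site_concordance_likelihood,
                                  site_concordance_parsimony)
from phylomix.trees import parse_newick, random_tree


REF6 = "((A:1,B:1):1,C:1,(D:1,E:1):1);"


def test_gcf_identical_gene_trees():
    ref = parse_newick("((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
    genes = [parse_newick(ref.to_newick()) for _ in range(10)]
    table = gene_concordance(ref, genes)
    assert (table.df["gCF"] == 100.0).all()
    assert (table.df["gN"] == 10).all()


def test_gcf_hand_fixture_counts():
    """6 concordant + 2 decisive-discordant + 2 non-decisive -> 75% of 8."""
    ref = parse_newick(REF6)
    conc = parse_newick(REF6)
    disc = parse_newick("((A:1,C:1):1,B:1,(D:1,E:1):1);")
    nodec = parse_newick("(A:1,D:1,E:1);")  # lacks B and C entirely
    genes = ([parse_newick(conc.to_newick()) for _ in range(6)]
             + [parse_newick(disc.to_newick()) for _ in range(2)]
             + [parse_newick(nodec.to_newick()) for _ in range(2)])
    row = gene_concordance(ref, genes).row("A|B")
    assert row["gCF"] == pytest.approx(75.0)
    assert row["gCF_N"] == 6
    assert row["gN"] == 8
    assert row["gDF1"] + row["gDF2"] == pytest.approx(25.0)


def test_gcf_row_sums_and_order_invariance(rng):
    ref = random_tree([f"t{i}" for i in range(7)], rng, (0.1, 0.3))
    genes = []
    for i in range(12):
        g, _ = ref.copy()
        if i % 3 == 0:
            uid = g.nni_edges()[int(rng.integers(len(g.nni_edges())))]
            g = g.nni_neighbors(uid)[int(rng.integers(2))]
        genes.append(g)
    t1 = gene_concordance(ref, genes)
    sums = t1.df[["gCF", "gDF1", "gDF2", "gDFP"]].sum(axis=1)
    assert np.allclose(sums.dropna(), 100.0, atol=0.01)
    perm = [genes[i] for i in rng.permutation(len(genes))]
    t2 = gene_concordance(ref, perm)
    merged = t1.df.set_index("branch_id").join(
        t2.df.set_index("branch_id"), rsuffix="_p")
    assert np.allclose(merged["gCF"].fillna(-1), merged["gCF_p"].fillna(-1))


def test_gcf_estimates_resampling_probability(rng):
    """Gene trees that keep the reference branch with probability q give
    gCF ~ 100q on that branch (binomial error, 200 trees)."""
    q = 0.7
    ref = parse_newick(REF6)
    clades = ref.clades()
    uid = next(u for u in ref.nni_edges()
               if clades[u] == frozenset("AB"))
    alts = ref.nni_neighbors(uid)
    genes = []
    for _ in range(200):
        if rng.random() < q:
            genes.append(parse_newick(ref.to_newick()))
        else:
            genes.append(parse_newick(alts[int(rng.integers(2))].to_newick()))
    row = gene_concordance(ref, genes).row("A|B")
    se = 100 * np.sqrt(q * (1 - q) / 200)
    assert abs(row["gCF"] - 100 * q) < 3 * se


def test_scf_hand_counts():
    ref = parse_newick("((A:1,B:1):1,C:1,D:1);")
    data = np.array([
        list("AAAAAAAA"),
        list("AAAAAACC"),
        list("CCCCCCAC"),
        list("CCCCCCCA"),
    ])
    aln = Alignment(list("ABCD"), data)
    row = site_concordance_parsimony(ref, aln, n_quartets=3, seed=0).row("A|B")
    assert row["sCF"] == pytest.approx(75.0)
    assert row["sDF1"] == pytest.approx(12.5)
    assert row["sDF2"] == pytest.approx(12.5)
    assert row["sN"] == pytest.approx(8.0)


def test_scf_constant_alignment_is_na():
    ref = parse_newick("((A:1,B:1):1,C:1,D:1);")
    aln = Alignment(list("ABCD"), np.array([list("AAAA")] * 4))
    row = site_concordance_parsimony(ref, aln, 3, 0).row("A|B")
    assert np.isnan(row["sCF"])


def test_scf_ambiguity_makes_site_nondecisive():
    ref = parse_newick("((A:1,B:1):1,C:1,D:1);")
    aln = Alignment(list("ABCD"), np.array([
        list("AN"), list("AA"), list("CC"), list("CC")]))
    row = site_concordance_parsimony(ref, aln, 2, 0).row("A|B")
    assert row["sN"] == pytest.approx(1.0)  # only the unambiguous site


def test_scf_seed_determinism(rng):
    ref = random_tree([f"s{i}" for i in range(6)], rng, (0.1, 0.3))
    aln = Alignment([f"s{i}" for i in range(6)],
                    rng.choice(list("ACGT"), size=(6, 200)))
    t1 = site_concordance_parsimony(ref, aln, 20, seed=5)
    t2 = site_concordance_parsimony(ref, aln, 20, seed=5)
    assert t1.df.equals(t2.df)


def test_scf_sampled_equals_exhaustive_when_single_choice():
    """With one leaf per adjacent clade every sample is the same quartet,
    so sampling and exhaustive averaging coincide."""
    ref = parse_newick("((A:1,B:1):1,C:1,D:1);")
    rngl = np.random.default_rng(1)
    aln = Alignment(list("ABCD"), rngl.choice(list("ACGT"), size=(4, 300)))
    sampled = site_concordance_parsimony(ref, aln, n_quartets=7, seed=3)
    exact = site_concordance_parsimony(ref, aln, n_quartets=1, seed=0,
                                       exhaustive=True)
    assert sampled.row("A|B")["sCF"] == pytest.approx(exact.row("A|B")["sCF"])


def test_scf_likelihood_agrees_on_clean_22_patterns():
    ref = parse_newick("((A:1,B:1):1,C:1,D:1);")
    data = np.array([
        list("AAAAAAAA"),
        list("AAAAAACC"),
        list("CCCCCCAC"),
        list("CCCCCCCA"),
    ])
    aln = Alignment(list("ABCD"), data)
    pars = site_concordance_parsimony(ref, aln, 2, seed=0).row("A|B")
    lik = site_concordance_likelihood(ref, aln, n_quartets=2, seed=0).row("A|B")
    assert lik["sCF_L"] == pytest.approx(pars["sCF"])
    assert lik["sN_L"] == pytest.approx(pars["sN"])  # constant sites tie out


def test_scf_row_sums(rng):
    ref = random_tree([f"q{i}" for i in range(6)], rng, (0.1, 0.4))
    aln = Alignment([f"q{i}" for i in range(6)],
                    rng.choice(list("ACGT"), size=(6, 500)))
    table = site_concordance_parsimony(ref, aln, 30, seed=2)
    sums = table.df[["sCF", "sDF1", "sDF2"]].sum(axis=1)
    assert np.allclose(sums.dropna(), 100.0, atol=0.01)


def test_annotated_tree_labels(rng):
    ref = parse_newick(REF6)
    genes = [parse_newick(REF6) for _ in range(4)]
    table = gene_concordance(ref, genes)
    annotated = annotate_tree(ref, table, ("gCF",))
    labels = [n.label for n in annotated.postorder()
              if not n.is_leaf and n.label]
    assert "100.0" in labels
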