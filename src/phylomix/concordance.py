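"""Gene and site concordance factors.

For every internal branch of a binary reference tree, the branch splits
the taxa into four adjacent clades A, B (below the branch's two child
subtrees) and C, D (the two subtrees on the parent side). Three
resolutions of the induced quartet exist: the reference pairing AB|CD
and the two nearest-neighbor alternatives AC|BD and AD|BC.

* gCF: percentage of decisive gene trees (those carrying at least one
  taxon from each of A, B, C, D) whose induced split matches AB|CD;
  gDF1/gDF2 count the two alternatives, gDFP the remainder.
* sCF (parsimony): quartets are sampled (one leaf per adjacent clade);
  a site is decisive for a quartet when its four characters are
  unambiguous and show exactly two states in a 2+2 pattern; the site
  supports the resolution pairing equal states. Per-quartet support
  fractions are averaged over quartets with at least one decisive site.
* sCF_L (likelihood): per quartet the three resolutions are fitted
  (branch lengths only) and each site is assigned to the resolution
  with the highest site log-likelihood; near-ties are non-decisive.
  This flavor is less sensitive to homoplasy than the parsimony count.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, compress_patterns
from .likelihood import optimize_branch_lengths, site_log_likelihoods
from .modelspec import parse_model_string
from .submodels import MixtureModel, jc
from .trees import Node, Tree

__all__ = ["ConcordanceTable", "gene_concordance",
           "site_concordance_parsimony", "site_concordance_likelihood",
           "annotate_tree"]

_TIE_TOL = 1e-9


@dataclass
class ConcordanceTable:
    """Per-branch concordance records, one row per internal branch."""

    df: pd.DataFrame
    seed: int | None = None

    def row(self, branch_id: str) -> pd.Series:
        return self.df.set_index("branch_id").loc[branch_id]

    def merge(self, other: "ConcordanceTable") -> "ConcordanceTable":
        left = self.df.set_index("branch_id")
        right = other.df.set_index("branch_id")
        cols = [c for c in right.columns if c not in left.columns]
        return ConcordanceTable(left.join(right[cols]).reset_index(), self.seed)

    def to_tsv(self, path) -> None:
        header = "" if self.seed is None else f"# quartet-sampling seed: {self.seed}\n"
        with open(path, "w") as fh:
            fh.write(header)
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def _adjacent_clades(tree: Tree):
    """Yield (branch_id, node, (A, B, C, D)) for internal branches of an
    unrooted binary reference tree; non-binary contexts are skipped."""
    clades = tree.clades()
    all_leaves = frozenset(tree.leaf_names())
    for v in tree.edges():
        if v.is_leaf or len(v.children) != 2:
            continue
        u = v.parent
        A = clades[v.children[0].uid]
        B = clades[v.children[1].uid]
        if u is tree.root and u.parent is None:
            others = [c for c in u.children if c is not v]
            if len(others) != 2:
                continue
            C = clades[others[0].uid]
            D = clades[others[1].uid]
        else:
            others = [c for c in u.children if c is not v]
            if len(others) != 1:
                continue
            C = clades[others[0].uid]
            D = all_leaves - clades[v.uid] - C
        if not D:
            continue
        branch_id = "|".join(sorted(clades[v.uid]))
        yield branch_id, v, (A, B, C, D)


def gene_concordance(reference: Tree, gene_trees: list[Tree]) -> ConcordanceTable:
    """Gene concordance/discordance factors per internal reference branch.

    Gene trees may lack taxa; taxa absent from the reference are ignored
    with a warning. A branch with no decisive gene tree gets NA.
    """
    ref, _ = reference.copy()
    ref.unroot()
    ref_taxa = set(ref.leaf_names())
    prepared = []
    for g in gene_trees:
        extra = set(g.leaf_names()) - ref_taxa
        if extra:
            warnings.warn(f"gene tree taxa absent from reference ignored: "
                          f"{sorted(extra)}")
        gs = set()
        leafset = frozenset(n for n in g.leaf_names() if n in ref_taxa)
        for side in g.clades().values():
            side = frozenset(side & leafset)
            other = leafset - side
            if len(side) >= 2 and len(other) >= 2:
                gs.add(frozenset([side, other]))
        prepared.append((leafset, gs))

    rows = []
    for branch_id, _v, (A, B, C, D) in _adjacent_clades(ref):
        n_conc = n_df1 = n_df2 = n_para = 0
        for leafset, gsplits in prepared:
            if not (A & leafset and B & leafset and C & leafset and D & leafset):
                continue  # not decisive
            X = frozenset((A | B) & leafset)
            concordant = frozenset([X, leafset - X]) in gsplits
            X1 = frozenset((A | C) & leafset)
            X2 = frozenset((A | D) & leafset)
            if concordant:
                n_conc += 1
            elif frozenset([X1, leafset - X1]) in gsplits:
                n_df1 += 1
            elif frozenset([X2, leafset - X2]) in gsplits:
                n_df2 += 1
            else:
                n_para += 1
        gN = n_conc + n_df1 + n_df2 + n_para
        if gN:
            rows.append({"branch_id": branch_id, "gCF": 100.0 * n_conc / gN,
                         "gCF_N": n_conc, "gDF1": 100.0 * n_df1 / gN,
                         "gDF2": 100.0 * n_df2 / gN, "gDFP": 100.0 * n_para / gN,
                         "gN": gN})
        else:
            rows.append({"branch_id": branch_id, "gCF": np.nan, "gCF_N": 0,
                         "gDF1": np.nan, "gDF2": np.nan, "gDFP": np.nan,
                         "gN": 0})
    return ConcordanceTable(pd.DataFrame(rows))


def _sample_quartets(clade_sets, n_quartets: int, rng, exhaustive: bool):
    A, B, C, D = (sorted(s) for s in clade_sets)
    if exhaustive:
        return [(a, b, c, d) for a in A for b in B for c in C for d in D]
    return [(A[rng.integers(len(A))], B[rng.integers(len(B))],
             C[rng.integers(len(C))], D[rng.integers(len(D))])
            for _ in range(n_quartets)]


def _quartet_site_masks(aln: Alignment, quartet):
    """Boolean site masks (decisive, ref-support, df1, df2) for one quartet
    under the 2+2 parsimony rule; any ambiguity makes a site non-decisive."""
    rows = [aln.data[aln.taxa.index(t)] for t in quartet]
    a, b, c, d = rows
    states = list(aln.alphabet.states)
    ok = (np.isin(a, states) & np.isin(b, states)
          & np.isin(c, states) & np.isin(d, states))
    ref = ok & (a == b) & (c == d) & (a != c)
    df1 = ok & (a == c) & (b == d) & (a != b)
    df2 = ok & (a == d) & (b == c) & (a != b)
    return ref | df1 | df2, ref, df1, df2


def site_concordance_parsimony(reference: Tree, aln: Alignment,
                               n_quartets: int = 100, seed: int = 0,
                               exhaustive: bool = False) -> ConcordanceTable:
    """Parsimony site concordance factors by quartet sampling.

    ``exhaustive=True`` averages over every quartet (one leaf per
    adjacent clade) instead of sampling ``n_quartets`` of them.
    """
    if n_quartets < 1:
        raise ValueError("need at least one quartet")
    ref, _ = reference.copy()
    ref.unroot()
    missing = set(ref.leaf_names()) - set(aln.taxa)
    if missing:
        raise ValueError(f"taxon not in alignment: {sorted(missing)[0]!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for branch_id, _v, clades4 in _adjacent_clades(ref):
        quartets = _sample_quartets(clades4, n_quartets, rng, exhaustive)
        f_ref, f_df1, f_df2, n_dec = [], [], [], []
        for q in quartets:
            dec, ref_m, df1_m, df2_m = _quartet_site_masks(aln, q)
            nd = int(dec.sum())
            if nd == 0:
                continue
            f_ref.append(ref_m.sum() / nd)
            f_df1.append(df1_m.sum() / nd)
            f_df2.append(df2_m.sum() / nd)
            n_dec.append(nd)
        if f_ref:
            rows.append({"branch_id": branch_id,
                         "sCF": 100.0 * float(np.mean(f_ref)),
                         "sDF1": 100.0 * float(np.mean(f_df1)),
                         "sDF2": 100.0 * float(np.mean(f_df2)),
                         "sN": float(np.mean(n_dec)),
                         "quartets": len(f_ref)})
        else:
            rows.append({"branch_id": branch_id, "sCF": np.nan,
                         "sDF1": np.nan, "sDF2": np.nan, "sN": 0.0,
                         "quartets": 0})
    return ConcordanceTable(pd.DataFrame(rows), seed)


def _quartet_trees(q):
    """The three unrooted resolutions of a labelled quartet."""
    def make(pairs):
        root = Node()
        (x, y), (z, w) = pairs
        inner = Node(length=0.1)
        inner.add(Node(x, 0.1))
        inner.add(Node(y, 0.1))
        root.add(inner)
        root.add(Node(z, 0.1))
        root.add(Node(w, 0.1))
        return Tree(root, rooted=False)
    a, b, c, d = q
    return [make(((a, b), (c, d))), make(((a, c), (b, d))),
            make(((a, d), (b, c)))]


def site_concordance_likelihood(reference: Tree, aln: Alignment,
                                model=None, n_quartets: int = 100,
                                seed: int = 0, exhaustive: bool = False,
                                ) -> ConcordanceTable:
    """Likelihood site concordance factors.

    Per sampled quartet, branch lengths of the three resolutions are
    fitted under ``model`` (a single-class `MixtureModel` or model
    string; default JC) and every site is assigned to the resolution
    with the highest site log-likelihood; ties are non-decisive.
    """
    ref, _ = reference.copy()
    ref.unroot()
    if model is None:
        model = MixtureModel.single(jc(aln.alphabet))
    elif isinstance(model, str):
        from .fitting import MixtureTemplate
        spec = parse_model_string(model)
        template = MixtureTemplate(spec, aln)
        model = template.build(template.x0())
    rng = np.random.default_rng(seed)
    rows = []
    for branch_id, _v, clades4 in _adjacent_clades(ref):
        quartets = _sample_quartets(clades4, n_quartets, rng, exhaustive)
        f_res = []
        n_dec = []
        skipped = 0
        for q in quartets:
            sub = aln.subset_taxa(list(q))
            pal = compress_patterns(sub)
            site_lnls = []
            try:
                for qt in _quartet_trees(q):
                    opt, _ = optimize_branch_lengths(qt, pal, model, tol=1e-5)
                    site_lnls.append(
                        site_log_likelihoods(opt, pal, model).site_lnl())
            except ValueError:
                warnings.warn(f"quartet {q} fit failed; skipped")
                skipped += 1
                continue
            L = np.stack(site_lnls)                      # (3, n_sites)
            order = np.sort(L, axis=0)
            decisive = (order[-1] - order[-2]) > _TIE_TOL
            nd = int(decisive.sum())
            if nd == 0:
                continue
            best = np.argmax(L, axis=0)
            fr = [(best[decisive] == t).sum() / nd for t in range(3)]
            f_res.append(fr)
            n_dec.append(nd)
        if f_res:
            f = np.array(f_res).mean(axis=0)
            rows.append({"branch_id": branch_id, "sCF_L": 100.0 * f[0],
                         "sDF1_L": 100.0 * f[1], "sDF2_L": 100.0 * f[2],
                         "sN_L": float(np.mean(n_dec)),
                         "quartets_L": len(f_res), "skipped_L": skipped})
        else:
            rows.append({"branch_id": branch_id, "sCF_L": np.nan,
                         "sDF1_L": np.nan, "sDF2_L": np.nan, "sN_L": 0.0,
                         "quartets_L": 0, "skipped_L": skipped})
    return ConcordanceTable(pd.DataFrame(rows), seed)


def annotate_tree(reference: Tree, table: ConcordanceTable,
                  columns=("gCF", "sCF")) -> Tree:
    """Copy of the reference with 'col1/col2' labels on internal nodes."""
    ref, _ = reference.copy()
    ref.unroot()
    by_id = table.df.set_index("branch_id")
    clades = ref.clades()
    for v in ref.edges():
        if v.is_leaf:
            continue
        bid = "|".join(sorted(clades[v.uid]))
        if bid in by_id.index:
            vals = []
            for c in columns:
                if c in by_id.columns:
                    x = by_id.loc[bid, c]
                    vals.append("NA" if pd.isna(x) else f"{x:.1f}")
            v.label = "/".join(vals)
    return ref
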