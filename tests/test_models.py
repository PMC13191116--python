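"""Substitution models: rate-matrix construction, transition
probabilities, model-string grammar, matrix file I/O."""
import numpy as np
import pytest

from phylomix.alphabet import DNA
from phylomix.modelspec import ModelStringError, parse_model_string
from phylomix.ratedist import discrete_gamma_rates
from phylomix.submodels import (MixtureModel, build_rate_matrix, gtr, hky,
                                is_reversible, jc, k2p, named_matrix, poisson,
                                read_nonreversible_matrix, read_paml_matrix,
                                unrest, write_paml_matrix)


def test_jc_matrix_values():
    Q = build_rate_matrix(jc())
    off = Q[~np.eye(4, dtype=bool)]
    assert np.allclose(off, 1.0 / 3.0, atol=1e-15)
    assert np.allclose(np.diag(Q), -1.0, atol=1e-15)


def test_gtr_detailed_balance_and_normalization(rng):
    for _ in range(5):
        m = gtr(rng.uniform(0.1, 5, 6), rng.dirichlet(np.ones(4) * 3))
        F = m.freqs[:, None] * m.Q
        assert np.max(np.abs(F - F.T)) < 1e-12
        assert np.max(np.abs(m.Q.sum(axis=1))) < 1e-12
        assert -(m.freqs @ np.diag(m.Q)) == pytest.approx(1.0, abs=1e-12)


def test_nonreversible_detected(rng):
    m = unrest(rng.uniform(0.2, 3, 12))
    assert not m.reversible
    assert not is_reversible(m.Q, m.freqs, tol=1e-6)
    # stationary distribution really is stationary
    assert np.max(np.abs(m.freqs @ m.Q)) < 1e-12


def test_invalid_model_inputs():
    with pytest.raises(ValueError):
        gtr([-1, 1, 1, 1, 1, 1], [0.25] * 4)
    with pytest.raises(ValueError):
        gtr([1] * 6, [0.5, 0.5, 0.5, 0.5])
    with pytest.raises(ValueError):
        hky(-2.0)


def test_transition_probability_identity_and_stationary_limit():
    m = jc()
    assert np.allclose(m.transition_probabilities(0.0), np.eye(4), atol=1e-12)
    assert np.allclose(m.transition_probabilities(50.0), 0.25, atol=1e-9)
    with pytest.raises(ValueError):
        m.transition_probabilities(-0.1)


def test_jc_closed_form_diagonal():
    P = jc().transition_probabilities(0.3)
    expect = 0.25 + 0.75 * np.exp(-4.0 * 0.3 / 3.0)
    assert np.allclose(np.diag(P), expect, atol=1e-12)


def test_chapman_kolmogorov_and_stationarity(rng):
    """P(t+s) = P(t) P(s) and pi P(t) = pi for random models."""
    models = [jc(), hky(float(rng.uniform(1, 5)), rng.dirichlet(np.ones(4) * 4)),
              gtr(rng.uniform(0.2, 3, 6), rng.dirichlet(np.ones(4) * 4)),
              unrest(rng.uniform(0.2, 3, 12))]
    for m in models:
        for _ in range(5):
            t, s = rng.uniform(0, 5, 2)
            lhs = m.transition_probabilities(t) @ m.transition_probabilities(s)
            rhs = m.transition_probabilities(t + s)
            assert np.max(np.abs(lhs - rhs)) < 1e-9
            assert np.max(np.abs(m.freqs @ m.transition_probabilities(t)
                                 - m.freqs)) < 1e-9


def test_mixture_cost_scales_linearly_with_classes(monkeypatch, rng):
    """One transition-matrix build per edge per class-category component."""
    from phylomix import likelihood as lk
    from phylomix.alignment import Alignment, compress_patterns
    from phylomix.trees import random_tree
    from phylomix.submodels import SubstitutionModel

    tree = random_tree(list("ABCDE"), rng)
    aln = Alignment(list("ABCDE"), rng.choice(list("ACGT"), size=(5, 20)))
    calls = {"n": 0}
    orig = SubstitutionModel.transition_probabilities

    def counting(self, t):
        calls["n"] += 1
        return orig(self, t)

    monkeypatch.setattr(SubstitutionModel, "transition_probabilities", counting)
    n_edges = len(tree.edges())
    counts = []
    for k in (1, 2, 3):
        mix = MixtureModel([(jc(), discrete_gamma_rates(1.0, 2))] * k)
        calls["n"] = 0
        lk.site_log_likelihoods(tree, aln, mix)
        counts.append(calls["n"])
    per_class = counts[0]
    assert counts == [per_class * k for k in (1, 2, 3)]
    assert per_class == n_edges * 2  # 2 rate categories


def test_mixture_canonical_order():
    mix = MixtureModel([(jc(), None), (hky(2.0), None)], [0.2, 0.8])
    canon = mix.canonicalized()
    assert canon.weights[0] == pytest.approx(0.8)
    assert canon.classes[0][0].name == "HKY"
    # tie on weight -> lexicographic model name
    tie = MixtureModel([(k2p(), None), (jc(), None)], [0.5, 0.5]).canonicalized()
    assert tie.classes[0][0].name == "JC"


@pytest.mark.parametrize("text,canonical", [
    ("GTR+G4", "GTR+G4"),
    ("MIX{JC,HKY}+G4", "MIX{JC,HKY}+G4"),
    ("HKY+FO+I+G{0.5}", "HKY+FO+I+G4{0.5}"),
    ("gtr+g", "GTR+G4"),
    ("JC+R3", "JC+R3"),
])
def test_model_string_roundtrip(text, canonical):
    spec = parse_model_string(text)
    assert spec.canonical() == canonical
    assert parse_model_string(spec.canonical()).canonical() == canonical


def test_model_string_errors():
    with pytest.raises(ModelStringError, match="conflicting rate"):
        parse_model_string("GTR+G4+R3")
    with pytest.raises(ModelStringError, match="unknown base"):
        parse_model_string("XYZ+G4")
    with pytest.raises(ModelStringError, match="unknown suffix"):
        parse_model_string("GTR+ZZ")
    with pytest.raises(ModelStringError):
        parse_model_string("MIX{JC,HKY")


def test_mix_spec_parses_classes():
    spec = parse_model_string("MIX{JC,HKY}+G4")
    assert len(spec.classes) == 2
    assert spec.rate_kind == "gamma" and spec.rate_categories == 4


def test_paml_roundtrip(tmp_path, rng):
    m = gtr(rng.uniform(0.2, 3, 6), rng.dirichlet(np.ones(4) * 4))
    path = tmp_path / "custom.dat"
    write_paml_matrix(m, path, precision=12)
    back = read_paml_matrix(path)
    assert back.alphabet.size == 4
    assert np.allclose(back.exchangeabilities, m.exchangeabilities, rtol=1e-10)
    assert np.allclose(back.freqs, m.freqs, rtol=1e-10)
    assert np.allclose(back.Q, m.Q, rtol=1e-9)


def test_nonreversible_matrix_file(tmp_path, rng):
    rates = rng.uniform(0.2, 3, 12)
    path = tmp_path / "nr.dat"
    path.write_text(" ".join(f"{r:.10g}" for r in rates))
    m = read_nonreversible_matrix(path)
    assert not m.reversible
    assert -(m.freqs @ np.diag(m.Q)) == pytest.approx(1.0, abs=1e-10)


def test_bundled_protein_matrices():
    for name in ("LG", "WAG", "JTT"):
        m = named_matrix(name)
        assert m.alphabet.size == 20
        assert m.reversible
        assert -(m.freqs @ np.diag(m.Q)) == pytest.approx(1.0, abs=1e-10)
    assert poisson().alphabet.size == 20
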