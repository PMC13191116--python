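"""Branch-length gradient and Hessian for approximate Bayesian dating.

Fits branch lengths by ML, computes the gradient (should be ~0 at the
optimum) and the Hessian (negative definite), and writes the plain-text
export consumed by approximate-likelihood divergence-time samplers.
"""
import numpy as np

from phylomix import (MixtureModel, SimulationConfig, branch_gradient_hessian,
                      export_dating_file, hky, optimize_branch_lengths,
                      random_tree, simulate)

rng = np.random.default_rng(3)
tree = random_tree([f"sp{i}" for i in range(6)], rng, (0.05, 0.3))
model = MixtureModel.single(hky(3.0, np.array([0.3, 0.2, 0.3, 0.2])))
aln = simulate(SimulationConfig(tree, model, 5000, seed=3))

ml_tree, lnl = optimize_branch_lengths(tree, aln, model, tol=1e-8)
curv = branch_gradient_hessian(ml_tree, aln, model, method="analytic")

print(f"lnL at ML branch lengths: {lnl:.2f}")
print(f"max |gradient| = {np.max(np.abs(curv.gradient)):.2e} (first-order optimality)")
eig = np.linalg.eigvalsh(curv.hessian)
print(f"Hessian eigenvalue range: [{eig.min():.1f}, {eig.max():.1f}]")
export_dating_file(curv, ml_tree, "dating_export.txt")
print("wrote dating_export.txt (taxon count, newick, lengths, gradient, Hessian)")
# All Hessian eigenvalues are negative at an interior ML optimum: the
# quadratic surrogate used by approximate Bayesian dating is well posed.
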