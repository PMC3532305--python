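"""P_ST - F_ST sensitivity analysis on synthetic phenotypes.

Generates a strongly diverged trait with known between-site (4.0) and
within-site (2.0) variance across six sites, then traces P_ST and its 95%
CI over the c/h^2 grid against a neutral F_ST interval, reporting the
critical ratio.  Writes the corresponding figure to pst_curve.png.
"""

from invadiv import pst_sensitivity
from invadiv.plotting import plot_pst_curve
from invadiv.simulate import PhenotypeSimConfig, simulate_phenotypes

cfg = PhenotypeSimConfig(
    sites=[f"site{i+1}" for i in range(6)], n_per_site=25, sexes=("m",),
    traits={"tarsus": 19.0}, sigma2_b=4.0, sigma2_w=2.0, seed=8,
)
pheno, truth = simulate_phenotypes(cfg)

curve = pst_sensitivity(
    pheno, "tarsus", sex=None, fst_interval=(0.016, 0.046), covariate=None,
    seed=9,
)
vc = curve.components
i1 = int((curve.ratios == 1.0).nonzero()[0][0])
print(f"estimated sigma2_B = {vc.sigma2_b:.3f} (true 4.0), "
      f"sigma2_W = {vc.sigma2_w:.3f} (true 2.0)")
print(f"P_ST at c/h^2 = 1: {curve.pst[i1]:.3f} "
      f"[{curve.lower[i1]:.3f}, {curve.upper[i1]:.3f}] (true 0.5)")
print(f"critical c/h^2 (lower CI clears F_ST upper bound "
      f"{curve.fst_interval[1]}): {curve.critical_ratio}")
print(
    "\nA critical ratio well below 1 would mean the trait's divergence"
    "\nexceeds neutral expectation even if between-population additive"
    "\neffects are much weaker than within-population heritability -"
    "\nrobust evidence for divergent selection over drift."
)

ax = plot_pst_curve(curve)
ax.figure.savefig("pst_curve.png", dpi=120, bbox_inches="tight")
print("\nwrote pst_curve.png")
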