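"""Simulate and globally fit an exchange-broadened NMR titration.

Generates a seeded synthetic HSQC titration (two-state binding, ligand
depletion handled exactly) from the intermediate-exchange preset and
re-estimates K_D and k_off from the stacked 1D cross-sections.
"""

from docklock import fit_titration
from docklock.synthetic import fixture_preset, generate

fix = fixture_preset("EBH_11MACF", seed=42, n_residues=3)
series = generate(fix, "titration_lineshapes")

fit = fit_titration(series, seed=0)

print(f"ground truth: K_D = {fix.kd} uM, k_off = {fix.koff} s-1")
print(f"global fit:   K_D = {fit.kd:.2f} +- {fit.kd_err:.2f} uM, "
      f"k_off = {fit.koff:.1f} +- {fit.koff_err:.1f} s-1")
print(f"exchange regime at the median shift difference: {fit.regime}")
# k_off ~ 130 s-1 sits between the slow and fast limits, where the
# lineshape carries the most kinetic information; both parameters come
# back within a few percent at 1% noise.
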