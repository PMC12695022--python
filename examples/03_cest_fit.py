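"""Fit CEST saturation profiles for a low-population bound state.

Simulates ¹⁵N CEST at B1 = 12.5/25/50 Hz (400 ms irradiation, ~2.5% bound)
and re-fits the dissociation rate globally across residues and fields.
"""

from docklock import fit_cest
from docklock.synthetic import fixture_preset, generate

fix = fixture_preset("EBH_11MACF", seed=7, n_residues=3, koff=143.6)
profiles = generate(fix, "cest")

fit = fit_cest(profiles, {p.residue: 0.0 for p in profiles})
print(f"ground truth k_off = 143.6 s-1, bound population = 2.5%")
print(f"global fit:  k_off = {fit.koff:.1f} +- {fit.koff_err:.1f} s-1, "
      f"p_bound = {100 * fit.p_bound:.2f}%")
print(f"slow-exchange flag: {fit.flag_slow_exchange}")

# the same experiment on a much slower binder is correctly rejected
slow = fixture_preset("EBH_11MACF", seed=7, n_residues=3, koff=15.0)
fit_slow = fit_cest(generate(slow, "cest"), {p.residue: 0.0 for p in profiles})
print(f"k_off = 15 s-1 regime -> flag: {fit_slow.flag_slow_exchange} "
      f"({fit_slow.flag_reason})")
# At ~15 s-1 too little saturation is transferred per 400 ms for the rate
# to be determined; the fitter reports this instead of a silent bias.
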