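"""Fit the stacked-isomer fraction from a donor fluorescence decay.

A donor/acceptor pair on two junction arms reports on the conformer: in
isomer I the dyes are close (fast transfer, fast donor decay), in isomer
II far apart.  The decay is a population-weighted mixture of two Gaussian
distance distributions; fitting the weight recovers the equilibrium
fraction, which the Boltzmann relation converts to a free-energy gap.
"""

from junctionmd import (
    DecaySpec,
    FretModel,
    fit_isomer_fraction,
    gen_decay,
    isomer_dg,
)

truth = FretModel(fr_iso1=0.95)  # J1-like bias
curve = gen_decay(DecaySpec(model=truth, total_counts=1e6), seed=4)
print(f"synthetic decay: {curve.counts.sum():.0f} photons in "
      f"{len(curve.times)} channels over {curve.times[-1]:.0f} ns")

fit = fit_isomer_fraction(curve, model=FretModel(fr_iso1=0.5),
                          n_boot=25, seed=4)
t = isomer_dg(fit.fr, temperature=298.0)
lo, hi = fit.fr_ci
print(f"fitted fr_IsoI = {fit.fr:.3f}  (95% bootstrap CI {lo:.3f}-{hi:.3f})")
print(f"ddG = {t.ddG_kcal:+.2f} kcal/mol ({t.ddG_kJ:+.2f} kJ/mol)")

print("\nA fraction of 0.95 corresponds to the 19:1 conformer ratio and a "
      "free-energy gap at or below -1.71 kcal/mol favouring isomer I.")
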