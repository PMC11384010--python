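"""AMP affinity from binding titrations at increasing urea concentration.

Generates noiseless 1:1 fraction-bound curves at the measured dissociation
constants (MST-style dilution series) and refits them, reporting the fold
change in Kd that underlies the relief of substrate inhibition.
"""

from akdyn.assays import fit_isotherm
from akdyn.simulate import simulate_titration

kds_true = {0.0: 332e-6, 0.4: 522e-6, 0.8: 758e-6}

fitted = {}
for urea, kd in kds_true.items():
    table = simulate_titration(kd, noise_rel=0.02, seed=int(urea * 10))
    fit = fit_isotherm(table["conc_M"], table["fraction_bound"])
    fitted[urea] = fit.Kd
    print(f"{urea:.1f} M urea: fitted Kd(AMP) = {fit.Kd * 1e6:6.1f} uM "
          f"(generated at {kd * 1e6:.0f} uM)")

print(f"\nKd fold change 0.8 M vs 0 M urea: {fitted[0.8] / fitted[0.0]:.2f}x")
# A ~2.3-fold weaker AMP affinity shifts flux away from the slow
# 'AMP first' pathway at intermediate AMP concentrations.
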