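"""Choose a screening NaCl concentration from pilot salt-injury data.

Simulates mean salt-injury indices (SII) on the standard 0-250 mM ladder
from a known linear dose-response, fits the line per trait, solves the
50%-injury concentration, and recommends a level from the ladder.
"""

import salicore as sc

fits = []
for trait, intercept, slope in [("NIL", 0.10, 1 / 360), ("LER", 0.06, 1 / 350)]:
    table = sc.simulate_dose_response(intercept, slope, noise_sd=0.02, seed=3, trait=trait)
    fit = sc.fit_sii_line(table["concentration_mM"], table["mean_sii"], trait_name=trait)
    fits.append(fit)
    print(f"{trait}: SII = {fit.intercept:.3f} + {fit.slope:.5f}*C, "
          f"r2 = {fit.r_squared:.3f}, C50 = {fit.c_at_target:.1f} mM")

rec = sc.recommend_concentration(fits, [0, 100, 150, 200, 250])
print(f"\nrecommended screening level: {rec.recommended_mM:g} mM")
print("C50 is the concentration at which the fitted line reaches 50% injury;")
print("the recommendation picks the ladder level closest to the per-trait C50s.")
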