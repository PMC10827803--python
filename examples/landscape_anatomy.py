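"""Anatomy of smooth vs rugged NK landscapes.

Generates one smooth (K=0) and one rugged (K=7) landscape over 15-bit
solutions and prints their peak structure and the effect of the power-8
payoff sharpening.
"""

from divlearn import generate_landscape

for k in (0, 7):
    land = generate_landscape(n_elements=15, k_interactions=k, seed=42)
    median_raw = sorted(land.raw_table)[len(land.raw_table) // 2]
    print(f"NK(15,{k}): local optima = {land.count_local_optima()}")
    print(f"  max raw payoff        = {land.max_raw:.4f}")
    print(f"  median raw / max      = {median_raw / land.max_raw:.4f}")
    print(f"  median sharpened      = {(median_raw / land.max_raw) ** 8:.4f}")

# A smooth landscape has a single peak, so local search alone always finds
# the optimum.  A rugged landscape has hundreds of peaks; the sharpening
# (normalize by the maximum, raise to the 8th power) leaves typical
# solutions with tiny payoffs, so only near-optimal solutions score highly.
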