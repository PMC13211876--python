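"""Recover the social weight of a paired flight from front-back leadership.

Paired flights are simulated with a known experienced-bird weight w; the
front-back statistic (sign of the experienced-minus-naive displacement
projected on the pair's direction of motion) should average 0.5 at w = 0.5
and rise toward 1 as the experienced bird takes control.
"""

import numpy as np

from homingchains import (
    SyntheticConfig, generate_paired_flight, generate_population, leadership_fraction,
)

config = SyntheticConfig(seed=3)
population = generate_population(config, 9)

print("generating w   mean front fraction (100 flights)")
for w in (0.1, 0.3, 0.5, 0.7, 0.9):
    fracs = [
        leadership_fraction(
            *generate_paired_flight(
                population[i % 9], population[(i + 1) % 9], w=w, seed=500 + i
            )
        ).front_fraction
        for i in range(100)
    ]
    print(f"    {w:.1f}             {np.mean(fracs):.3f}")
# The mean front fraction increases monotonically with w: who flies in front
# is an observable proxy for who is steering the fused route.
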