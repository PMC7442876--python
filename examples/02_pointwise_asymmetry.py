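"""Pointwise interocular asymmetry testing across the scan circle.

Paired t-tests of the OS-OD difference at each of the 768 locations with
Bonferroni adjustment, the global difference, and empirical quantile bands.
"""

import numpy as np

from rnflasym import (
    default_params,
    empirical_quantiles,
    generate_population,
    global_difference,
    normalize_and_difference,
    pointwise_paired_tests,
)

diffs = [
    normalize_and_difference(p)
    for p in generate_population(default_params(n_subjects=400, seed=2))
]

mean, t, p = global_difference(diffs)
print(f"global OS-OD difference: {mean:+.2f} um (t = {t:.1f}, p = {p:.2g})")

res = pointwise_paired_tests(diffs)
print(
    f"locations with significant asymmetry after Bonferroni x768: "
    f"{int(res.significant.sum())}/768 ({100 * res.fraction_significant:.1f}%)"
)
print(
    f"pointwise mean difference ranges from {res.mean_delta.min():+.1f} um "
    f"to {res.mean_delta.max():+.1f} um across the circle"
)

bands = empirical_quantiles(diffs, [0.05, 0.5, 0.95])
width = bands.values[:, 2] - bands.values[:, 0]
i = int(np.argmax(width))
print(
    f"widest 5-95% band: {width[i]:.1f} um at {i * 360 / 768:.0f} deg "
    "(dispersion peaks at the nerve-fiber bundles)"
)
# A negative global mean means right eyes are thicker on average; most
# locations show a significant left-right difference, and the quantile
# bands are widest where the major bundles cross the scan circle.
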