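"""Interocular asymmetry of the major nerve-fiber-bundle peaks.

Each eye's profile is smoothed by a +/-12 deg circular moving average; the
superotemporal and inferotemporal peaks are the maxima of the superior and
inferior half-circles, and their interocular shifts are tested across the
cohort.
"""

from rnflasym import default_params, generate_population, population_peak_stats

pairs = generate_population(default_params(n_subjects=400, seed=3))
stats = population_peak_stats(pairs)

print(f"superior peak shift OS-OD: {stats.sup_shift_mean:+.2f} deg (p = {stats.sup_shift_p:.2g})")
print(f"inferior peak shift OS-OD: {stats.inf_shift_mean:+.2f} deg (p = {stats.inf_shift_p:.2g})")
print(
    f"interpeak-angle difference OS-OD: {stats.interpeak_diff_mean:+.2f} deg "
    f"(p = {stats.interpeak_diff_p:.2g})"
)
print(
    f"correlation of interpeak difference with radius difference: "
    f"r = {stats.pearson_r:+.3f}, explaining {100 * stats.variance_explained_by_rd:.2f}% of variance"
)
# The generator's defaults shift the left eye's superior peak ~1.55 deg
# nasally and its inferior peak ~4.42 deg temporally, so the left interpeak
# angle is ~2.9 deg smaller; radius differences explain almost none of the
# interpeak-angle variability.
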