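"""Detect the bias of a single-precision random number generator.

A uniform generator on a floor grid of spacing eps = 2^-23 (emulating
single precision) cannot reach deviates arbitrarily close to 1, so the
Lambertian entrance angle tops out at arccos(sqrt(eps)) = 1.570451 rad
instead of pi/2, and the longest slab trajectories are missing.  For
the ballistic 10 mm matched slab the missing-tail bias is
-2 d sqrt(eps) = -0.0069 mm, and the closed-form detection statistic
says one-tailed significance needs about N = 1e8 trajectories.
"""

from meanpath import (
    SP_EPS,
    detection_t,
    max_entrance_angle,
    run_precision_experiment,
    truncation_bias_ballistic_slab,
)

d = 10.0
print(f"max entrance angle on the 2^-23 grid : {max_entrance_angle(SP_EPS):.6f} rad")
print(f"missing-tail bias (d = {d:g} mm)        : {truncation_bias_ballistic_slab(d, SP_EPS):+.4f} mm")
print(f"closed-form detection t at N = 1e8   : {detection_t(d, SP_EPS, 1e8):+.2f}")
print()

table = run_precision_experiment(d, SP_EPS, 10**7, mu_s_grid=[0.0], seed=3)
print("engine runs at N = 1e7 (invariant <L>_IP = 20 mm):")
print(table[["quantized", "mean_mm", "se_mm", "t", "p_one_tailed"]].to_string(index=False))
print()
print("At N = 1e7 the quantized run's deficit is still inside the noise;")
print("push N to ~1e9 and the one-tailed test rejects, exposing the")
print("reduced-precision generator without inspecting a single line of code.")
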