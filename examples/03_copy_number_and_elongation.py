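"""From replicate Ct values to relative copy number and elongation calls.

Relative copy number uses the standard 2^-ddCt method: each qPCR cycle
of difference is a two-fold change in template abundance. A recombinant
stock is called 'elongated' when its copy number at the last assayed
generation is at least twice its generation-0 value (dCt dropped by
>= 1 cycle).
"""

from telmap import CtMeasurement, call_elongation, delta_ct, relative_copy_number

# one sample measured in triplicate for target and single-copy reference
target = CtMeasurement("stock_A", "HeT-A_gag", (20.0, 20.2, 19.8))
reference = CtMeasurement("stock_A", "RpS17", (15.0, 15.1, 14.9))
d = delta_ct(target, reference)
print(f"dCt = {d.value:.2f} +- {d.sd:.2f}  (target minus single-copy gene)")

calibrator_dct = 6.0
rcn = relative_copy_number(d.value, calibrator_dct)
print(f"relative copy number vs calibrator (dCt={calibrator_dct}): {rcn:.2f}")

# a trajectory drifting 0.25 dCt per generation over 12 generations
traj = [(g, 5.0 - 0.25 * g) for g in (0, 6, 9, 12)]
call = call_elongation("stock_A", traj)
print(f"\ntrajectory {traj}")
print(f"fold change g0->g12: {call.fold_change:.1f}  "
      f"slope {call.slope:+.2f} dCt/generation  elongated={call.elongated}")
print("\nA 3-cycle dCt drop corresponds to 2^3 = 8-fold copy gain.")
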