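"""Combine transposon side calls into a candidate interval.

Loads the packaged mapping-experiment table (14 transposon insertions
on 3R with Left/Right side calls from marker-classed recombinants) and
combines the calls round by round. The interval shrinks from 316 kb
(round 1) to 77 kb (rounds 1-2) to the final ~15 kb as later rounds
add insertions closer to the locus.
"""

from telmap import combine_sides, interval_width_kb, mapping_table_path
from telmap.io import read_mapping_table, side_calls_from_table

pairs = side_calls_from_table(read_mapping_table(mapping_table_path()))
print(f"{len(pairs)} insertions with side calls\n")

for label, rounds in [("round 1", {1}), ("rounds 1-2", {1, 2}), ("all rounds", None)]:
    iv = combine_sides(pairs, rounds=rounds)
    print(f"{label:>11}: {iv.interval.chrom}:{iv.lower:,}-{iv.upper:,} "
          f"(~{interval_width_kb(iv.interval)} kb; bounded by "
          f"{iv.lower_insertion} and {iv.upper_insertion})")

print("\nEach interval is bounded below by the rightmost insertion whose "
      "recombinants place the mutation to its right, and above by the "
      "leftmost insertion placing it to the left.")
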