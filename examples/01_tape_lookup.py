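"""Reading a color-zone tape: height -> zone, height -> weight, weight -> zone.

Builds the two built-in tapes and shows the three lookups a clinician
implicitly performs when laying the tape alongside a child.
"""

from ipwet import builtin_tape, predicted_weight, zone_for_height, zone_for_weight

broselow = builtin_tape("broselow_2007b")
ipwet = builtin_tape("ipwet")

for tape in (broselow, ipwet):
    print(f"{tape.tape_name}: heights {tape.height_min}-{tape.height_max} cm, "
          f"weights {tape.weight_min}-{tape.weight_max} kg, "
          f"{len(tape.zones)} zones")

h = 100.0  # a typical 4-year-old's supine length, in cm
zone = zone_for_height(h, broselow)
w = predicted_weight(h, broselow)
print(f"\nA {h:.0f} cm child falls in the {zone!r} zone; the tape reads "
      f"{w:.1f} kg (the zone's weight range interpolated at this height).")

# the reverse lookup classifies a measured weight into its zone
print(f"A measured weight of 13.8 kg belongs to the "
      f"{zone_for_weight(13.8, ipwet)!r} zone of the recalibrated tape.")
print(f"A weight of 5.5 kg falls in an inter-zone gap of the original tape: "
      f"zone = {zone_for_weight(5.5, broselow)}")
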