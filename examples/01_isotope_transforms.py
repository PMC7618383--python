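"""Closed-form isotope transforms: thermometers, scale transfers, calibration.

Evaluates the two paleothermometers, forward predictions, the
carbonate->phosphate transfer chain and a two-point reference calibration
on hand-checkable numbers.
"""

from elasmoiso import isotopes as iso

# A shark tooth measuring 22.0 permil VSMOW in water of -1.0 permil formed at:
t = iso.phosphate_temperature(22.0, -1.0)
print(f"phosphate thermometer: d18Op=22.0, d18Ow=-1.0  ->  T = {t:.1f} C")

# ... and the forward prediction inverts exactly:
print(f"forward prediction at {t:.1f} C -> d18Op* = {iso.predict_d18Op(t, -1.0):.1f} permil")

# An aragonite shell at 0.5 permil VPDB in the same water:
print(f"aragonite thermometer: d18Oc=0.5 -> T = {iso.aragonite_temperature(0.5, -1.0):.1f} C")

# Transpose a bulk bivalve carbonate value to its phosphate equivalent
# (VPDB -> VSMOW scale shift, then the empirical carbonate-phosphate offset):
c = 1.04  # a typical late-unit Cucullaea mean, permil VPDB
print(f"carbonate 1.04 permil VPDB -> phosphate-equivalent {iso.carbonate_to_phosphate(c):.2f} permil VSMOW")

# A 0.2 PSU seasonal freshening barely moves seawater d18O:
print(f"0.2 PSU freshening -> d18Ow shift {iso.d18Ow_shift_from_salinity(0.2):.3f} permil")

# Two-point calibration: both references measured 0.5 permil low means the
# instrument ran low; raw values are shifted up accordingly.
cal = iso.two_point_calibrate([21.5, 22.7], ref_measured=(12.6, 34.9))
print(f"calibrated raw [21.5, 22.7] -> {cal.round(2).tolist()} permil VSMOW")
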