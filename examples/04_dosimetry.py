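"""Exposure dose arithmetic for the isothiazolinone test conditions.

20 µL of each solution is applied inside an 8 mm diameter insert; the
applied mass is volume × concentration (µL · g/L = µg) and the areal
dose divides by the insert footprint.  Values print at full precision
with a 2-significant-figure display column.
"""

from dabdepth import STUDY_EXPOSURES, exposure_table

table = exposure_table(STUDY_EXPOSURES)
cols = ["name", "concentration_ppm", "concentration_g_per_L",
        "mass_applied_ug", "areal_dose_g_per_m2", "areal_dose_display"]
print(table[cols].to_string(index=False))
print("\ne.g. 30 ppm = 0.03 g/L -> 0.6 ug in 20 uL -> 0.012 g/m^2 over the 8 mm insert")
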