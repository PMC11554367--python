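"""Convert insulin and lipid panel values between conventional and SI units.

Two insulin conventions circulate: the WHO/ADA factor (1 uU/mL = 6.00
pmol/L) and a legacy reciprocal factor (pmol/L * 0.166 = uU/mL). They
differ by a fixed ratio of 0.996, which matters when trying to reproduce
published tables to the printed decimal.
"""

from refrange import LEGACY_RECIPROCAL, WHO, convert
from refrange.analytes import round_for_display as disp

lower, upper = 2.52, 13.14   # a proposed insulin reference interval, uU/mL
print(f"insulin RI {lower}-{upper} uU/mL")
print(f"  WHO factor (x6.00):        "
      f"{disp(convert(lower, 'insulin', 'to_si', WHO))}-"
      f"{disp(convert(upper, 'insulin', 'to_si', WHO))} pmol/L")
print(f"  legacy reciprocal (/0.166): "
      f"{disp(convert(lower, 'insulin', 'to_si', LEGACY_RECIPROCAL))}-"
      f"{disp(convert(upper, 'insulin', 'to_si', LEGACY_RECIPROCAL))} pmol/L")

print(f"glucose 89 mg/dL  = {disp(convert(89, 'glucose', 'to_si'))} mmol/L")
print(f"Tg      73 mg/dL  = {disp(convert(73, 'tg', 'to_si'))} mmol/L")
print(f"HDL-c   62 mg/dL  = {disp(convert(62, 'hdl', 'to_si'))} mmol/L")
# The two insulin lines differ in the first decimal: that is the 0.996
# convention ratio, not a computation error.
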