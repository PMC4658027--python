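"""Shared physical constants of the growth model.

All body-weight conversions live here so the forward (gain from intake) and
backward (intake from gain) calculations are guaranteed to use identical
factors.
"""

#: Empty body weight per unit shrunk body weight (EBW = 0.891 * SBW).
EBW_PER_SBW = 0.891

#: Empty-body gain per unit shrunk-weight gain (EBG = 0.956 * SWG).
EBG_PER_SWG = 0.956

#: Standard reference shrunk weight, kg, at the 28 % empty-body-fat endpoint.
#: Used to size-scale retained-energy requirements (EQSBW = SBW * SRW / AFSBW).
SRW_KG = 478.0

#: Default target empty body fat, % of empty body weight (USDA low Choice).
DEFAULT_TARGET_EBF_PCT = 28.0

#: Default age, days, assumed when hip height is measured (12 months).
DEFAULT_AGE_D = 365.0
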