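"""Internal unit system and physical constants.

All quantities are held internally in mmHg, ml (= cm^3), s and cm.
Conversions to CGS pressure units happen only inside the momentum balance,
where the pressure gradient must carry mechanical units.
"""

# 1 mmHg expressed in dyn/cm^2 (= g cm^-1 s^-2)
MMHG_TO_CGS = 1333.22

# Blood properties (defaults; overridable per network document)
BLOOD_DENSITY = 1.06          # g/ml
BLOOD_VISCOSITY = 0.04        # poise = g/(cm s)

M_PER_S_TO_CM_PER_S = 100.0
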