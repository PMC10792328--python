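"""Direct (model-free) HLYL estimation from a life table.

Builds a synthetic cohort from a Gompertz-Makeham mortality schedule,
appends the mortality-space columns and reads off the peak of the bx
curve — the direct estimate of healthy life years lost.
"""

import numpy as np

from lifeyears import SimConfig, direct_columns, direct_hlyl, make_life_table, sms_areas

lt = make_life_table(SimConfig())  # default human-like schedule, radix 100000
cols = direct_columns(lt)
est = direct_hlyl(lt)
surv, mort = sms_areas(lt)

print(f"life expectancy at birth : {lt.e0:.2f} years")
print(f"direct HLYL (peak of bx) : {est.hlyl:.3f} years at age {est.age}")
print(f"bx at ages 50/70/90      : "
      + " / ".join(f"{cols.bx[a]:.3f}" for a in (50, 70, 90)))
print(f"survival / mortality area: {surv:.1f} / {mort:.1f} person-years per person")

# The bx curve rises with age to a peak and then declines; its peak is the
# number of years of remaining life expectancy lost to ill health.  The two
# areas partition the (omega+1)-year age span: the survival area is e0 plus
# the half-interval closure term.
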