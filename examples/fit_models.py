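"""Parametric HLYL estimation: log-logistic, Weibull and Gompertz fits.

Fits each lifetime model to the same synthetic life table and prints the
shape parameter l — the HLYL carrier — together with the goodness of fit.
The log-logistic and Weibull hazards are fitted to the mortality-rate
series; the Gompertz (Gumbel) CDF is fitted to the death-age distribution.
"""

from lifeyears import FitConfig, SimConfig, compute_hle, fit_model, make_life_table

lt = make_life_table(SimConfig(hazard="weibull", params={"b": 1 / 80, "l": 7.0}))
print(f"table generated from a Weibull hazard with true shape l = 7.0; "
      f"e0 = {lt.e0:.2f} years\n")

print(f"{'model':<12} {'HLYL (l)':>9} {'R2':>8} {'SSE':>10} {'std err':>9} {'HLE':>7}")
for family in ("loglogistic", "weibull", "gompertz"):
    fr = fit_model(lt, FitConfig(family=family))
    hle = compute_hle(lt.e0, fr.hlyl)
    print(f"{family:<12} {fr.hlyl:>9.3f} {fr.r2:>8.4f} {fr.sse:>10.2e} "
          f"{fr.std_error:>9.2e} {hle:>7.2f}")

# The matched family (weibull) recovers l = 7 to solver precision.  The
# Gompertz CDF tracks the death distribution closely.  The log-logistic
# hazard saturates at l/x for large x, so on a schedule whose rates keep
# accelerating it can only follow the oldest ages by inflating its shape —
# the fitted l is always larger than the Weibull's, and model choice
# matters; on real data the WHO comparison arbitrates between them.
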