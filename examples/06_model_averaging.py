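"""All-subsets AICc model averaging of at-sea FMR on the packaged table.

Fits every main-effect subset of {season, trip duration, % time diving,
mean max depth, FA cluster, tag frontal surface area} with a random
intercept per seal (refit as plain linear models when the random-effect
variance collapses to zero), AICc-weights the candidates, and conditionally
averages each coefficient over the 95% confidence set.
"""

from sealflux.models import effect_as_percent
from sealflux.pipeline import fmr_model_set
from sealflux.study import load_study_table

table = load_study_table("table1")
out = fmr_model_set(table)

print(f"candidate models : {len(out.models)} (n = {out.n} complete cases)")
print(f"95% confidence set: {len(out.confidence_set)} models")
print()
print("top five models by Akaike weight:")
top = out.models.head(5).copy()
top["effects"] = top["effects"].apply(lambda e: "+".join(e) or "(intercept)")
print(top[["effects", "k", "AICc", "dAICc", "weight"]].round(3).to_string(index=False))
print()
print("model-averaged coefficients (conditional, 95% confidence set):")
print(out.averaged.round(3).to_string())
print()
fall = effect_as_percent(out, "season[fall]")
day = effect_as_percent(out, "trip_duration")
print(f"fall effect    : {fall:+.1f}% of the averaged intercept")
print(f"trip-day effect: {day:+.1f}% per additional day at sea")
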