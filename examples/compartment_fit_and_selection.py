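"""Fit 1T/2T compartment models to a noisy tissue TAC and select by AICc.

Simulates a bone-marrow-like TAC (two-tissue kinetics with a small efflux
rate k4 representing cell trafficking out of the tissue), fits all three
candidate models with duration/decay weighting, and prints the AICc ranking
plus the net influx rate Ki of the winner.
"""
from petkin import (
    ModelSpec,
    REGION_ARCHETYPES,
    fit_model,
    generate_blood,
    generate_tissue,
    ki_macro,
    make_study_schedule,
    select_model,
)

schedule = make_study_schedule()
blood = generate_blood()
truth = REGION_ARCHETYPES["bone_marrow"]
tac, truth_record = generate_tissue(truth, blood, schedule, noise_scale=0.05,
                                    seed=42, region="bone_marrow")

fits = [fit_model(tac, blood, ModelSpec(model=m), seed=0)
        for m in ("1T3P", "2T4P", "2T5P")]
selection = select_model(fits)

print(selection.table.round(4).to_string(index=False))
print()
best = selection.best
print(f"selected model : {best.model}")
print(f"estimated Ki   : {best.ki:.5f} /min   (truth {ki_macro(truth):.5f})")
print()
print("Lower AICc wins; the k4 > 0 generating kinetics make the full 2T5P")
print("model worth its extra parameter once the 48-h frame is in the fit.")
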