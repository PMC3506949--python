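"""Predict flux rerouting after a gene knockout, four methods side by side.

Deleting the major branch's gene (gR1, reference flux 8) forces flux
through the minor branch R2 (reference flux 2, enzyme contribution 2).
The relative-change predictor limits the rerouted flux by the surviving
enzyme's capacity; MOMA, which only minimizes Euclidean distance, reroutes
far more; FBA ignores enzyme capacity entirely.
"""

from relatch import PerturbationSpec, estimate_reference, fba, moma, predict, room, select_params
from relatch.fixtures import make_synthetic_reference_data, make_toy_network

model = make_toy_network("diamond")
sc = make_synthetic_reference_data(model, seed=0, noise_sigma=0.0)
ref = estimate_reference(model, sc.mfa, sc.expression, sc.physiology)
ko = PerturbationSpec(knockouts={"gR1"})

tight = predict(model, ref, ko, select_params("non_adapted"))
relaxed = predict(model, ref, ko, select_params("adapted"))
mom = moma(model, ref, ko)
ro = room(model, ref, ko)
fb = fba(model, ko)

print("rerouted flux through the surviving branch R2 (mmol/gDW/h):")
print(f"  tight (alpha=10, gamma=1.1):   {tight.flux['R2']:.4f}"
      "   <- capped at 1.1 x its reference contribution of 2")
print(f"  relaxed (alpha=1, gamma=inf):  {relaxed.flux['R2']:.4f}"
      "   <- unconstrained stationary point 70/27")
print(f"  MOMA:                          {mom.flux['R2']:.4f}"
      "   <- Euclidean compromise 22/3")
print(f"  FBA:                           {fb.flux['R2']:.4f}"
      "   <- full uptake, no capacity limits")
print(f"ROOM significant changes: {int(ro.objective)} "
      "(the deleted branch and the rerouted one)")
print(f"tight objective {tight.objective:.4f} = "
      "1 (dead branch) + 2 x (1-0.22)^2 (throughput drop) + 0.01 (R2 change)")
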