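"""Score predicted fluxes against measurements and call growth phenotypes.

Predictions are compared to (here: synthetic) mutant MFA data by the sum
of squared errors per flux (SSE) and Pearson's r, including a lumped
measurement that sums two reactions, and growth predictions are reduced to
growth / no-growth calls tabulated in a confusion matrix.
"""

from relatch import (
    PerturbationSpec,
    classify_growth,
    compute_sse,
    confusion_accuracy,
    estimate_reference,
    mfa_from_records,
    predict,
    select_params,
)
from relatch.fixtures import make_synthetic_reference_data, make_toy_network

model = make_toy_network("diamond")
sc = make_synthetic_reference_data(model, seed=0, noise_sigma=0.0)
ref = estimate_reference(model, sc.mfa, sc.expression, sc.physiology)
ko = PerturbationSpec(knockouts={"gR1"})
pred = predict(model, ref, ko, select_params("non_adapted"))

# stand-in mutant measurements, including a lumped map over both branches
mutant_mfa = mfa_from_records(
    [("u", "U", 2.0, 0.1), ("r1", "R1", 0.3, 0.1),
     ("branches", "R1+R2", 2.3, 0.1), ("x", "R3", 2.0, 0.1)], model)
report = compute_sse(pred.flux, mutant_mfa)
print(report)
for mid, sq in report.per_measurement.items():
    print(f"  {mid:10s} squared error {sq:.4f}")

wt_growth = ref.flux[model.biomass_id]
call = classify_growth(pred.growth, wt_growth)
print(f"\npredicted growth {pred.growth:.3f} vs wild type {wt_growth:.3f}"
      f" -> {call}")

cm = confusion_accuracy([("growth", call), ("growth", "growth"),
                         ("no_growth", "no_growth")])
print(f"confusion counts +/+ {cm.pp}, +/- {cm.pn}, -/+ {cm.np_}, -/- {cm.nn}; "
      f"accuracy {cm.accuracy:.1f}%")
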