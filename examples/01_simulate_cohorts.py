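"""Simulate the three synthetic cohort types and inspect the planted truth.

Generates (a) FACS-sorted cell populations with population-specific marker
genes, (b) a 9-responder / 12-nonresponder drug cohort with signed signal
genes, and (c) a bulk tumor cohort mixing cell-type profiles with six latent
subtypes and subtype-linked survival hazards.
"""

from tmesig import (
    simulate_bulk_cohort,
    simulate_response_cohort,
    simulate_sorted_populations,
)

sorted_mx, sorted_truth = simulate_sorted_populations(seed=0)
print(f"sorted populations: {sorted_mx.n_genes} genes x {sorted_mx.n_samples} samples")
for pop, markers in sorted_truth.marker_genes.items():
    print(f"  {pop}: {len(markers)} planted marker genes")

resp_mx, resp_truth = simulate_response_cohort(seed=0)
counts = resp_truth.response_labels.value_counts()
print(f"response cohort: {counts['responder']} responders, "
      f"{counts['nonresponder']} nonresponders, "
      f"{len(resp_truth.signal_signs)} signed signal genes")

bulk_mx, bulk_ann, bulk_truth = simulate_bulk_cohort(n_samples=120, seed=0)
print(f"bulk cohort: {bulk_mx.n_genes} genes x {bulk_mx.n_samples} samples, "
      f"subtype counts: {bulk_truth.subtype_labels.value_counts().sort_index().to_dict()}")
print("  mixing fractions of the first sample:",
      bulk_truth.mixing_fractions.iloc[0].round(3).to_dict())
# Each bulk profile is a convex mixture of cell-type profiles; the fractions
# above sum to 1 and are the truth the deconvolution stage must recover.
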