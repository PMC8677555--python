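"""Exome variant prioritisation: the full filter cascade on a synthetic table.

Builds an annotated variant table for the Arab Muslim CD family with two
planted causal-like candidates and ten decoys (each violating exactly one
filter criterion), then runs the cascade: site tranche filter, genotype
quality rules, no-call-rate filter, homozygous/damaging/frequency
selection in the proband, and sibling segregation with family controls.
"""

from consangmap import (
    FilterThresholds,
    SegregationRule,
    SynthConfig,
    apply_genotype_filters,
    candidate_table,
    family_fixtures,
    generate_variant_table,
    no_call_filter,
    proband_candidates,
    segregation_filter,
    site_filter,
)
from consangmap.synth import CandidateSpec, DecoySpec, DECOY_KINDS

ped = family_fixtures()["AM-CD"]
cases, controls = ("V-1", "V-3"), ("V-2", "V-4", "IV-2")
pops = ("gnomad", "gmev")

records, annotations, truth = generate_variant_table(
    ped, SynthConfig(seed=4),
    [CandidateSpec("CAND1", cases), CandidateSpec("CAND2", cases)],
    [DecoySpec(kind, cases) for kind in DECOY_KINDS],
    control_ids=controls,
)
print(f"input variants: {len(records)} "
      f"(2 planted, {len(DECOY_KINDS)} decoys, the rest background)")

t = FilterThresholds()
kept = no_call_filter(apply_genotype_filters(site_filter(records, t), t), t)
print(f"after site/genotype/no-call filters: {len(kept)}")

cands = proband_candidates(kept, "V-1", pops, t)
rule = SegregationRule(required_hom_cases="all", control_exclusion="any")
final = segregation_filter(cands, rule, cases, controls)
print(f"prioritised: {len(final)}")
print(candidate_table(final, pops).to_string(index=False))
# Only the planted candidates survive: homozygous in both affected
# brothers, damaging, below 5% in both reference populations, and not
# homozygous in any family control; every decoy falls at the stage whose
# criterion it violates.
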