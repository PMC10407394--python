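"""Annotate a single heavy-chain amplicon: V/D/J calls, junction, mutations.

Takes one simulated cell (so the right answer is known), assigns germline
genes by local alignment, cuts the junction between the conserved 2nd-CYS
and J-TRP codons, and counts somatic mutations over the V segment.
"""

from ighclone import (
    SimConfig,
    annotate_sequence,
    count_v_mutations,
    simulate_sample,
    synthetic_germline_set,
)

germlines = synthetic_germline_set(seed=3)
sample = simulate_sample(
    SimConfig(seed=20, n_cells=1, clone_spec=(), mutated_fraction=1.0), germlines
)
truth = sample.truth[0]

r = annotate_sequence(truth.cell_id, str(sample.records[0].seq), germlines)
r.mutation = count_v_mutations(r, germlines)

print(f"cell:        {r.cell_id}")
print(f"v_call:      {r.v.gene}  (identity {r.v.identity_pct:.1f}%)")
print(f"d_call:      {r.d.gene if r.d else 'none (no 7-base run)'}")
print(f"j_call:      {r.j.gene}")
print(f"junction:    {r.junction.nt}")
print(f"cdr3:        {r.junction.cdr3_nt}")
print(f"productive:  {r.productive}")
print(
    f"mutations:   {r.mutation.n_diff} over {r.mutation.aligned_len} nt "
    f"= {r.mutation.freq_pct:.2f}% -> {r.mutation.status}"
)
print(f"truth was:   {truth.v_name} / {truth.d_name} / {truth.j_name}, "
      f"{len(truth.implanted_mutations)} implanted mutations")
# identity <100% reflects the implanted hypermutation; the mutation count
# should match the number of implanted substitutions upstream of the CDR3.
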