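"""Mutagenesis-library design math and the two-step anti-repressor sort.

Prints the NNS site-saturation coverage numbers (32 codons; the per-codon
probability that 96 picked clones include any given codon, and the much
stricter probability that they include all 32), the EP-PCR substitution
statistics for the standard region/error-rate, and then runs an equal
four-phenotype mutant library through the two-step FACS plan: low-FITC with
ligand, then high-FITC without, each pass repeated.  The composition table
shows the anti-repressor fraction rising toward 1.
"""

from txlogic.screening import (
    default_fa_sort_plan, ep_pcr_mutation_stats, library_coverage, nns_codon_set,
    run_sort_plan,
)
from txlogic.synthetic_data import FRUCTOSE, Phenotype, TFSpec, profile_from_phenotype

codons = nns_codon_set()
aas = {aa for _, aa in codons if aa != "*"}
stops = [c for c, aa in codons if aa == "*"]
print(f"NNS codons: {len(codons)} covering {len(aas)} amino acids; stops: {stops}")

cov = library_coverage(n_picks=96, n_codons=32)
print(f"96 picks: per-codon coverage {cov.per_codon_prob:.1%}, "
      f"all-32 coverage {cov.all_covered_prob:.1%}")

ep = ep_pcr_mutation_stats(region_len=815, error_rate=0.007)
print(f"EP-PCR: mean {ep.mean:.2f} substitutions/clone "
      f"(~{ep.expected_residues_hit:.1f} codons hit)")

tfs = [TFSpec(f"F_{p.value}", FRUCTOSE, "YQR", p) for p in Phenotype]
mix = [(profile_from_phenotype(tf, "O1", "proximal"), 0.25) for tf in tfs]
result = run_sort_plan(mix, default_fa_sort_plan(FRUCTOSE), seed=2024)
print("sort-plan composition (per pass):")
for i, comp in enumerate(result.history):
    stage = "start" if i == 0 else f"pass {i}"
    print("  " + stage + ":  " + "  ".join(f"{g}={f:.3f}" for g, f in comp.items()))
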