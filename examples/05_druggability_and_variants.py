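"""Motif-graph druggability and GWAS variant filtering.

Scores genes by the enrichment of their sequence motifs among drugged genes
(one-sided Fisher's exact test; a never-drugged gene inherits credit from a
drugged motif-mate), then filters GWAS variants down to candidates that are
non-synonymous, genome-wide significant, directionally replicated, and
carried by genes the drug-target model likes.
"""

from pwas.compounds import (VariantRecord, motif_druggability,
                            variant_candidate_filter)

membership = {
    "KINASE1": {"protein_kinase_domain"},
    "KINASE2": {"protein_kinase_domain"},
    "KINASE3": {"protein_kinase_domain"},
    "GPCR1": {"seven_tm_domain"},
    "SCAFFOLD1": {"coiled_coil"},
    "SCAFFOLD2": {"coiled_coil"},
    "ORPHAN1": set(),
}
drugged = {"KINASE1", "KINASE2", "GPCR1"}
scores = motif_druggability(membership, drugged)
print("druggability (-log10 Fisher p of best motif):")
for gene in sorted(membership):
    print(f"  {gene:10s} {scores.get(gene):.3f}")
# KINASE3 scores like its drugged motif-mates despite never being drugged;
# ORPHAN1, with no motifs, scores 0.

variants = [
    VariantRecord("GCKR", "rs8179206", "Glu77Gly", -2.945, 20.18, 2, 0.90),
    VariantRecord("CD40", "rs7273698", "Phe150Phe", -1.675, 12.26, 2, 0.55),
    VariantRecord("WEAK1", "rs000001", "Ala10Val", 0.4, 6.5, 2, 0.80),
    VariantRecord("LONE1", "rs000002", "Gly5Asp", 1.1, 15.0, 1, 0.80),
    VariantRecord("LOWLIK", "rs000003", "Met1Thr", -0.9, 14.0, 2, 0.10),
]
kept = variant_candidate_filter(variants)
print("\nvariants passing all four criteria:")
for r in kept:
    print(f"  {r.gene} {r.rsid} {r.amino_acid_change} "
          f"(-log10 p = {r.minus_log10_p}, likelihood {r.likelihood})")
# Only the GCKR variant survives: non-synonymous, p < 1e-9, two consistent
# studies, and model likelihood above 0.3.
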