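"""Per-site association between haplotype groups with FDR correction.

Generates a phased panel whose two haplogroups carry inversion-like fixed
differences plus shared background polymorphism, tests every site with an
exact allele x group test, and adjusts across sites with the
Benjamini-Hochberg procedure.  Divergent sites surface with small q-values;
shared polymorphism does not.
"""

from mimicrylab import haplotypes, synth

spec = synth.PanelSpec(
    n_target=10,
    n_reference=10,
    n_sites=400,
    n_planted=0,
    divergence=0.08,
    target_group="mimetic",
    reference_group="nonmimetic",
    seed=4,
)
matrix, truth = synth.generate_haplotype_panel(spec)
result = haplotypes.site_association(matrix, ("mimetic", "nonmimetic"))
table = result.table

hits = table[table["q"] < 0.05]
divergent = set(truth.divergent_positions)
true_hits = sum(pos in divergent for pos in hits["position"])
print(f"panel: {matrix.n_haplotypes} haplotypes x {matrix.n_sites} sites")
print(f"generator planted {len(divergent)} fixed inter-group differences")
print(f"sites with q < 0.05: {len(hits)} ({true_hits} are planted divergent sites)")
print(f"smallest q among planted sites: {table[table['position'].isin(divergent)]['q'].min():.2e}")
print(
    "\nA perfectly separating site among 10+10 haplotypes reaches the exact\n"
    "test's floor p = 2/C(20,10) ~ 1.1e-5; BH keeps those discoveries while\n"
    "the shared background polymorphism stays non-significant."
)
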