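"""Morph-specific SNP discovery on phased haplotype panels.

Builds two synthetic panels with planted target-specific SNPs (emulating
the dark-mimetic *theseus* morph against *polytes* haplotypes in two
island populations), recovers them with the tolerance rules used for
2-haplotype (no exceptions) and 6-haplotype (one exception) groups, and
intersects the two site sets.
"""

from mimicrylab import haplotypes, synth

reports = {}
for name, (n_target, exceptions, n_planted, seed) in {
    "indonesia": (6, 1, 110, 1),
    "philippines": (2, 0, 107, 2),
}.items():
    spec = synth.PanelSpec(
        n_target=n_target,
        n_reference=4,
        n_sites=1000,
        n_planted=n_planted,
        missing_rate=0.02,
        seed=seed,
    )
    matrix, truth = synth.generate_haplotype_panel(spec)
    report = haplotypes.morph_specific_sites(
        matrix, "theseus", "polytes", max_exceptions_target=exceptions
    )
    recovered = len(set(truth.planted_positions) & set(report.positions))
    reports[name] = report
    print(
        f"{name}: planted {n_planted} target-specific SNPs, recovered "
        f"{recovered} ({len(report.positions)} qualifying sites in total, "
        f"extras are inversion-divergence sites that also separate the groups)"
    )

shared = haplotypes.shared_specific_sites(reports["indonesia"], reports["philippines"])
print(
    f"positions shared between the two independent panels: {len(shared)}\n"
    "(the panels are planted independently, so only chance positional\n"
    "collisions remain - independently originated morphs share essentially\n"
    "no specific sites)"
)
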