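"""Founder hitchhiking and McDonald-Kreitman patterns in a coding supergene.

Simulates the two-phase scenario - a large population under purifying
selection (omega = 0.05) from which a single haplotype founds a rapidly
expanding 'mimetic' class - and classifies variation against the known
ancestor.  The founder's accumulated variants appear as fixed differences
of the mimetic sample even though selection never changed.
"""

import numpy as np

from mimicrylab import codon, mk, synth

rng = np.random.default_rng(0)
gmrca = synth.generate_gmrca(300, rng)

replicates = codon.hitchhiking_replicates(gmrca, n_replicates=5, seed=0)
print("per replicate: fixed(mim) fixed(non)  pi(mim)   pi(non)   MK p(mim)")
for i, s in enumerate(replicates):
    t_mim = mk.classify_sites(s.samples["mimetic"], gmrca)
    t_non = mk.classify_sites(s.samples["nonmimetic"], gmrca)
    pi_m = codon.mean_pairwise_divergence(s.samples["mimetic"])
    pi_n = codon.mean_pairwise_divergence(s.samples["nonmimetic"])
    p = mk.fisher_exact_2x2(t_mim.as_2x2())
    print(
        f"  rep {i}:   {t_mim.total_fixed:>5}      {t_non.total_fixed:>5}"
        f"     {pi_m:.4f}    {pi_n:.4f}    {p:.3f}"
    )

last = replicates[-1]
omega = mk.omega_summary(last.sample_sequences("nonmimetic"), gmrca)
print(
    f"\nnon-mimetic Ka/Ks = {omega.mean:.3f} +/- {omega.se:.3f} "
    f"(simulated under omega = 0.05: purifying selection is recovered)"
)
print(
    "The mimetic class shows more fixed differences and lower internal\n"
    "diversity than its source population - the hitchhiking signature -\n"
    "while its MK table stays consistent with neutrality (p well above 0.05)."
)
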