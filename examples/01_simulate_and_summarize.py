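"""Simulate one locus under an expansion history and summarize it.

A bogus-yucca-moth-like mitochondrial locus (n=25, 1800 bp, TrN+Gamma) is
simulated under a population doubling at 13 KYA, then the standard expansion
diagnostics are computed: strongly negative Fu's Fs and a unimodal mismatch
distribution are the classic signatures of growth.
"""

from comdemog import (
    DemographicScenario,
    SubstitutionModel,
    evolve_sequences,
    mismatch_tau,
    simulate_genealogy,
    summary_stats,
    tau_to_years,
)

scenario = DemographicScenario(
    ne_present=1e6,
    ratio_ancestral=240 / 432,  # past range about half the present range
    t_change_years=13_000.0,
    generations_per_year=1.0,
)
model = SubstitutionModel("TrN", rate_AG=65.95, rate_CT=24.28, alpha=0.04)

genealogy = simulate_genealogy(25, scenario, seed=1)
aln = evolve_sequences(genealogy, model, mu=1.5e-8, n_sites=1800, seed=1)

ss = summary_stats(aln)
fit = mismatch_tau(aln)
print(f"n={ss.n}  S={ss.S}  haplotypes={ss.k_hap}")
print(f"pi={ss.pi:.2f}  Watterson theta={ss.theta_w:.2f}")
print(f"Fu's Fs = {ss.fs:.3f}  (negative favours expansion)")
print(f"Tajima's D = {ss.tajima_d:.3f}")
print(f"mismatch tau = {fit.tau_hat:.3f}")
mu_locus_per_year = 1.5e-8 * 1800  # per-locus rate, 1 generation per year
print(
    "implied change time =",
    f"{tau_to_years(fit.tau_hat, mu_locus_per_year):.3g} years",
    "(table convention t = tau/mu)",
)
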