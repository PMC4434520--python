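"""The complete co-occupancy signature analysis in one call.

Runs every stage on a simulated study: signal matrix, randomized-SSE
choice of k, semantic cluster labels, element distributions, motif
discovery and enrichment, and the expression linkage.  Reduced problem
sizes keep this example fast; scripts/acceptance.py runs the full-size
version.
"""

from chipsig.pipeline import run_analysis
from chipsig.simulate import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))
res = run_analysis(study, seed=1, k_max=6, n_random=20, anneal_steps=5000)

print(f"chosen k: {res.k_curve.chosen_k}")
print("\ncluster profiles (tags/bp at 1e7 depth):")
print(res.profiles.round(2).to_string())
print("\nelement distribution (%):")
print((100 * res.element_distribution).round(1).to_string())
print(f"\ndiscriminative motif: {res.motif.consensus} "
      f"(AUC {res.motif_auc:.3f})")
print("motif fraction per cluster:",
      {c: round(f, 3) for c, f in res.motif_fractions.items()})
print(f"KS over-representation: D = {res.ks_stat:.3f}, p = {res.ks_p:.3g}")
for key, (stat, p) in res.shift_tests.items():
    print(f"t-shift {key}: t = {stat:.1f}, p = {p:.3g}")
for key, (odds, p, _) in res.fisher_tests.items():
    print(f"Fisher {key}: odds = {odds:.2f}, p = {p:.3g}")
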