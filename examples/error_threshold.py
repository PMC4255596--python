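"""Locate the quasi-species error threshold on a single-peak landscape.

With master superiority sigma = e and genome length L = 100, the classical
theory puts the genome-wide threshold at mu_c * L = ln(sigma) = 1: about one
mutation per genome per replication. Above it, the stationary population
loses the master sequence entirely ("self-destruction of genetic
information").
"""

import math

from replicore import quasispecies as qs

landscape = qs.SinglePeakLandscape(L=100, sigma=math.e)
res = qs.find_error_threshold(landscape, p=0.0, epsilon=1e-3)
print(f"per-base critical rate mu_c = {res.mu_critical:.6f}")
print(f"genome-wide critical number mu_c * L = {res.genome_wide_rate:.4f}")
print("-> the population tolerates just under one mutation per genome per "
      "replication before the master class collapses below 1e-3.")

# master frequency on both sides of the threshold
for mu in (0.8 * res.mu_critical, 1.2 * res.mu_critical):
    x = qs.solve_stationary(landscape, qs.ReplicationKernel(mu=mu))
    print(f"stationary master frequency at mu = {mu:.5f}: {x[0]:.2e}")
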