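"""Show the error threshold moving up and disappearing as an error-free
replication channel is mixed in.

A fraction p of replication events use an error-less polymerase (the
leading-strand abstraction). Once sigma * p > 1, selection on the faithful
copies alone sustains the master sequence at any error rate: the threshold
is gone.
"""

from replicore import quasispecies as qs

table = qs.threshold_phase_table(
    sigma_grid=[2.0, 10.0], p_grid=[0.0, 0.2, 0.4, 0.6], L=50, tol=1e-4
)
print(table.to_string(index=False))
print("\nFor sigma = 2 the threshold rises with p and disappears at p = 0.6 "
      "(sigma*p = 1.2 > 1); for sigma = 10 any p >= 0.2 already removes it.")
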