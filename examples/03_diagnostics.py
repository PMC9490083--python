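"""Model evaluation: bootstrap, NPDE and prediction-corrected VPC.

On self-consistent data (evaluated by the model that generated it) the
bootstrap medians should track the point estimates, the NPDE should be close
to N(0,1) — the study reported mean 0.039 and variance 1 — and the observed
pcVPC medians should stay inside their simulation envelopes.
"""

import neocefpk as n
from neocefpk.diagnostics import bootstrap, npde, pcvpc
from neocefpk.estimate import FINAL_MODEL

data = n.make_fixture("study-like", seed=1)
fit = n.fit_model(data, settings=n.FitSettings(compute_rse=False))

boot = bootstrap(data, FINAL_MODEL, B=100, seed=2, warm_start=fit)
print(f"bootstrap ({boot.n_replicates} replicates, {boot.n_failed} failed):")
for k in ("theta_v", "theta_cl"):
    print(f"  {k}: estimate {getattr(fit, k):.4f}  "
          f"median {boot.median[k]:.4f}  5th-95th {boot.p5[k]:.4f}-{boot.p95[k]:.4f}")

nd = npde(fit, data, K=500, seed=3)
print(f"NPDE: mean {nd.mean:.3f}, variance {nd.variance:.3f} (target ~0, ~1)")

v = pcvpc(fit, data, n_sim=300, bins=6, seed=4)
print(f"pcVPC: observed median inside its 95% envelope in "
      f"{int(v.median_within_envelope.sum())}/6 bins")
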