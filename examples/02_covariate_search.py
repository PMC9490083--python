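"""Stepwise covariate selection on synthetic data with known truth.

The generator puts current weight (allometric, exponent 1.68) and postnatal
age (maturation, exponent 0.444) on clearance. Forward inclusion at
p < 0.05 (dOFV > 3.84) followed by backward elimination at p < 0.01
(dOFV > 6.635) should recover exactly those two covariates and reject
gestational and postmenstrual age, whose apparent effects are explained away
once weight and postnatal age are in the model.
"""

import neocefpk as n
from neocefpk.covsearch import stepwise_search
from neocefpk.estimate import BASE_MODEL, CovariateEffect

data = n.make_fixture("study-like", seed=1)
candidates = [
    CovariateEffect("CW", "cl", 2310.0),
    CovariateEffect("PNA", "cl", 1.0),
    CovariateEffect("GA", "cl", 35.7),
    CovariateEffect("PMA", "cl", 35.9),
]

trace = stepwise_search(data, BASE_MODEL, candidates)
print(f"base OFV {trace.base_ofv:.1f} -> final OFV {trace.final_ofv:.1f}")
for s in trace.steps:
    flag = "ACCEPT" if s.accepted else "reject"
    print(f"  {s.action:6s} {s.candidate:8s} dOFV {s.dofv:8.2f} vs {s.threshold:.2f}  {flag}")
print("selected:", [e.label for e in trace.final_spec.effects])
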