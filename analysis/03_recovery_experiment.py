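#!/usr/bin/env python
"""Scaled-down refinement recovery experiment.

Refines a random box of isolated molecules against the noise-free S(Q) of
a fixture made entirely of singly hydrogen-bonded pairs (donor-acceptor
coordination n_O2-O1(3.2 A) = 0.5) and reports how closely the refined
ensemble recovers that coordination number, together with the fit-metric
trace and the depth the empirical O-O perturbation settled at.  Writes
results/recovery/recovery.json and the per-cycle trace as CSV.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from epsrlite.experiments import recovery_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "recovery"
OUT.mkdir(parents=True, exist_ok=True)

res = recovery_experiment(seed=7)

(OUT / "recovery.json").write_text(json.dumps({
    "n_target": res.n_target,
    "n_recovered": res.n_recovered,
    "final_r_factor": res.r_trace[-1],
    "initial_r_factor": res.r_trace[0],
    "u_oo_contact_kj_mol": res.u_oo_contact,
}, indent=2) + "\n")

with open(OUT / "trace.csv", "w") as fh:
    fh.write("cycle,r_factor,n_O2_O1\n")
    for k, (r, n) in enumerate(zip(res.r_trace, res.n_trace)):
        fh.write(f"{k},{r!r},{n!r}\n")

print(f"target n_O2-O1(3.2) = {res.n_target:.3f}")
print(f"recovered           = {res.n_recovered:.3f}")
print(f"R-factor {res.r_trace[0]:.4f} -> {res.r_trace[-1]:.4f}")
print(f"empirical O-O energy at contact: {res.u_oo_contact:.2f} kJ/mol")
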