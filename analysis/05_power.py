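"""Simulation-based power of the MR design at the modelled study's scale.

Simulates the study design (2,001 cases / 2,237 controls, overall-allele-
score first-stage F ~ 16) under a true protective effect equal to the
observed top-vs-bottom-quintile OR of 0.47 per SD of 25-OHD, and measures
how often the IV analysis rejects OR = 1.  The result — well below 0.8 —
shows why a null MR finding at this sample size is uninformative about a
true effect of this magnitude.
"""

import argparse
import json
from pathlib import Path

from vitdmr import diagnostics

def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--reps", type=int, default=300)
    ap.add_argument("--estimator", default="control_function")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = diagnostics.study_power_config(seed=args.seed)
    res = diagnostics.power_simulation(
        config, estimator=args.estimator, reps=args.reps, n_boot=200,
        seed=args.seed)
    print(f"power of the {args.estimator} MR analysis at the study design: "
          f"{res.power:.2f} (MC-SE {res.mc_se:.3f}, {res.n_replicates} replicates)")
    print("true causal effect simulated: OR "
          f"{0.47:.2f} per SD of 25-OHD; alpha = {res.alpha}")
    (args.out / "power.json").write_text(json.dumps({
        "power": res.power, "mc_se": res.mc_se, "reps": res.n_replicates,
        "estimator": res.estimator, "alpha": res.alpha}, indent=2))

if __name__ == "__main__":
    main()
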