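"""Instrumental-variable estimates of the causal odds ratio on the synthetic cohort.

Runs the full instrument x adjustment grid of the control-function estimator
(the study's primary method) plus the four supplementary estimators (Wald
ratio, two-stage, multiplicative and logistic structural mean models) on the
confounded-null synthetic cohort.  Because psi = 0 in the generator, every
consistent estimator should hover near OR 1.00/ng/ml while the naive
observational model does not.
"""

import argparse
from pathlib import Path

from vitdmr import SimulationConfig, prepare_phenotype, run_table4
from vitdmr import association, genetics
from vitdmr.report import write_table
from vitdmr.simulate import generate_cohort

def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--reps", type=int, default=500, help="bootstrap resamples")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = prepare_phenotype(generate_cohort(SimulationConfig(seed=args.seed)))
    cohort = genetics.add_allele_scores(cohort)

    naive = association.logistic_or(cohort, "x_std")
    print(f"naive logistic OR per ng/ml: {naive.estimate:.3f} "
          f"({naive.ci_low:.3f}, {naive.ci_high:.3f}) - confounded by construction")

    grid = run_table4(
        cohort,
        estimators=("control_function", "wald", "two_stage", "msmm", "lsmm"),
        n_boot=args.reps, seed=args.seed)
    write_table(grid, args.out / "iv_estimates",
                "IV causal odds ratios per ng/ml 25-OHD (true value 1.00)")
    show = grid[grid["method"] == "control_function"]
    print(show[["instrument", "adjusted", "or_per_unit", "ci_low", "ci_high",
                "f_stat", "weak"]].round(3).to_string(index=False))
    n_bad = int((grid["note"] != "").sum())
    print(f"{len(grid)} estimator rows, {n_bad} non-estimable "
          "(weak instruments are estimated but flagged)")

if __name__ == "__main__":
    main()
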