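"""Observational association analyses on published counts and the synthetic cohort.

Part 1 reproduces the modelled study's printed contingency-table and grouped
per-allele odds ratios exactly from its published counts (deficiency 0.62;
top-vs-bottom quintile 0.47; rs2282679 per-A-allele deficiency 0.88;
rs12785878 per-T 0.89).  Part 2 runs the same model suite — crude, age+sex
(model I) and fully adjusted (model II) logistic regressions, quintile trend,
stratified analyses and the genotype x 25-OHD interaction LRT — on the
synthetic cohort, where the inverse association is pure confounding by
construction.
"""

import argparse
from pathlib import Path

import pandas as pd

from vitdmr import (SimulationConfig, contingency_or, per_allele_or,
                    prepare_phenotype, stratified_analysis, interaction_lrt,
                    trend_test)
from vitdmr import association, published
from vitdmr.report import or_results_frame, write_table
from vitdmr.simulate import generate_cohort

def published_part(out: Path) -> None:
    rows = {}
    b = published.TABLE1_BINARY
    rows["25-OHD >=10 vs <10 ng/ml"] = contingency_or(
        (b["sufficient"], b["deficient"]))
    q = published.TABLE1_QUINTILES
    rows["25-OHD top vs bottom quintile"] = contingency_or((q[4], q[0]))
    for snp, counts in published.TABLE2_DEFICIENCY.items():
        rows[f"{snp} per raising allele (deficiency)"] = per_allele_or(
            [c[0] for c in counts], [c[1] for c in counts])
    frame = or_results_frame(rows)
    write_table(frame, out / "published_association",
                "Odds ratios recomputed from published counts")
    print(frame[["label", "or", "ci_low", "ci_high"]].round(2).to_string(index=False))

def synthetic_part(out: Path, seed: int) -> None:
    cohort = prepare_phenotype(generate_cohort(SimulationConfig(seed=seed)))
    rows = {}
    for model in ("crude", "modelI", "modelII"):
        rows[f"25-OHD continuous ({model})"] = association.logistic_or(
            cohort, "x_std", model_label=model)
    frame = or_results_frame(rows)
    write_table(frame, out / "synthetic_association",
                "Observational models on the synthetic cohort (per ng/ml)")
    p_trend = trend_test(cohort["quintile"], cohort["y"])
    strat = stratified_analysis(cohort, "sex")
    stat, df, p_int = interaction_lrt(cohort, "rs10741657")
    print(frame[["label", "or", "ci_low", "ci_high"]].round(3).to_string(index=False))
    print(f"quintile trend p = {p_trend:.2e}")
    for level, r in strat.items():
        print(f"  sex={level}: OR {r.estimate:.3f} ({r.ci_low:.3f}, {r.ci_high:.3f})")
    print(f"rs10741657 x 25-OHD interaction LRT: chi2={stat:.2f} (df={df}), p={p_int:.2f}")
    sd = cohort["x_std"].std()
    crude = rows["25-OHD continuous (crude)"].estimate
    print(f"synthetic crude OR per SD ({sd:.1f} ng/ml): {crude ** sd:.2f} "
          "- confounding alone reproduces the observational inverse association")

def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    published_part(args.out)
    synthetic_part(args.out, args.seed)

if __name__ == "__main__":
    main()
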