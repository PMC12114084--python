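"""Run the bidirectional MR analysis over the simulated study.

Forward: each simulated taxon against the allergy outcome. Reverse: the
allergy trait against each taxon outcome. Produces the combined result
table, a report shaped like a standard MR summary (id, method, p, OR, CI,
n SNP), per-pair diagnostics, scatter-plot data series, the shared-SNP
overlap report, and the attrition log; everything under results/.

Run analysis/01_simulate_cohorts.py first.
"""

import json
from pathlib import Path

import pandas as pd

from tsmr.pipeline import AnalysisPlan, PipelineConfig, run_plan, scatter_data, shared_snp_report
from tsmr.sumstats import read_sumstats, write_results

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "sim_study"
ANALYSIS_SEED = 7_202_6


def main() -> None:
    config = PipelineConfig(n_boot=5000, presso_nsim=1000, seed=ANALYSIS_SEED)

    fwd_dir = STUDY / "forward"
    taxa = [
        read_sumstats(p, trait_id=p.stem)
        for p in sorted(fwd_dir.glob("*.tsv"))
        if p.stem != "food_allergy"
    ]
    allergy = read_sumstats(fwd_dir / "food_allergy.tsv", trait_id="food_allergy", trait_type="binary")
    forward_plan = AnalysisPlan(exposures=taxa, outcomes=[allergy], direction="forward", config=config)
    fwd_df, fwd_pairs = run_plan(forward_plan)

    rev_dir = STUDY / "reverse"
    allergy_exp = read_sumstats(rev_dir / "food_allergy.tsv", trait_id="food_allergy", trait_type="binary")
    taxa_out = [
        read_sumstats(p, trait_id=p.stem)
        for p in sorted(rev_dir.glob("*.tsv"))
        if p.stem != "food_allergy"
    ]
    # roles are already swapped in the input layout, so direction=forward here
    reverse_plan = AnalysisPlan(
        exposures=[allergy_exp], outcomes=taxa_out, direction="forward", config=config
    )
    rev_df, rev_pairs = run_plan(reverse_plan)
    rev_df["direction"] = "reverse"
    for pr in rev_pairs:
        pr.direction = "reverse"

    results = pd.concat([fwd_df, rev_df], ignore_index=True)
    results.to_csv(ROOT / "mr_results.tsv", sep="\t", index=False)

    report_rows = [
        (pr.exposure_id if pr.direction == "forward" else pr.outcome_id, est)
        for pr in fwd_pairs + rev_pairs
        if pr.analyzable
        for est in pr.estimates
    ]
    write_results(report_rows, ROOT / "mr_report.tsv")

    diagnostics = {}
    scatter_dir = ROOT / "scatter_data"
    scatter_dir.mkdir(parents=True, exist_ok=True)
    attrition_rows = []
    for pr in fwd_pairs + rev_pairs:
        key = f"{pr.direction}:{pr.exposure_id}->{pr.outcome_id}"
        diagnostics[key] = {
            "attrition": pr.attrition,
            "not_analyzable": pr.not_analyzable,
            "sensitivity": pr.sensitivity.to_dict() if pr.sensitivity else None,
        }
        attrition_rows.append({"pair": key, **pr.attrition, "note": pr.not_analyzable or ""})
        if pr.analyzable:
            scatter_data(pr).to_csv(
                scatter_dir / f"{key.replace(':', '_').replace('->', '_to_')}.tsv",
                sep="\t",
                index=False,
            )
    (ROOT / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    pd.DataFrame(attrition_rows).to_csv(ROOT / "attrition.tsv", sep="\t", index=False)

    instrument_sets = {
        pr.outcome_id: [i.snp_id for i in pr.instruments if i.kept]
        for pr in rev_pairs
        if pr.analyzable
    }
    if len(instrument_sets) >= 2:
        shared = shared_snp_report(instrument_sets)
        shared.to_csv(ROOT / "shared_snps.tsv", sep="\t", index=False)

    truth = json.loads((STUDY / "truth.json").read_text())
    print("=== bidirectional MR over the simulated study ===")
    ivw_rows = results[results.method == "ivw"]
    for _, row in ivw_rows.iterrows():
        taxon = row.exposure if row.direction == "forward" else row.outcome
        t = truth.get(taxon, truth.get(f"reverse:{taxon}", {}))
        print(
            f"{row.direction:8s} {taxon:32s} IVW OR {row['or']:.3f} "
            f"({row.ci_low:.3f}-{row.ci_high:.3f}) p {row.p:.3g} nSNP {row.n_snp}"
            + (f"  [true OR {t['true_or']:.3f}]" if t else "")
        )
    na = results[results.note != ""]
    for _, row in na.iterrows():
        print(f"{row.direction:8s} {row.exposure:32s} not analyzable: {row.note}")
    print(f"tables written under {ROOT}")


if __name__ == "__main__":
    main()
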