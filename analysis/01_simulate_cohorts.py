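"""Build the synthetic two-sample MR study used by the downstream analyses.

Forward direction: five simulated microbiota taxa (one protective with true
OR 0.65, one risk-increasing with true OR 1.54, two true nulls, and one
null taxon carrying a deliberately weak instrument) against one combined
binary "allergy" outcome GWAS. Reverse direction: the allergy trait as
exposure with four instruments against two taxon outcomes generated from
the same instrument draws, so they share all four SNPs — the situation
where two taxa cannot be read as independent signals.

Writes tab-delimited summary statistics and truth sidecars under
results/sim_study/.
"""

import json
import math
from dataclasses import replace
from pathlib import Path

from tsmr.simulate import SimScenario, simulate_pair
from tsmr.sumstats import TraitTable, write_sumstats

STUDY_SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "sim_study"

FORWARD_TAXA = {
    # trait id -> (seed offset, true causal effect on ln(OR) scale)
    "c_Verrucomicrobiae_like": (1, math.log(0.65)),
    "g_LachnospiraceaeUCG004_like": (2, math.log(1.541)),
    "g_null_taxon_a": (3, 0.0),
    "g_null_taxon_b": (4, 0.0),
    "g_weak_instrument_taxon": (5, 0.0),
}

REVERSE_TAXA = {
    # both generated from the same seed: identical instruments, shared SNPs
    "g_Adlercreutzia_like": math.log(0.856),
    "g_Olsenella_like": math.log(0.802),
}


def main() -> None:
    forward_dir = OUT / "forward"
    reverse_dir = OUT / "reverse"
    forward_dir.mkdir(parents=True, exist_ok=True)
    reverse_dir.mkdir(parents=True, exist_ok=True)

    outcome_records = []
    truths = {}
    for trait_id, (offset, beta_causal) in FORWARD_TAXA.items():
        scen = SimScenario(
            seed=STUDY_SEED + offset,
            beta_causal=beta_causal,
            exposure_id=trait_id,
            outcome_id="food_allergy",
        )
        exposure, outcome, truth = simulate_pair(scen)
        if trait_id == "g_weak_instrument_taxon":
            # one instrument with a tiny effect but a confident p-value:
            # it survives selection and must die at the F >= 10 filter
            rec = exposure.records[0]
            exposure.records[0] = replace(rec, beta=0.005, se=0.012, pvalue=1e-9)
        write_sumstats(exposure, forward_dir / f"{trait_id}.tsv")
        outcome_records.extend(outcome.records)
        truths[trait_id] = {"beta_causal": beta_causal, "true_or": math.exp(beta_causal)}

    allergy = TraitTable(
        trait_id="food_allergy", trait_type="binary", records=outcome_records
    )
    write_sumstats(allergy, forward_dir / "food_allergy.tsv")

    # reverse: allergy as exposure (large GWAS, 4 instruments), taxa as outcomes
    for trait_id, beta_causal in REVERSE_TAXA.items():
        scen = SimScenario(
            seed=STUDY_SEED + 100,  # same seed for both: shared instruments
            n_snp=4,
            beta_causal=beta_causal,
            n_exposure=169_716,
            n_outcome=14_263,
            gamma_range=(0.03, 0.08),  # plausible effect sizes for a 170k GWAS
            exposure_id="food_allergy",
            outcome_id=trait_id,
        )
        exposure, outcome, truth = simulate_pair(scen)
        if not (reverse_dir / "food_allergy.tsv").exists():
            write_sumstats(exposure, reverse_dir / "food_allergy.tsv")
        write_sumstats(outcome, reverse_dir / f"{trait_id}.tsv")
        truths[f"reverse:{trait_id}"] = {
            "beta_causal": beta_causal,
            "true_or": math.exp(beta_causal),
        }

    (OUT / "truth.json").write_text(json.dumps(truths, indent=2))
    n_files = len(list(forward_dir.glob("*.tsv"))) + len(list(reverse_dir.glob("*.tsv")))
    print(f"simulated study written to {OUT} ({n_files} summary-statistics tables)")
    print("true effects:", json.dumps(truths, indent=2))


if __name__ == "__main__":
    main()
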