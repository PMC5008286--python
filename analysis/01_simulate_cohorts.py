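#!/usr/bin/env python
"""Generate the synthetic study: methylation cohort, triads, clones, Ct, survival.

Writes the study-sized dataset (8 normal bone / 23 early-onset / 9 late-onset
tumors) plus a 1000-per-group calibration cohort used by the recovery
analyses, all under results/data/.
"""

from pathlib import Path

from imprintscore.io import write_table
from imprintscore.scoring import score_cohort
from imprintscore.synthetic_data import (
    SimulationConfig,
    simulate_clones,
    simulate_cohort,
    simulate_outcomes,
    simulate_triads,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = SimulationConfig(seed=SEED)
    meth = simulate_cohort(study)
    write_table(meth, OUT / "methylation.tsv")
    study.to_json(str(OUT / "sim_config.json"))

    calib = study.replace(n_per_group=1000)
    write_table(simulate_cohort(calib), OUT / "methylation_calibration.tsv")

    write_table(simulate_triads(10, study), OUT / "triads.tsv")
    write_table(simulate_triads(5000, calib), OUT / "triads_calibration.tsv")

    clones = simulate_clones(study.p_meth_dense, study.p_meth_sparse,
                             study.n_clones, study.n_cpg,
                             study.conversion_efficiency, seed=SEED)
    clones.to_fasta(str(OUT / "reference.fa"), str(OUT / "clones.fa"))

    scores = score_cohort(meth)
    index = scores.set_index("sample_id")["fourteen_q_index"]
    ct, surv = simulate_outcomes(index, study)
    write_table(ct, OUT / "expression_ct.tsv")
    write_table(surv, OUT / "survival.tsv")

    print(f"wrote synthetic study (seed {SEED}) to {OUT}")
    print(f"  samples: {meth['sample_id'].nunique()}  rows: {len(meth)}")


if __name__ == "__main__":
    main()
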