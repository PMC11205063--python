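#!/usr/bin/env python
"""Simulate the two synthetic cohorts the downstream analyses use.

Cohort A (cross-sectional): two knowledge groups, one timepoint, with the
high-knowledge group's planted semantic network less rewired (more
clustered) than the low-knowledge group's.  Cohort B (longitudinal): the
same two groups measured at two timepoints, each cell with its own planted
network.  Writes pipeline-ready CSVs plus ground-truth tables under
results/data/.
"""

from pathlib import Path

from fluencynet import default_config, simulate_study

OUT = Path("results/data")
SEED = 20240901


def write(study: dict, name: str) -> None:
    out = OUT / name
    out.mkdir(parents=True, exist_ok=True)
    study["fluency"].to_csv(out / "fluency.csv", index=False)
    study["scores"].to_csv(out / "scores.csv", index=False)
    study["group_truth"].to_csv(out / "group_truth.csv", index=False)
    study["network_truth"].to_csv(out / "network_truth.csv", index=False)
    n = study["fluency"]["participant_id"].nunique()
    print(f"{name}: {n} participants, {len(study['fluency'])} responses "
          f"-> {out}")


def main() -> None:
    cross = default_config(master_seed=SEED, participants_per_group=60,
                           n_words=60)
    write(simulate_study(cross), "cross_sectional")

    longi = default_config(master_seed=SEED + 1, participants_per_group=60,
                           n_words=60, timepoints=("T1", "T2"))
    write(simulate_study(longi), "longitudinal")


if __name__ == "__main__":
    main()
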