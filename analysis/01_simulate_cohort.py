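"""Simulate the dose-escalation cohort: 21 patients over 6 cohorts.

Draws per-patient dosing and baseline covariates from the escalation plan
and per-cohort demographics, and writes the baseline table.
"""

import argparse
from pathlib import Path

from cedose.io import write_table
from cedose.pipeline import _spawn_seeds
from cedose.synthetic import simulate_covariates


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cov_seed = _spawn_seeds(args.seed, 4)[0]
    patients = simulate_covariates(seed=cov_seed)
    path = write_table(patients, args.results / "cohort_baseline.csv")

    print(f"simulated {len(patients)} patients across {patients['cohort'].nunique()} cohorts")
    print(patients.groupby("cohort")[["administered_mCi", "infused_mL"]].first())
    print(
        f"age {patients['age_y'].mean():.1f} +/- {patients['age_y'].std():.1f} y; "
        f"tumor volume {patients['baseline_tumor_mL'].mean():.1f} mL "
        f"({patients['baseline_tumor_mL'].min():.1f}-{patients['baseline_tumor_mL'].max():.1f})"
    )
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
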