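"""Simulate a case/control cohort and its raw biochip measurements.

Generates a 400-sample cohort (200 lung-cancer cases, 200 controls) with five
planted effect epitopes (natural-log effect 1.0) and a COPD-linked confounder
on one non-effect epitope, runs it through the QP300 biochip layout with the
default noise model, and writes the raw measurement table, the sample
metadata, and the true abundance matrix.
"""

import argparse
from pathlib import Path

from epitomics import biochip, synthetic

EFFECTS = [(f"mab_{i:03d}", 1.0) for i in range(1, 6)]
CONFOUNDERS = {"copd_grade": {"mab_010": 0.5}}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--layout", choices=["qp69", "qp300"], default="qp300")
    ap.add_argument("--n-cases", type=int, default=200)
    ap.add_argument("--n-controls", type=int, default=200)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = synthetic.CohortConfig(
        n_cases=args.n_cases, n_controls=args.n_controls, n_mabs=20,
        effect_mabs=EFFECTS, confounder_effects=CONFOUNDERS, seed=args.seed,
    )
    meta, abundance = synthetic.generate_cohort(cfg)
    run = synthetic.generate_biochip_runs(
        abundance, args.layout.upper(), synthetic.NoiseModel(), seed=args.seed + 1
    )

    meta.to_csv(args.out_dir / "metadata.tsv", sep="\t")
    abundance.to_csv(args.out_dir / "abundance_truth.tsv", sep="\t")
    biochip.write_measurements(run, args.out_dir / "measurements.tsv")
    n_runs = run.records["run_id"].nunique()
    print(
        f"simulated {len(meta)} samples x {abundance.shape[1]} mAbs "
        f"({len(EFFECTS)} planted effects), {n_runs} {args.layout.upper()} runs, "
        f"{len(run.records)} raw records -> {args.out_dir}"
    )


if __name__ == "__main__":
    main()
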