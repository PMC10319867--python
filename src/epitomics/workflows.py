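"""End-to-end convenience drivers composing the pipeline stages.

These functions wire the stages together the way the analysis scripts and the
calibration tests use them: cohort simulation -> raw biochip runs ->
normalization -> replicate aggregation -> feature matrix, and the pooled
differential screen run through the same measurement path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from epitomics import biochip, screening, synthetic

__all__ = ["simulate_feature_matrix", "pooled_screen"]


def simulate_feature_matrix(
    config: synthetic.CohortConfig,
    noise: synthetic.NoiseModel | None = None,
    layout_kind: str = "QP300",
    run_seed: int | None = None,
    n_replicates: int = 3,
):
    """Simulate a cohort and push it through normalization to a feature matrix.

    Returns (features, labels, metadata): ``features`` is the sample x mAb
    RLU/RLUmax % matrix at the layout's reference dilution after replicate
    averaging and the 120 cap; ``labels`` is 1 for cases.
    """
    noise = noise if noise is not None else synthetic.NoiseModel()
    meta, abundance = synthetic.generate_cohort(config)
    run = synthetic.generate_biochip_runs(
        abundance,
        layout_kind,
        noise,
        seed=config.seed + 1 if run_seed is None else run_seed,
        n_replicates=n_replicates,
    )
    profile = biochip.normalize_run(run)
    agg = biochip.aggregate_replicates(profile)
    ref_dilution = agg.values["dilution"].min()
    features = agg.matrix(dilution=ref_dilution).loc[meta.index]
    labels = (meta["group"] == "case").astype(int).to_numpy()
    return features, labels, meta


def pooled_screen(
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    noise: synthetic.NoiseModel | None = None,
    layout_kind: str = "QP300",
    seed: int = 0,
    rel_threshold: float = 0.30,
    n_repeats: int = 3,
) -> screening.DifferentialSelection:
    """Differential screen of physically pooled case vs control samples.

    Pooling mixes equal plasma volumes, so the pool's epitope abundance is the
    arithmetic mean over its members. Each pool is measured ``n_repeats``
    times through the biochip path, repeat profiles are averaged, and the
    >30 %-of-control selection rule is applied.
    """
    noise = noise if noise is not None else synthetic.NoiseModel.noise_free()
    pools = pd.DataFrame(
        {
            "pool_case": abundance[meta["group"] == "case"].mean(axis=0),
            "pool_control": abundance[meta["group"] == "control"].mean(axis=0),
        }
    ).T
    run = synthetic.generate_biochip_runs(
        pools, layout_kind, noise, seed=seed, n_replicates=n_repeats
    )
    agg = biochip.aggregate_replicates(biochip.normalize_run(run))
    ref_dilution = agg.values["dilution"].min()
    matrix = agg.matrix(dilution=ref_dilution)
    case_pool = screening.PoolProfile("pool_case", matrix.loc["pool_case"], n_repeats=n_repeats)
    ctrl_pool = screening.PoolProfile("pool_control", matrix.loc["pool_control"], n_repeats=n_repeats)
    return screening.differential_mabs(ctrl_pool, case_pool, rel_threshold=rel_threshold)
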