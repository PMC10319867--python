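"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data-shaped world of a plasma epitome profiling
study:

- a case/control cohort with log-normally distributed epitope abundances,
  planted log-fold case effects on chosen mAbs, and confounder-linked effects
  (COPD grade, sex, BMI class, smoking pack-year class);
- raw biochip runs in the QP69 (18 positions, 2 tracer-only) or QP300
  (3 positions, 1 tracer-only) layout, where a sample's RLU follows the
  one-site competitive transfer function RLU = RLUmax / (1 + abundance/k50)
  (more epitope -> more tracer competed off -> lower signal), multiplied by
  log-normal noise components (intra-replicate, run, operator, lot);
- mimotope peptide sets with redundant pairs planted at a target shared
  clone fraction s, so the pair's RedXY is s^2 * 100 by construction;
- 4PL inhibition curves and two-state SPR sensorgrams, noise-free curves
  being exact model evaluations.

Everything is a pure function of (config, seed): the same inputs give
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from epitomics.biochip import LAYOUTS, MEASUREMENT_COLUMNS, BiochipRun
from epitomics.mimotopes import MimotopeSet
from epitomics.qualification import four_pl
from epitomics.spr import Sensorgram, TwoStateParams, simulate_two_state

__all__ = [
    "CohortConfig",
    "NoiseModel",
    "RedundancySpec",
    "ConfigurationError",
    "generate_cohort",
    "generate_biochip_runs",
    "generate_mimotope_sets",
    "planted_redundancy_library",
    "generate_inhibition_curves",
    "generate_sensorgrams",
    "load_cohort_config",
    "mab_ids",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: metadata categories mirroring the clinical cohort coding
COPD_GRADES = ["non_copd", "A", "B", "C", "D"]
BMI_CLASSES = ["A", "B", "C"]                      # <20 / 20-30 / >30 kg/m2
SMOKING_CLASSES = ["non_smoker", "A", "B", "C", "D"]  # pack-year bands
STAGES = ["I", "II", "IIIA", "IIIB", "IV"]
HISTOLOGY_CODES = list(range(11))                  # 0-10 per the cohort coding

#: which level(s) of a metadata field count as "exposed" for confounder effects
CONFOUNDER_EXPOSED = {
    "copd_grade": {"C", "D"},
    "sex": {"male"},
    "bmi_class": {"C"},
    "smoking_class": {"C", "D"},
}


class ConfigurationError(ValueError):
    """Invalid generator configuration (e.g. unknown effect mAb id)."""


def mab_ids(n: int) -> list[str]:
    return [f"mab_{i:03d}" for i in range(1, n + 1)]


@dataclass
class NoiseModel:
    """Fractional CVs of the multiplicative log-normal noise components.

    The magnitudes are calibration choices (the assay's qualification gate is
    CV < 20%, with no published component values): intra-replicate 8%, the
    shared run/operator/lot components 5% each. All zero means noise-free.
    """

    cv_intra: float = 0.08
    cv_inter_run: float = 0.05
    cv_operator: float = 0.05
    cv_lot: float = 0.05

    def __post_init__(self) -> None:
        for name in ("cv_intra", "cv_inter_run", "cv_operator", "cv_lot"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @classmethod
    def noise_free(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the requested fractional CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


@dataclass
class CohortConfig:
    n_cases: int = 200
    n_controls: int = 200
    n_mabs: int = 20
    effect_mabs: list = field(default_factory=list)        # [(mab_id, log-fold effect)]
    confounder_effects: dict = field(default_factory=dict)  # field -> {mab_id: effect}
    baseline_log_mean: float = 0.0   # abundance ~ lognormal, in units of k50
    baseline_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("need n_cases >= 1 and n_controls >= 1")
        ids = set(mab_ids(self.n_mabs))
        for mab, _ in self.effect_mabs:
            if mab not in ids:
                raise ConfigurationError(f"effect mAb {mab!r} not among the {self.n_mabs} mAbs")
        for fld, effects in self.confounder_effects.items():
            if fld not in CONFOUNDER_EXPOSED:
                raise ConfigurationError(
                    f"unknown confounder field {fld!r}; known: {sorted(CONFOUNDER_EXPOSED)}"
                )
            for mab in effects:
                if mab not in ids:
                    raise ConfigurationError(f"confounder mAb {mab!r} not among the {self.n_mabs} mAbs")


def load_cohort_config(path) -> CohortConfig:
    """Read a CohortConfig from a YAML/JSON document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "effect_mabs" in doc:
        doc["effect_mabs"] = [tuple(e) for e in doc["effect_mabs"]]
    return CohortConfig(**doc)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample metadata and the true (noise-free) abundance matrix.

    Abundances are log-normal per mAb; case samples of an effect mAb are
    multiplied by exp(effect), and samples whose metadata level is "exposed"
    for a configured confounder field are multiplied by exp(effect) for the
    confounded mAbs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    sample_ids = [f"s{i:04d}" for i in range(1, n + 1)]
    group = ["case"] * config.n_cases + ["control"] * config.n_controls
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "sex": rng.choice(["female", "male"], size=n),
            "age": rng.integers(40, 80, size=n),
            "copd_grade": rng.choice(COPD_GRADES, size=n, p=[0.45, 0.12, 0.2, 0.11, 0.12]),
            "bmi_class": rng.choice(BMI_CLASSES, size=n, p=[0.12, 0.65, 0.23]),
            "smoking_class": rng.choice(SMOKING_CLASSES, size=n, p=[0.2, 0.05, 0.06, 0.13, 0.56]),
        }
    ).set_index("sample_id")
    meta["stage"] = [
        rng.choice(STAGES) if g == "case" else "not_applicable" for g in group
    ]
    meta["histology_code"] = [
        int(rng.choice(HISTOLOGY_CODES)) if g == "case" else -1 for g in group
    ]

    mabs = mab_ids(config.n_mabs)
    log_ab = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=(n, config.n_mabs))
    abundance = pd.DataFrame(np.exp(log_ab), index=meta.index, columns=mabs)
    is_case = (meta["group"] == "case").to_numpy()
    for mab, effect in config.effect_mabs:
        abundance.loc[is_case, mab] *= np.exp(effect)
    for fld, effects in config.confounder_effects.items():
        exposed = meta[fld].isin(CONFOUNDER_EXPOSED[fld]).to_numpy()
        for mab, effect in effects.items():
            abundance.loc[exposed, mab] *= np.exp(effect)
    return meta, abundance


def generate_biochip_runs(
    abundances: pd.DataFrame,
    layout_kind: str,
    noise: NoiseModel,
    seed: int,
    n_replicates: int = 3,
    rlumax: float = 10000.0,
    k50: float = 1.0,
    dilutions: tuple | None = None,
    n_operators: int = 2,
    n_lots: int = 2,
) -> BiochipRun:
    """Raw biochip measurement records for a cohort's abundance matrix.

    Each replicate pass lays the samples out across runs of the requested
    layout (QP69: 16 sample + 2 tracer positions, QP300: 2 sample + 1 tracer).
    Reference dilutions are 100x/1000x for QP69 and 300x for QP300; the
    effective competing abundance scales with the reference/actual dilution
    ratio. Sample signal:

        RLU = rlumax / (1 + abundance_eff / k50)
              * intra * run * operator * lot noise factors

    Tracer-only positions see no competition (abundance 0 -> RLU = rlumax
    times the same run-level factors), so per-run normalization cancels the
    shared components exactly.
    """
    if layout_kind not in LAYOUTS:
        raise ConfigurationError(f"unknown layout {layout_kind!r}")
    total_pos, tracer_pos = LAYOUTS[layout_kind]
    sample_pos = total_pos - tracer_pos
    if dilutions is None:
        dilutions = (100.0, 1000.0) if layout_kind == "QP69" else (300.0,)
    ref_dilution = min(dilutions)
    rng = np.random.default_rng(seed)
    sample_ids = list(abundances.index)
    mabs = list(abundances.columns)
    rows = []
    run_counter = 0
    for rep in range(1, n_replicates + 1):
        for dilution in dilutions:
            for block_start in range(0, len(sample_ids), sample_pos):
                run_counter += 1
                run_id = f"run_{run_counter:04d}"
                operator = f"op_{rng.integers(1, n_operators + 1)}"
                lot = f"lot_{rng.integers(1, n_lots + 1)}"
                run_f = _lognormal_factor(rng, noise.cv_inter_run)
                op_f = _lognormal_factor(rng, noise.cv_operator)
                lot_f = _lognormal_factor(rng, noise.cv_lot)
                shared = run_f * op_f * lot_f
                block = sample_ids[block_start : block_start + sample_pos]
                # tracer-only positions occupy the first slots of the run
                for pos in range(1, tracer_pos + 1):
                    intra = _lognormal_factor(rng, noise.cv_intra, size=len(mabs))
                    for mab, f in zip(mabs, intra):
                        rows.append(
                            ("", mab, run_id, 1 + (pos - 1) // 9, pos, "tracer_only",
                             operator, lot, np.nan, rep, rlumax * shared * f)
                        )
                for k, sid in enumerate(block):
                    pos = tracer_pos + 1 + k
                    ab_eff = abundances.loc[sid].to_numpy() * (ref_dilution / dilution)
                    signal = rlumax / (1.0 + ab_eff / k50)
                    intra = _lognormal_factor(rng, noise.cv_intra, size=len(mabs))
                    for mab, s, f in zip(mabs, signal, intra):
                        rows.append(
                            (sid, mab, run_id, 1 + (pos - 1) // 9, pos, "sample",
                             operator, lot, dilution, rep, s * shared * f)
                        )
    records = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return BiochipRun(layout_kind=layout_kind, records=records)


@dataclass
class RedundancySpec:
    """Planted redundancy structure for mimotope generation.

    Each listed pair shares one peptide present at the target clone fraction
    in both members, so the pair's RedXY is target^2 * 100 by construction
    (up to clone-count rounding).
    """

    pairs: list = field(default_factory=list)  # [(mab_a, mab_b, target_shared_fraction)]
    clones_per_mab: int = 12
    peptide_length: int = 12

    def __post_init__(self) -> None:
        if self.clones_per_mab < 12:
            raise ConfigurationError("clones_per_mab must be >= 12 (phage sequencing depth)")
        for a, b, s in self.pairs:
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError(f"shared fraction for ({a}, {b}) must be in [0, 1]")


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_mimotope_sets(n_mabs: int, spec: RedundancySpec, seed: int) -> list[MimotopeSet]:
    """Mimotope sets with planted redundant pairs.

    Non-pair clones are unique random peptides (collisions over the 20^12
    space are negligible), giving RedXY ~ 0 for unplanted pairs.
    """
    ids = mab_ids(n_mabs)
    known = set(ids)
    for a, b, _ in spec.pairs:
        if a not in known or b not in known:
            raise ConfigurationError(f"pair ({a!r}, {b!r}) references unknown mAb ids")
    rng = np.random.default_rng(seed)
    shared_counts: dict[str, list] = {m: [] for m in ids}
    for a, b, s in spec.pairs:
        n_shared = int(round(s * spec.clones_per_mab))
        if n_shared > 0:
            pep = _random_peptide(rng, spec.peptide_length)
            shared_counts[a].append((pep, n_shared))
            shared_counts[b].append((pep, n_shared))
    sets = []
    for m in ids:
        peptides: dict[str, int] = {}
        used = 0
        for pep, cnt in shared_counts[m]:
            peptides[pep] = peptides.get(pep, 0) + cnt
            used += cnt
        for _ in range(max(spec.clones_per_mab - used, 0)):
            peptides[_random_peptide(rng, spec.peptide_length)] = 1
        sets.append(MimotopeSet(mab_id=m, peptides=peptides))
    return sets


def planted_redundancy_library(n_mabs: int = 173, seed: int = 0) -> list[MimotopeSet]:
    """A mAb library with a fully specified planted redundancy structure.

    Fifteen mAbs carry an off-diagonal RedXY partner above 40 %: one pair at
    exactly 92 (shared peptide at clone fractions 23/25 and 25/25), five
    symmetric pairs between ~46 and ~71, and one three-mAb chain whose middle
    member shares a different peptide with each end. All remaining mAbs get
    unique random 12-mers, so unplanted redundancies are 0 (up to negligible
    collision probability). Synthetic stand-in for a profiled library whose
    peptide lists are not distributed with this package.
    """
    if n_mabs < 15:
        raise ConfigurationError("planted structure needs at least 15 mAbs")
    rng = np.random.default_rng(seed)
    ids = mab_ids(n_mabs)
    sets: list[MimotopeSet] = []

    def uniques(k: int) -> dict:
        return {_random_peptide(rng, 12): 1 for _ in range(k)}

    # the maximal pair: Red = (23/25) * (25/25) * 100 = 92 exactly
    p_max = _random_peptide(rng, 12)
    sets.append(MimotopeSet(ids[0], {p_max: 23, **uniques(2)}))
    sets.append(MimotopeSet(ids[1], {p_max: 25}))
    # five symmetric pairs: Red = (n/25)^2 * 100 for n = 17..21 (46.24 .. 70.56)
    for k, n_shared in enumerate((17, 18, 19, 20, 21)):
        p = _random_peptide(rng, 12)
        sets.append(MimotopeSet(ids[2 + 2 * k], {p: n_shared, **uniques(25 - n_shared)}))
        sets.append(MimotopeSet(ids[3 + 2 * k], {p: n_shared, **uniques(25 - n_shared)}))
    # chain a-b-c: Red(a,b) = (20*13)/625*100 = 41.6, Red(b,c) = (12*22)/625*100 = 42.24
    p_ab, p_bc = _random_peptide(rng, 12), _random_peptide(rng, 12)
    sets.append(MimotopeSet(ids[12], {p_ab: 20, **uniques(5)}))
    sets.append(MimotopeSet(ids[13], {p_ab: 13, p_bc: 12}))
    sets.append(MimotopeSet(ids[14], {p_bc: 22, **uniques(3)}))
    # the rest of the library: no planted redundancy
    for m in ids[15:]:
        sets.append(MimotopeSet(m, uniques(12)))
    return sets


def generate_inhibition_curves(
    params_per_mab: dict,
    dilutions=(10.0, 30.0, 100.0, 300.0, 1000.0),
    noise_cv: float = 0.0,
    seed: int = 0,
    tracer_kind: str = "total_plasma",
) -> pd.DataFrame:
    """4PL inhibition curves: mab_id, tracer_kind, dilution, response.

    ``params_per_mab`` maps mab_id -> (a, b, c, d). Noise is multiplicative
    log-normal with fractional CV ``noise_cv``; noise-free responses are the
    exact 4PL evaluated at the dilutions.
    """
    dilutions = np.asarray(dilutions, dtype=float)
    if np.any(dilutions <= 0):
        raise ConfigurationError("dilutions must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for mab, (a, b, c, d) in params_per_mab.items():
        y = four_pl(dilutions, a, b, c, d)
        y = y * _lognormal_factor(rng, noise_cv, size=dilutions.size)
        for x, v in zip(dilutions, y):
            rows.append((mab, tracer_kind, float(x), float(v)))
    return pd.DataFrame(rows, columns=["mab_id", "tracer_kind", "dilution", "response"])


def generate_sensorgrams(
    params: TwoStateParams,
    concentrations,
    t_assoc: float = 180.0,
    t_dissoc: float = 120.0,
    step: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[Sensorgram]:
    """Two-state sensorgrams at an analyte concentration series.

    Noise is additive white Gaussian in RU; noise-free traces are the exact
    linear-ODE solution.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0):
        raise ConfigurationError("analyte concentrations must be positive")
    rng = np.random.default_rng(seed)
    grams = []
    for i, conc in enumerate(concentrations):
        g = simulate_two_state(
            params, float(conc), t_assoc=t_assoc, t_dissoc=t_dissoc, step=step,
            trace_id=f"trace_{i + 1}",
        )
        if noise_sd > 0:
            g.response = g.response + rng.normal(0.0, noise_sd, size=g.response.size)
        grams.append(g)
    return grams
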