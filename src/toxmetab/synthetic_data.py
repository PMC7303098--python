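"""Synthetic LC-HRMS feature tables with the structure of a HepaRG dosing study.

The generator emulates the statistical design the pipeline is built for:
three incubation groups (Blank 0 uM, Low 12.5 uM, High 25 uM) with nine
wells each, a pooled QC injected five times at the start of the sequence
and then once every five study samples, multiplicative injection-order
drift, lognormal measurement noise, zero/dropout below a detection limit,
a constant-level internal-standard channel (a tryptophan-d5 analog), and
drug-derived features (parent, 13C isotopologues, amino-acid adducts, a
metabolite) that are absent in Blank and proportional to dose.

It does not emulate chromatographic peak shapes, retention-time drift, or
multi-batch effects; a green downstream test therefore establishes
correctness of the statistics, not robustness to those artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formula_mass import (
    C13_C12_DELTA,
    ElementalFormula,
    IonSpec,
    PROTON,
    feature_name,
    imine_adduct_ion,
    ion_mz,
    parse_formula,
)
from .preprocess import FeatureTable

__all__ = ["SyntheticConfig", "GroundTruth", "generate_injection_sequence",
           "generate_experiment", "ALPHA_PBP", "GLYCINE", "ALANINE"]

ALPHA_PBP = parse_formula("C14H19NO")
GLYCINE = parse_formula("C2H5NO2")
ALANINE = parse_formula("C3H7NO2")


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated experimental world of the simulated dosing study.

    ``effect_size`` is the multiplicative fold-change per dose step for
    the dose-affected background features; drug-derived features instead
    scale proportionally to dose (Low = half of High) and are truly absent
    in Blank. ``drift_slope`` is the fractional sensitivity change per
    injection; ``noise_cv`` the lognormal coefficient of variation of a
    single measurement.
    """

    n_wells_per_group: int = 9
    group_doses: tuple[tuple[str, float], ...] = (("Blank", 0.0), ("Low", 12.5), ("High", 25.0))
    n_background_features: int = 500
    n_affected_features: int = 20
    n_drug_features: int = 8
    effect_size: float = 4.0
    drift_slope: float = 0.005
    noise_cv: float = 0.2
    dropout_lod: float = 1000.0
    isotopologue_ratio: float = 0.15
    qc_every: int = 5
    n_leading_qc: int = 5
    seed: int = 0

    def __post_init__(self):
        doses = [d for _, d in self.group_doses]
        if not all(a < b for a, b in zip(doses, doses[1:])):
            raise ValueError("group doses must be strictly increasing")
        if self.qc_every < 2:
            raise ValueError("qc_every must be >= 2")
        for name in ("effect_size", "drift_slope", "noise_cv", "dropout_lod",
                     "isotopologue_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the pipeline is supposed to recover from a synthetic table."""

    affected_feature_ids: list[str]
    drug_feature_ids: dict[str, str]  # feature id -> role (parent/isotopologue/adduct/metabolite)
    is_feature_id: str
    drift_profile: np.ndarray  # per-injection multiplier, index 0 = injection 1
    true_levels: pd.DataFrame | None = None  # samples x features, noise/drift-free


def generate_injection_sequence(cfg: SyntheticConfig) -> pd.DataFrame:
    """Run order: leading QCs, then randomized study samples with periodic QCs.

    Returns a DataFrame indexed by sample id with ``group`` and
    ``injection_index`` (consecutive from 1). Study wells are shuffled
    into a seeded random order; a QC follows every ``qc_every`` study
    samples, including one after a trailing partial block.
    """
    rng = np.random.default_rng(cfg.seed)
    study = [f"{g}_{w + 1}" for g, _ in cfg.group_doses for w in range(cfg.n_wells_per_group)]
    study = [study[i] for i in rng.permutation(len(study))]

    rows: list[tuple[str, str]] = []
    n_qc = 0

    def add_qc():
        nonlocal n_qc
        n_qc += 1
        rows.append((f"QC_{n_qc:02d}", "QC"))

    for _ in range(cfg.n_leading_qc):
        add_qc()
    for i, sid in enumerate(study, start=1):
        rows.append((sid, sid.rsplit("_", 1)[0]))
        if i % cfg.qc_every == 0:
            add_qc()
    if len(study) % cfg.qc_every != 0:
        add_qc()

    df = pd.DataFrame(rows, columns=["sample_id", "group"]).set_index("sample_id")
    df["injection_index"] = np.arange(1, len(df) + 1)
    return df


def _drug_feature_plan() -> list[dict]:
    """Planted drug-derived channels: the pyrrolidinophenone parent ion,
    its amino-acid adducts, one oxygenated metabolite, and the +1 13C
    companion of each."""
    parent_ion = IonSpec(neutral=ALPHA_PBP, adduct_delta=PROTON)
    gly_ion = imine_adduct_ion(ALPHA_PBP, GLYCINE)
    ala_ion = imine_adduct_ion(ALPHA_PBP, ALANINE)
    metab_ion = IonSpec(neutral=ALPHA_PBP + ElementalFormula({"O": 1}), adduct_delta=PROTON)
    base = [
        ("parent", ion_mz(parent_ion), 222.0, 5e5),
        ("adduct", ion_mz(gly_ion), 249.0, 8e4),
        ("adduct", ion_mz(ala_ion), 265.0, 6e4),
        ("metabolite", ion_mz(metab_ion), 217.0, 1e5),
    ]
    plan = []
    for role, mz, rt, level in base:
        plan.append({"role": role, "mz": mz, "rt": rt, "high_level": level})
        plan.append({"role": "isotopologue", "mz": mz + C13_C12_DELTA, "rt": rt,
                     "high_level": None, "parent_index": len(plan) - 1})
    return plan


def generate_experiment(cfg: SyntheticConfig) -> tuple[FeatureTable, GroundTruth]:
    """Simulate one complete run sequence and return table plus ground truth.

    True (noise-free) levels per feature and sample are built first; the
    pooled QC level of every feature is the mean of its 27 study-well
    levels. Each measurement is then the true level times the linear drift
    multiplier ``1 + drift_slope * (injection_index - 1)`` times lognormal
    noise with the configured CV; values below ``dropout_lod`` are
    recorded as 0.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = generate_injection_sequence(cfg)
    groups = dict(cfg.group_doses)
    dose_step = {g: i for i, (g, _) in enumerate(cfg.group_doses)}
    high_dose = max(groups.values())

    feature_rows: list[dict] = []
    level_by_group: list[dict[str, float]] = []  # per feature: group -> true level
    affected_ids: list[str] = []
    drug_ids: dict[str, str] = {}

    def add_feature(fid, mz, rt, levels, kind):
        feature_rows.append({"feature_id": fid, "mz": mz, "rt_seconds": rt,
                             "name": feature_name(mz, rt)})
        level_by_group.append(levels)
        if kind == "affected":
            affected_ids.append(fid)
        elif kind not in ("background", "is"):
            drug_ids[fid] = kind

    # background features: dose-independent
    for i in range(cfg.n_background_features):
        mz = rng.uniform(70, 700)
        rt = rng.uniform(30, 900)
        base = 10 ** rng.normal(5.0, 0.5)
        add_feature(f"BG{i:04d}", mz, rt, {g: base for g in groups}, "background")

    # dose-affected endogenous features: multiplicative fold change per step
    for i in range(cfg.n_affected_features):
        mz = rng.uniform(70, 700)
        rt = rng.uniform(30, 900)
        base = 10 ** rng.normal(5.0, 0.5)
        direction = 1 if rng.random() < 0.5 else -1
        levels = {g: base * cfg.effect_size ** (direction * dose_step[g]) for g in groups}
        add_feature(f"AF{i:03d}", mz, rt, levels, "affected")

    # drug-derived features: absent in Blank, proportional to dose
    plan = _drug_feature_plan()
    if cfg.n_drug_features > len(plan):
        raise ValueError(
            f"n_drug_features <= {len(plan)} supported, got {cfg.n_drug_features}"
        )
    plan = plan[: cfg.n_drug_features]
    for i, spec in enumerate(plan):
        if spec["role"] == "isotopologue":
            parent_levels = level_by_group[len(feature_rows) - 1]  # immediately preceding
            levels = {g: v * cfg.isotopologue_ratio for g, v in parent_levels.items()}
        else:
            levels = {g: spec["high_level"] * groups[g] / high_dose for g in groups}
        add_feature(f"DR{i:02d}", spec["mz"], spec["rt"], levels, spec["role"])

    # internal standard: tryptophan-d5 analog, constant in every sample
    is_id = "IS000"
    add_feature(is_id, 210.1283, 180.0, {g: 1e6 for g in groups}, "is")

    features = pd.DataFrame(feature_rows).set_index("feature_id")

    # true level per sample: group level for wells, pooled mean for QC
    levels_arr = np.array(
        [[lv[g] for lv in level_by_group] for g in groups], float
    )  # groups x features
    group_index = np.array([list(groups).index(g) if g in groups else -1
                            for g in samples["group"]])
    true = np.empty((len(samples), len(features)))
    qc_level = levels_arr.mean(axis=0)  # pooling all 27 wells = equal-weight group mean
    for si, gi in enumerate(group_index):
        true[si] = qc_level if gi < 0 else levels_arr[gi]

    inj = samples["injection_index"].to_numpy(float)
    drift = 1.0 + cfg.drift_slope * (inj - 1.0)
    measured = true * drift[:, None]
    if cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
        noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=measured.shape))
        measured = measured * noise
    measured = np.where(measured < cfg.dropout_lod, 0.0, measured)

    abundances = pd.DataFrame(measured, index=samples.index, columns=features.index)
    table = FeatureTable(abundances=abundances, samples=samples, features=features)
    truth = GroundTruth(
        affected_feature_ids=affected_ids,
        drug_feature_ids=drug_ids,
        is_feature_id=is_id,
        drift_profile=drift,
        true_levels=pd.DataFrame(true, index=samples.index, columns=features.index),
    )
    return table, truth
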