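"""End-to-end orchestration, file I/O, and exact-mass hypothesis annotation.

``run_pipeline`` executes preprocess -> ANOVA screen -> PC-DFA with
Monte-Carlo cross-validation -> hierarchical clustering -> exact-mass
annotation on a synthetic or user-supplied feature table, writing every
intermediate table plus a JSON summary into a run directory. Every output
file carries the config hash and seed that produced it.

Annotation is hypothesis matching only: each significant feature's m/z is
compared against a set of theoretical ions — protonated parent, +1 13C
companions, glycine and alanine condensation-adduct ions, and the
ammoniated polyethylene-glycol homolog series — within a ppm tolerance.
A match is a mass hypothesis, never an identification claim.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import pcdfa as _pcdfa
from .formula_mass import (
    C13_C12_DELTA,
    ElementalFormula,
    IonSpec,
    PROTON,
    imine_adduct_ion,
    ion_mz,
    parse_formula,
    peg_ammonium_ion,
    ppm_error,
)
from .preprocess import FeatureTable, preprocess_pipeline
from .screen import screen_features
from .synthetic_data import ALANINE, GLYCINE, SyntheticConfig, generate_experiment

__all__ = ["AnnotationHypothesis", "RunConfig", "build_hypotheses",
           "annotate_features", "run_pipeline"]

logger = logging.getLogger("toxmetab")

#: optional biotransformation mass-shift rules (not applied by default)
METABOLITE_SHIFTS = {
    "hydroxylation (+O)": ElementalFormula({"O": 1}).mass,
    "lactam (+O -H2)": ElementalFormula({"O": 1}).mass - ElementalFormula({"H": 2}).mass,
    "dihydro (+H2)": ElementalFormula({"H": 2}).mass,
}

#: in-source artifacts below this m/z were not measurable on the instrument
MZ_CUTOFF = 50.0


@dataclass(frozen=True)
class AnnotationHypothesis:
    label: str
    theoretical_mz: float
    tolerance_ppm: float = 5.0

    def __post_init__(self):
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")

    def matches(self, mz: float) -> bool:
        return abs(ppm_error(mz, self.theoretical_mz)) <= self.tolerance_ppm


def build_hypotheses(
    parents: list[str | ElementalFormula],
    tolerance_ppm: float = 5.0,
    peg_range: tuple[int, int] = (4, 14),
    include_metabolite_shifts: bool = False,
) -> list[AnnotationHypothesis]:
    """Theoretical ion set for a list of parent-drug formulas.

    Per parent: [M+H]+, its glycine and alanine condensation adduct ions,
    and the +1 13C companion of each; plus the shared ammoniated PEG
    homolog series. Optional biotransformation shifts (+O, +O-H2, +H2)
    extend the set when requested.
    """
    hyps: list[AnnotationHypothesis] = []

    def add(label, mz):
        if mz < MZ_CUTOFF:
            logger.warning("hypothesis %s at m/z %.4f below instrument cutoff %g",
                           label, mz, MZ_CUTOFF)
        hyps.append(AnnotationHypothesis(label, mz, tolerance_ppm))

    for parent in parents:
        f = parse_formula(parent) if isinstance(parent, str) else parent
        name = str(f)
        ions = [
            (f"{name} [M+H]+", ion_mz(IonSpec(neutral=f, adduct_delta=PROTON))),
            (f"{name} glycine adduct", ion_mz(imine_adduct_ion(f, GLYCINE))),
            (f"{name} alanine adduct", ion_mz(imine_adduct_ion(f, ALANINE))),
        ]
        if include_metabolite_shifts:
            base = ion_mz(IonSpec(neutral=f, adduct_delta=PROTON))
            ions += [(f"{name} {label}", base + shift)
                     for label, shift in METABOLITE_SHIFTS.items()]
        for label, mz in ions:
            add(label, mz)
            add(f"{label} +1 13C", mz + C13_C12_DELTA)
    for n in range(peg_range[0], peg_range[1] + 1):
        add(f"PEG-{n} ammoniated", ion_mz(peg_ammonium_ion(n)))
    return hyps


def annotate_features(
    features: pd.DataFrame,
    parents: list[str | ElementalFormula],
    tolerance_ppm: float = 5.0,
    peg_range: tuple[int, int] = (4, 14),
    include_metabolite_shifts: bool = False,
) -> pd.DataFrame:
    """Match features (index = id, column ``mz``) against the hypothesis set.

    Every hypothesis within tolerance is reported with its ppm error;
    features matching nothing get a single ``unknown`` row.
    """
    hyps = build_hypotheses(parents, tolerance_ppm, peg_range, include_metabolite_shifts)
    rows = []
    for fid, row in features.iterrows():
        mz = float(row["mz"])
        matched = False
        for h in hyps:
            if h.matches(mz):
                rows.append((fid, row.get("name", ""), mz, h.label,
                             h.theoretical_mz, ppm_error(mz, h.theoretical_mz)))
                matched = True
        if not matched:
            rows.append((fid, row.get("name", ""), mz, "unknown", np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["feature_id", "name", "mz", "hypothesis",
                       "theoretical_mz", "ppm_error"]
    )


@dataclass
class RunConfig:
    """Everything one pipeline run needs; hashable for provenance."""

    in_dir: str | None = None          # CSV bundle; None -> synthetic
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    is_feature_id: str | None = None   # default: ground-truth IS for synthetic runs
    alpha: float = 0.001
    include_qc_in_anova: bool = False
    include_qc_in_pcdfa: bool = True
    cv_iterations: int = 200
    cv_test_fraction: float = 1 / 3
    linkage_method: str = "complete"
    annotation_parents: tuple[str, ...] = ("C14H19NO",)
    tolerance_ppm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, stamp: str, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, **kwargs)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full workflow and write all outputs under *out_dir*.

    Returns the summary dict (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={cfg.config_hash()} seed={cfg.seed}"
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, out, stamp)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path, stamp: str) -> dict:
    logger.info("run start: %s", stamp)
    truth = None
    if cfg.in_dir is None:
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        table, truth = generate_experiment(syn)
        logger.info("synthetic table: %d samples x %d features",
                    table.n_samples, table.n_features)
        table.to_csv_bundle(out / "input", header_comment=stamp)
    else:
        table = FeatureTable.from_csv_bundle(cfg.in_dir)
        logger.info("loaded table from %s", cfg.in_dir)

    is_id = cfg.is_feature_id or (truth.is_feature_id if truth else None)
    if is_id is None:
        raise ValueError("is_feature_id required for non-synthetic input")

    try:
        processed, report = preprocess_pipeline(table, is_feature_id=is_id)
    except Exception as exc:
        raise RuntimeError(f"[preprocess] {exc}") from exc
    logger.info("preprocess: surrogate LOD %.6g, %d features drift-corrected, order %s",
                report.surrogate_lod, report.n_drift_corrected,
                "->".join(report.steps_applied))
    _write_csv(processed.abundances, out / "preprocessed.csv", stamp)

    try:
        screening = screen_features(processed, threshold=cfg.alpha,
                                    include_qc=cfg.include_qc_in_anova)
    except Exception as exc:
        raise RuntimeError(f"[screen] {exc}") from exc
    logger.info("screen: %d/%d significant at p < %g",
                screening.n_significant, table.n_features, cfg.alpha)
    _write_csv(screening.table, out / "screening.csv", stamp)

    sig_ids = [fid for fid in screening.significant_ids if fid != is_id]
    summary: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "surrogate_lod": report.surrogate_lod,
        "n_drift_corrected": report.n_drift_corrected,
        "preprocess_order": list(report.steps_applied),
        "n_significant": len(sig_ids),
        "alpha": cfg.alpha,
    }

    if len(sig_ids) >= 2:
        sig = processed.subset_features(sig_ids)
        mask = (np.ones(sig.n_samples, bool) if cfg.include_qc_in_pcdfa
                else sig.study_mask().to_numpy())
        X = sig.abundances.to_numpy(float)[mask]
        y = sig.samples["group"].to_numpy()[mask]
        try:
            model = _pcdfa.fit_pcdfa(X, y)
            cv = _pcdfa.mc_cross_validate(
                X, y, n_iter=cfg.cv_iterations,
                test_fraction=cfg.cv_test_fraction, seed=cfg.seed,
            )
        except Exception as exc:
            raise RuntimeError(f"[pcdfa] {exc}") from exc
        logger.info("pcdfa: %d PCs retained; CV accuracy %.3f kappa %.3f (%s)",
                    model.n_retained, cv.accuracy, cv.kappa, cv.kappa_category)
        scores = pd.DataFrame(
            np.hstack([model.pc_scores, model.ld_scores]),
            index=sig.samples.index[mask],
            columns=[f"PC{i+1}" for i in range(model.n_retained)]
            + [f"LD{i+1}" for i in range(model.ld_scores.shape[1])],
        )
        scores.insert(0, "group", y)
        _write_csv(scores, out / "pcdfa_scores.csv", stamp)
        loadings = pd.DataFrame(
            model.loadings, index=sig_ids,
            columns=[f"PC{i+1}" for i in range(model.n_retained)],
        )
        _write_csv(loadings, out / "pcdfa_loadings.csv", stamp)
        with open(out / "cv_report.json", "w") as fh:
            json.dump({"provenance": stamp, **cv.to_dict()}, fh, indent=2)
        summary.update(
            n_retained_components=model.n_retained,
            cv_accuracy=cv.accuracy,
            cv_kappa=cv.kappa,
            kappa_category=cv.kappa_category,
        )

        try:
            clustering = _cluster.cluster_table(sig.abundances.T,
                                                linkage_method=cfg.linkage_method)
        except Exception as exc:
            raise RuntimeError(f"[cluster] {exc}") from exc
        _write_csv(clustering.zscored, out / "zscores.csv", stamp)
        for which, link in (("features", clustering.feature_linkage),
                            ("samples", clustering.sample_linkage)):
            _write_csv(
                pd.DataFrame(link, columns=["left", "right", "height", "size"]),
                out / f"linkage_{which}.csv", stamp,
            )

        try:
            annotations = annotate_features(
                sig.features, list(cfg.annotation_parents),
                tolerance_ppm=cfg.tolerance_ppm,
            )
        except Exception as exc:
            raise RuntimeError(f"[annotate] {exc}") from exc
        _write_csv(annotations, out / "annotations.csv", stamp, index=False)
        summary["n_annotated"] = int((annotations["hypothesis"] != "unknown").sum())
        summary["annotations"] = annotations[annotations["hypothesis"] != "unknown"][
            ["feature_id", "name", "hypothesis", "ppm_error"]
        ].to_dict("records")
    else:
        logger.warning("fewer than 2 significant features: skipping PC-DFA, "
                       "clustering, annotation")

    if truth is not None:
        planted = set(truth.affected_feature_ids) | set(truth.drug_feature_ids)
        recovered = planted & set(sig_ids)
        background_fp = [f for f in sig_ids
                         if f.startswith("BG")]
        summary["planted_recovery"] = len(recovered) / len(planted)
        summary["background_false_positives"] = len(background_fp)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("run complete: %d significant features", summary["n_significant"])
    return summary
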