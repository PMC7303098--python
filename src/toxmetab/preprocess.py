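"""Feature-table container and the preprocessing chain.

The pipeline starts from an aligned feature table (samples x features, as
exported by XCMS-style peak pickers) and applies, in the default order:

1. zero imputation with a global surrogate LOD,
2. log10 transformation,
3. QC-anchored injection-order drift correction,
4. internal-standard (tryptophan-d5) normalization.

The order is configurable because step 4 could equally be applied on the
raw scale before the log transform; the applied order is recorded in the
report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "FeatureTable",
    "PreprocessReport",
    "impute_zeros",
    "log_transform",
    "qc_drift_correct",
    "is_normalize",
    "preprocess_pipeline",
]

GROUPS = ("Blank", "Low", "High", "QC")


class PreprocessError(ValueError):
    pass


@dataclass
class FeatureTable:
    """Abundance matrix with sample and feature metadata.

    Attributes
    ----------
    abundances : DataFrame, samples x features
        Non-negative peak areas; 0 means not detected. After the log
        transform the values are log10 areas and may be negative.
    samples : DataFrame indexed by sample id
        Columns ``group`` (Blank/Low/High/QC) and ``injection_index``
        (unique, 1-based position in the run sequence).
    features : DataFrame indexed by feature id
        Columns ``mz``, ``rt_seconds``, ``name``.
    detected : DataFrame of bool, samples x features
        Pre-imputation detection mask (abundance > 0 at load time);
        preserved through all transforms so drift correction can tell
        which features were truly detected in every QC injection.
    log_scale : bool
        Whether ``abundances`` currently holds log10 values.
    """

    abundances: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame
    detected: pd.DataFrame | None = None
    log_scale: bool = False

    def __post_init__(self):
        if list(self.abundances.index) != list(self.samples.index):
            raise PreprocessError("abundance rows do not match sample metadata")
        if list(self.abundances.columns) != list(self.features.index):
            raise PreprocessError("abundance columns do not match feature metadata")
        unknown = set(self.samples["group"]) - set(GROUPS)
        if unknown:
            raise PreprocessError(f"unknown sample groups: {sorted(unknown)}")
        inj = self.samples["injection_index"]
        if inj.duplicated().any():
            raise PreprocessError("injection indices must be unique")
        if self.detected is None:
            self.detected = self.abundances > 0

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundances.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            abundances=self.abundances.copy(),
            samples=self.samples.copy(),
            features=self.features.copy(),
            detected=self.detected.copy(),
            log_scale=self.log_scale,
        )

    def study_mask(self) -> pd.Series:
        return self.samples["group"] != "QC"

    def qc_mask(self) -> pd.Series:
        return self.samples["group"] == "QC"

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = list(feature_ids)
        return FeatureTable(
            abundances=self.abundances[feature_ids],
            samples=self.samples.copy(),
            features=self.features.loc[feature_ids],
            detected=self.detected[feature_ids],
            log_scale=self.log_scale,
        )

    # -- three-file CSV bundle ------------------------------------------

    def to_csv_bundle(self, out_dir: str | Path, header_comment: str | None = None) -> None:
        """Write abundances.csv, samples.csv, features.csv under *out_dir*."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fname, df in (
            ("abundances.csv", self.abundances),
            ("samples.csv", self.samples),
            ("features.csv", self.features),
        ):
            with open(out_dir / fname, "w") as fh:
                if header_comment:
                    fh.write(f"# {header_comment}\n")
                df.to_csv(fh)

    @classmethod
    def from_csv_bundle(cls, in_dir: str | Path, log_scale: bool = False) -> "FeatureTable":
        in_dir = Path(in_dir)
        abundances = pd.read_csv(in_dir / "abundances.csv", index_col=0, comment="#")
        samples = pd.read_csv(in_dir / "samples.csv", index_col=0, comment="#")
        features = pd.read_csv(in_dir / "features.csv", index_col=0, comment="#")
        abundances.columns = features.index
        return cls(abundances=abundances, samples=samples, features=features,
                   log_scale=log_scale)


@dataclass
class PreprocessReport:
    surrogate_lod: float | None = None
    n_drift_corrected: int | None = None
    is_feature_id: str | None = None
    steps_applied: tuple[str, ...] = ()

    def record(self, step: str) -> None:
        self.steps_applied = self.steps_applied + (step,)


def impute_zeros(t: FeatureTable, report: PreprocessReport | None = None) -> FeatureTable:
    """Replace zero abundances by the lowest measured (nonzero) abundance.

    The replacement value is the global matrix minimum, acting as a
    surrogate limit of detection shared by all features.
    """
    values = t.abundances.to_numpy(float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise PreprocessError("all-zero matrix: nothing to impute from")
    lod = float(nonzero.min())
    out = t.copy()
    out.abundances = t.abundances.mask(t.abundances == 0, lod)
    if report is not None:
        report.surrogate_lod = lod
        report.record("impute")
    return out


def log_transform(t: FeatureTable, report: PreprocessReport | None = None) -> FeatureTable:
    """Elementwise log10; requires strictly positive abundances."""
    if (t.abundances.to_numpy(float) <= 0).any():
        raise PreprocessError("non-positive abundances present: impute zeros first")
    out = t.copy()
    out.abundances = np.log10(t.abundances)
    out.log_scale = True
    if report is not None:
        report.record("log10")
    return out


def qc_drift_correct(
    t: FeatureTable,
    n_leading_qc: int = 5,
    report: PreprocessReport | None = None,
) -> tuple[FeatureTable, PreprocessReport]:
    """Remove injection-order drift using the periodic pooled-QC injections.

    Only features detected (nonzero before imputation) in every QC sample
    are corrected. Per feature, a piecewise-linear curve through the QC
    abundances versus injection index (flat extrapolation beyond the first
    and last anchor) is evaluated at every sample's index and removed —
    subtracted on the log scale, divided out on the raw scale — then the
    feature is re-anchored at its mean QC level.

    The first ``n_leading_qc`` QC injections are treated as column
    conditioning and excluded from the anchors (they still count for the
    detected-in-every-QC requirement).
    """
    if report is None:
        report = PreprocessReport()
    qc = t.qc_mask()
    if int(qc.sum()) < 2:
        raise PreprocessError("drift correction needs at least 2 QC samples")

    qc_inj = t.samples.loc[qc, "injection_index"].sort_values()
    anchor_ids = qc_inj.index[n_leading_qc:] if n_leading_qc < len(qc_inj) else qc_inj.index
    if len(anchor_ids) < 2:
        anchor_ids = qc_inj.index  # too few post-conditioning QCs: use all
    anchor_x = t.samples.loc[anchor_ids, "injection_index"].to_numpy(float)
    order = np.argsort(anchor_x)
    anchor_x = anchor_x[order]
    anchor_ids = anchor_ids[order]

    in_all_qc = t.detected.loc[qc.index[qc]].all(axis=0)
    correctable = t.features.index[in_all_qc]

    out = t.copy()
    x_all = t.samples["injection_index"].to_numpy(float)
    for fid in correctable:
        y_anchor = t.abundances.loc[anchor_ids, fid].to_numpy(float)
        drift = np.interp(x_all, anchor_x, y_anchor)
        if t.log_scale:
            out.abundances[fid] = t.abundances[fid].to_numpy(float) - drift + y_anchor.mean()
        else:
            ref = y_anchor.mean()
            out.abundances[fid] = t.abundances[fid].to_numpy(float) / drift * ref
    report.n_drift_corrected = len(correctable)
    report.record("drift")
    return out, report


def is_normalize(
    t: FeatureTable,
    is_feature_id: str,
    report: PreprocessReport | None = None,
) -> FeatureTable:
    """Normalize every sample to its internal-standard (tryptophan-d5) area.

    On the log scale the IS column is subtracted per sample; on the raw
    scale each sample is divided by its IS value. After normalization the
    IS column is exactly constant.
    """
    if is_feature_id not in t.abundances.columns:
        raise PreprocessError(f"internal-standard feature {is_feature_id!r} not in table")
    is_col = t.abundances[is_feature_id].to_numpy(float)
    if not t.log_scale and (is_col <= 0).any():
        raise PreprocessError("internal standard not positive in every sample")
    out = t.copy()
    if t.log_scale:
        out.abundances = t.abundances.sub(t.abundances[is_feature_id], axis=0)
    else:
        out.abundances = t.abundances.div(t.abundances[is_feature_id], axis=0)
    if report is not None:
        report.is_feature_id = is_feature_id
        report.record("is_normalize")
    return out


DEFAULT_ORDER = ("impute", "log10", "drift", "is_normalize")


def preprocess_pipeline(
    t: FeatureTable,
    is_feature_id: str | None = None,
    order: tuple[str, ...] = DEFAULT_ORDER,
    n_leading_qc: int = 5,
) -> tuple[FeatureTable, PreprocessReport]:
    """Run the preprocessing steps in the given order and report what was done."""
    report = PreprocessReport()
    for step in order:
        if step == "impute":
            t = impute_zeros(t, report)
        elif step == "log10":
            t = log_transform(t, report)
        elif step == "drift":
            t, report = qc_drift_correct(t, n_leading_qc=n_leading_qc, report=report)
        elif step == "is_normalize":
            if is_feature_id is None:
                raise PreprocessError("is_normalize requested but no IS feature given")
            t = is_normalize(t, is_feature_id, report)
        else:
            raise PreprocessError(f"unknown preprocessing step {step!r}")
    return t, report
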