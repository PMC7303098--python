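"""Univariate feature screening by one-way ANOVA across incubation groups.

Features are kept when the classical (equal-variance) one-way ANOVA over
the incubation groups gives p < alpha (default 0.001, no multiplicity
correction — the screen is a triage step, not an inference). QC samples
are pooled mixtures rather than an incubation condition and are excluded
by default; they can be included as a fourth level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureTable

__all__ = ["ScreeningResult", "anova_pvalue", "screen_features"]


class ScreenError(ValueError):
    pass


@dataclass
class ScreeningResult:
    table: pd.DataFrame  # per feature: F, p_value, significant
    threshold: float
    groups_used: tuple[str, ...]

    @property
    def significant_ids(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def anova_pvalue(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA F and upper-tail p.

    ``values`` may be 1-D (one feature) or 2-D (samples x features, in
    which case arrays of F and p are returned). A degenerate feature with
    zero between- and within-group variance gets F = 0, p = 1.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ScreenError("ANOVA needs at least 2 groups")
    parts = [values[groups == g] for g in labels]
    for g, p in zip(labels, parts):
        if p.shape[0] < 2:
            raise ScreenError(f"group {g!r} has fewer than 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*parts, axis=0)
    # zero variance everywhere -> nan from scipy; define as no evidence
    f = np.where(np.isnan(f), 0.0, f)
    p = np.where(np.isnan(p), 1.0, p)
    if f.ndim == 0:
        return float(f), float(p)
    return f, p


def screen_features(
    t: FeatureTable,
    threshold: float = 0.001,
    include_qc: bool = False,
) -> ScreeningResult:
    """Per-feature ANOVA over the incubation groups; flag p < threshold."""
    if not 0 < threshold <= 1:
        raise ScreenError(f"threshold must be in (0, 1], got {threshold}")
    mask = np.ones(t.n_samples, bool) if include_qc else t.study_mask().to_numpy()
    values = t.abundances.to_numpy(float)[mask]
    groups = t.samples["group"].to_numpy()[mask]
    f, p = anova_pvalue(values, groups)
    table = pd.DataFrame(
        {
            "name": t.features["name"],
            "mz": t.features["mz"],
            "rt_seconds": t.features["rt_seconds"],
            "F": f,
            "p_value": p,
            "significant": p < threshold,
        },
        index=t.features.index,
    )
    return ScreeningResult(table=table, threshold=threshold,
                           groups_used=tuple(np.unique(groups)))


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Optional BH-adjusted p-values (not used by the default screen)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]
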