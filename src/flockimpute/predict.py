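"""Pre-imputation prediction of which animals will impute poorly.

The predictor works entirely on low-density genotypes, before any
imputation is run: each target animal's AVTOP10 — the mean Mendelian
inconsistency (opposing-homozygote count) against the k = 10 reference
animals with the lowest MI — measures how much haplotype it shares with
the reference set.  Animals whose AVTOP10 exceeds a density-specific
threshold (default 400 for a 5K-like panel, 3000 for a 50K-like panel,
strict inequality) are flagged at-risk of imputing below ~80% concordance.
These defaults originate from one sheep population and are data-dependent;
:func:`calibrate_threshold` re-derives the cut on data where achieved
accuracies are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, GenotypeMatrix, ParameterError
from .relatedness import allele_frequencies, avtop10_mi, compute_G, top_k_relationships

__all__ = [
    "DEFAULT_THRESHOLDS",
    "PredictionReport",
    "CalibrationResult",
    "predict_at_risk",
    "calibrate_threshold",
]

DEFAULT_THRESHOLDS = {"5K-like": 400.0, "50K-like": 3000.0}

_LABEL_ALIASES = {
    "5k": "5K-like", "5k-like": "5K-like", "5K": "5K-like", "5K-like": "5K-like",
    "50k": "50K-like", "50k-like": "50K-like", "50K": "50K-like", "50K-like": "50K-like",
    "custom": "custom",
}


@dataclass
class PredictionReport:
    table: pd.DataFrame  # animal, avtop10, mean_top10_g, flag
    threshold: float
    panel_label: str
    k: int

    def at_risk(self) -> list:
        return self.table.loc[self.table["flag"] == "at-risk", "animal"].tolist()


def predict_at_risk(
    low_density: GenotypeMatrix,
    reference: GenotypeMatrix,
    panel_label: str = "custom",
    threshold: float | None = None,
    k: int = 10,
    with_g: bool = True,
) -> PredictionReport:
    """Flag target animals whose AVTOP10 MI exceeds the threshold.

    ``low_density`` holds the target animals, ``reference`` the reference
    animals, both on the same low-density SNP frame (the intersection of
    their SNP ids is used).  ``flag`` is 'at-risk' iff AVTOP10 > threshold
    (an AVTOP10 exactly at the threshold passes).
    """
    label = _LABEL_ALIASES.get(panel_label)
    if label is None:
        raise ParameterError(f"unknown panel label {panel_label!r}")
    if threshold is None:
        if label == "custom":
            raise ParameterError("custom panels require an explicit threshold")
        threshold = DEFAULT_THRESHOLDS[label]
    shared = [s for s in low_density.snps if s in set(reference.snps)]
    if not shared:
        raise DataError("no shared SNPs between targets and reference")
    if set(low_density.animals) & set(reference.animals):
        raise ParameterError("target and reference animal sets overlap")
    tg = low_density.subset_snps(shared)
    rg = reference.subset_snps(shared)
    combined = GenotypeMatrix(
        np.concatenate([rg.animals, tg.animals]),
        np.array(shared, dtype=object),
        np.vstack([rg.data, tg.data]),
    )
    profile = avtop10_mi(list(tg.animals), list(rg.animals), combined, k=k)
    table = profile.table.rename(columns={"target": "animal"})[["animal", "avtop10"]]
    if with_g:
        freqs = allele_frequencies(combined)
        gmat = compute_G(combined, freqs)
        stats_k = top_k_relationships(gmat, list(rg.animals), list(tg.animals), k=k)
        table = table.merge(
            stats_k.summary.rename(columns={"target": "animal", "mean": "mean_top10_g"})
            [["animal", "mean_top10_g"]],
            on="animal", how="left")
    else:
        table["mean_top10_g"] = np.nan
    table["flag"] = np.where(table["avtop10"] > threshold, "at-risk", "pass")
    return PredictionReport(table, float(threshold), label, k)


@dataclass
class CalibrationResult:
    threshold: float | None
    balanced_accuracy: float | None
    rank_correlation: float  # Spearman rho between AVTOP10 and achieved CR
    degenerate: bool
    n: int
    diagnostic: str = ""


def calibrate_threshold(
    avtop10,
    achieved_cr,
    target_cr: float = 80.0,
) -> CalibrationResult:
    """Choose the AVTOP10 cut best separating animals below ``target_cr``.

    Scans midpoints between consecutive distinct AVTOP10 values and returns
    the cut maximising balanced accuracy for classifying CR < target_cr
    (ties -> smallest cut), together with the Spearman rank correlation
    between AVTOP10 and CR.  If every animal falls on one side of
    ``target_cr`` the classification is degenerate and no threshold is
    returned.
    """
    avtop10 = np.asarray(avtop10, dtype=float)
    cr = np.asarray(achieved_cr, dtype=float)
    ok = np.isfinite(avtop10) & np.isfinite(cr)
    avtop10, cr = avtop10[ok], cr[ok]
    n = len(avtop10)
    if n < 20:
        raise ParameterError(f"calibration needs >= 20 animals with both values, got {n}")
    if np.ptp(avtop10) == 0 or np.ptp(cr) == 0:
        rho = float("nan")  # constant input: no defined ordering
    else:
        rho = float(stats.spearmanr(avtop10, cr).statistic)
    poor = cr < target_cr
    if poor.all() or (~poor).all():
        return CalibrationResult(None, None, rho, True, n,
                                 "all animals on one side of the target CR")
    uniq = np.unique(avtop10)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_ba = None, -1.0
    n_poor, n_good = poor.sum(), (~poor).sum()
    for t in candidates:
        pred = avtop10 > t
        tpr = (pred & poor).sum() / n_poor
        tnr = (~pred & ~poor).sum() / n_good
        ba = (tpr + tnr) / 2.0
        if ba > best_ba + 1e-12:
            best_ba, best_t = ba, float(t)
    return CalibrationResult(best_t, float(best_ba), rho, False, n)
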