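"""Quality control of SNP genotype matrices.

Per-SNP filters run in a fixed order — undefined map position, minor allele
frequency, call rate, Hardy–Weinberg equilibrium — and each dropped SNP is
recorded with its first failing rule only.  The per-animal call-rate filter
runs last, on QC-retained SNPs; SNP statistics are not recomputed after
animal removal (single pass, flagged in the report).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, DataError, GenotypeMatrix, MarkerMap, ParameterError

__all__ = ["QCThresholds", "QCReport", "snp_statistics", "hwe_pvalues", "qc_filter"]


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; ``None`` switches a rule off.

    Defaults are the chip-QC settings the pipeline assumes throughout:
    drop SNPs with MAF < 0.0005, call rate < 0.95 or HWE p < 1e-5, drop
    SNPs without a defined map position, and drop animals with call rate
    < 0.95.
    """

    min_maf: float | None = 0.0005
    min_snp_call_rate: float | None = 0.95
    min_hwe_p: float | None = 1e-5
    require_position: bool = True
    min_animal_call_rate: float | None = 0.95
    hwe_method: str = "chisq"  # or "exact"


@dataclass
class QCReport:
    snp_table: pd.DataFrame  # snp_id, maf, call_rate, hwe_p, kept, reason
    animal_table: pd.DataFrame  # animal, call_rate, kept, reason
    thresholds: QCThresholds
    recomputed_after_animal_filter: bool = False


def snp_statistics(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP MAF (folded, from non-missing calls) and call rate."""
    data = genotypes.data
    called = data != MISSING
    n_called = called.sum(axis=0)
    dosage_sum = np.where(called, data, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, dosage_sum / (2.0 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    call_rate = n_called / max(genotypes.n_animals, 1)
    return pd.DataFrame({
        "snp_id": genotypes.snps, "p_b": p, "maf": maf,
        "call_rate": call_rate, "n_called": n_called,
    })


def _hwe_chisq(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = (2 * n0 + n1) / (2.0 * np.maximum(n, 1))
    pb = 1.0 - pa
    e0, e1, e2 = n * pa**2, 2 * n * pa * pb, n * pb**2
    chi2 = np.zeros(len(n), dtype=float)
    for o, e in ((n0, e0), (n1, e1), (n2, e2)):
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
        chi2 += term
    pvals = stats.chi2.sf(chi2, df=1)
    pvals[(n == 0) | (np.minimum(pa, pb) == 0)] = 1.0  # monomorphic or empty: no test
    return pvals


def _hwe_exact_one(n_ab: int, n_aa: int, n_bb: int) -> float:
    """Exact HWE test (sum of genotype probabilities <= observed)."""
    n = n_aa + n_ab + n_bb
    rare = 2 * min(n_aa, n_bb) + n_ab
    if n == 0 or rare == 0:
        return 1.0
    # probability over heterozygote counts with fixed rare-allele count
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    h = mid
    while h > 1:
        probs[h - 2] = probs[h] * h * (h - 1.0) / (
            4.0 * ((rare - h) / 2.0 + 1.0) * ((2 * n - rare - h) / 2.0 + 1.0))
        h -= 2
    h = mid
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * ((rare - h) / 2.0) * ((2 * n - rare - h) / 2.0) / (
            (h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    return min(1.0, sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total)


def hwe_pvalues(genotypes: GenotypeMatrix, method: str = "chisq") -> np.ndarray:
    data = genotypes.data
    n0 = (data == 0).sum(axis=0)
    n1 = (data == 1).sum(axis=0)
    n2 = (data == 2).sum(axis=0)
    if method == "chisq":
        return _hwe_chisq(n0, n1, n2)
    if method == "exact":
        return np.array([_hwe_exact_one(int(b), int(a), int(c))
                         for a, b, c in zip(n0, n1, n2)])
    raise ParameterError(f"unknown HWE method {method!r}")


def qc_filter(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    thresholds: QCThresholds = QCThresholds(),
):
    """Apply SNP filters in order, then the animal call-rate filter.

    Returns ``(filtered GenotypeMatrix, filtered MarkerMap, QCReport)``.
    """
    if genotypes.n_animals == 0 or genotypes.n_snps == 0:
        raise DataError("empty genotype matrix")
    geno = genotypes.subset_snps(marker_map.snp_ids)
    stats_tab = snp_statistics(geno)
    hwe_p = hwe_pvalues(geno, thresholds.hwe_method)
    stats_tab["hwe_p"] = hwe_p

    pos_ok = marker_map.positions_defined()
    reason = np.array([""] * geno.n_snps, dtype=object)
    kept = np.ones(geno.n_snps, dtype=bool)

    def apply(rule: str, fails: np.ndarray) -> None:
        hit = kept & fails
        reason[hit] = rule
        kept[hit] = False

    if thresholds.require_position:
        apply("position", ~pos_ok)
    if thresholds.min_maf is not None:
        maf = stats_tab["maf"].to_numpy()
        apply("maf", np.isnan(maf) | (maf < thresholds.min_maf))
    if thresholds.min_snp_call_rate is not None:
        apply("call_rate", stats_tab["call_rate"].to_numpy() < thresholds.min_snp_call_rate)
    if thresholds.min_hwe_p is not None:
        apply("hwe", hwe_p < thresholds.min_hwe_p)

    stats_tab["kept"] = kept
    stats_tab["reason"] = reason
    kept_snps = geno.snps[kept]
    geno2 = geno.subset_snps(kept_snps)

    animal_cr = (geno2.data != MISSING).mean(axis=1) if geno2.n_snps else np.ones(geno2.n_animals)
    a_kept = np.ones(geno2.n_animals, dtype=bool)
    a_reason = np.array([""] * geno2.n_animals, dtype=object)
    if thresholds.min_animal_call_rate is not None:
        fail = animal_cr < thresholds.min_animal_call_rate
        a_reason[fail] = "call_rate"
        a_kept[fail] = False
    animal_tab = pd.DataFrame({
        "animal": geno2.animals, "call_rate": animal_cr,
        "kept": a_kept, "reason": a_reason,
    })
    geno3 = geno2.subset_animals(geno2.animals[a_kept])
    report = QCReport(stats_tab, animal_tab, thresholds)
    return geno3, marker_map.subset(kept_snps), report
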