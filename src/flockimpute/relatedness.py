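"""Genomic relationships, Mendelian inconsistency and MDS clustering.

The genomic relationship matrix follows VanRaden's method 1,

    G = XX' / (2 * sum_i p_i (1 - p_i)),

where X is the dosage matrix centered by twice the B-allele frequency p_i
of each SNP and missing dosages contribute 0 after centering (mean
imputation).  Mendelian inconsistency (MI) between two animals is the count
of opposing homozygotes (dosages 0 vs 2) over SNPs called in both; low MI
marks haplotype sharing and is the basis of the pre-imputation accuracy
predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, DataError, GenotypeMatrix, ParameterError

__all__ = [
    "AlleleFrequencies",
    "GMatrix",
    "TopKStats",
    "MIProfile",
    "allele_frequencies",
    "compute_G",
    "top_k_relationships",
    "mendelian_inconsistency",
    "mi_counts",
    "avtop10_mi",
    "mds_cluster",
]


@dataclass
class AlleleFrequencies:
    """Per-SNP B-allele frequency over a stated animal set."""

    snps: np.ndarray
    p: np.ndarray
    defined: np.ndarray  # False where the SNP had zero non-missing calls
    animal_set: tuple = ()

    def series(self) -> pd.Series:
        return pd.Series(self.p, index=self.snps)


def allele_frequencies(genotypes: GenotypeMatrix, animal_set=None) -> AlleleFrequencies:
    """p_i = (sum of dosages) / (2 x non-missing count), per SNP."""
    if animal_set is not None:
        animal_set = list(animal_set)
        if not animal_set:
            raise DataError("animal_set is empty")
        geno = genotypes.subset_animals(animal_set)
    else:
        geno = genotypes
        animal_set = list(geno.animals)
    called = geno.data != MISSING
    n_called = called.sum(axis=0)
    dosage = np.where(called, geno.data, 0).sum(axis=0)
    p = np.full(geno.n_snps, np.nan)
    ok = n_called > 0
    p[ok] = dosage[ok] / (2.0 * n_called[ok])
    return AlleleFrequencies(geno.snps.copy(), p, ok, tuple(animal_set))


@dataclass
class GMatrix:
    animals: np.ndarray
    G: np.ndarray
    X: np.ndarray  # centered incidence matrix actually used
    scale: float  # 2 * sum p(1-p) over contributing SNPs

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.G, index=self.animals, columns=self.animals)


def compute_G(genotypes: GenotypeMatrix, freqs: AlleleFrequencies) -> GMatrix:
    """VanRaden method-1 G from dosages and the supplied frequencies.

    SNPs with undefined frequency are excluded from both X and the scaling
    sum; if every SNP is monomorphic the scaling degenerates and a
    ``DataError`` is raised.
    """
    if genotypes.n_animals < 2:
        raise DataError("G requires at least 2 animals")
    if not np.array_equal(genotypes.snps, freqs.snps):
        freqs_idx = {s: i for i, s in enumerate(freqs.snps)}
        try:
            order = np.array([freqs_idx[s] for s in genotypes.snps])
        except KeyError as exc:
            raise DataError(f"no frequency for SNP {exc.args[0]!r}") from None
        p = freqs.p[order]
        defined = freqs.defined[order]
    else:
        p, defined = freqs.p, freqs.defined
    use = defined & np.isfinite(p)
    p = p[use]
    data = genotypes.data[:, use].astype(float)
    X = np.where(data == MISSING, 2.0 * p, data) - 2.0 * p
    scale = 2.0 * float(np.sum(p * (1.0 - p)))
    if scale <= 0.0:
        raise DataError("all SNPs monomorphic: G scaling constant is zero")
    G = (X @ X.T) / scale
    return GMatrix(genotypes.animals.copy(), G, X, scale)


@dataclass
class TopKStats:
    """Per-target top-k genomic relationships against a reference set.

    ``scenario_mean``/``min``/``max`` average the per-target top-k mean, min
    and max — the Mean/Min/Max Top10 summaries used to characterise how
    related an imputation target group is to its reference.
    """

    per_target: pd.DataFrame  # target, rank, reference, relationship
    summary: pd.DataFrame  # target, mean, min, max, k_used, shortfall
    k: int
    scenario_mean: float
    scenario_min: float
    scenario_max: float


def top_k_relationships(gmat: GMatrix, reference, targets, k: int = 10) -> TopKStats:
    reference, targets = list(reference), list(targets)
    if not reference:
        raise DataError("empty reference set")
    if set(reference) & set(targets):
        raise ParameterError("reference and target sets overlap")
    if k < 1:
        raise ParameterError("k must be >= 1")
    idx = {a: i for i, a in enumerate(gmat.animals)}
    ref_idx = np.array([idx[a] for a in reference])
    rows, srows = [], []
    k_used = min(k, len(reference))
    ref_arr = np.array(reference, dtype=object)
    for t in targets:
        rel = gmat.G[idx[t], ref_idx]
        order = np.argsort(-rel, kind="stable")[:k_used]
        vals = rel[order]
        for rank, (r, v) in enumerate(zip(ref_arr[order], vals), start=1):
            rows.append((t, rank, r, v))
        srows.append((t, vals.mean(), vals.min(), vals.max(), k_used, k - k_used))
    per_target = pd.DataFrame(rows, columns=["target", "rank", "reference", "relationship"])
    summary = pd.DataFrame(srows, columns=["target", "mean", "min", "max", "k_used", "shortfall"])
    return TopKStats(
        per_target, summary, k,
        float(summary["mean"].mean()), float(summary["min"].mean()),
        float(summary["max"].mean()),
    )


def mendelian_inconsistency(a: np.ndarray, b: np.ndarray) -> tuple:
    """(opposing-homozygote count, co-called SNP count) for two dosage vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise DataError("genotype vectors differ in length")
    called = (a != MISSING) & (b != MISSING)
    opposing = called & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
    return int(opposing.sum()), int(called.sum())


def mi_counts(genotypes: GenotypeMatrix, rows, cols) -> tuple:
    """MI count and co-called matrices for all row x col animal pairs.

    Vectorised via indicator matmuls; returns (counts, co_called) with shape
    (len(rows), len(cols)).
    """
    ra = genotypes.subset_animals(list(rows)).data
    ca = genotypes.subset_animals(list(cols)).data
    r0 = (ra == 0).astype(np.float64)
    r2 = (ra == 2).astype(np.float64)
    rc = (ra != MISSING).astype(np.float64)
    c0 = (ca == 0).astype(np.float64)
    c2 = (ca == 2).astype(np.float64)
    cc = (ca != MISSING).astype(np.float64)
    counts = r0 @ c2.T + r2 @ c0.T
    co = rc @ cc.T
    return counts.astype(np.int64), co.astype(np.int64)


@dataclass
class MIProfile:
    """Per-target AVTOP10: mean MI over the k lowest-MI reference animals."""

    table: pd.DataFrame  # target, avtop10, k_used + lowest-MI reference ids
    pairs: pd.DataFrame  # target, reference, mi, co_called (the k kept pairs)
    k: int


def avtop10_mi(targets, reference, genotypes: GenotypeMatrix, k: int = 10) -> MIProfile:
    """AVTOP10 per target: ties in MI break by reference animal-id order."""
    targets, reference = list(targets), list(reference)
    if not reference:
        raise DataError("empty reference set")
    counts, co = mi_counts(genotypes, targets, reference)
    order_ref = np.argsort(np.array(reference, dtype=object), kind="stable")
    rows, prows = [], []
    k_used = min(k, len(reference))
    ref_sorted = [reference[i] for i in order_ref]
    for ti, t in enumerate(targets):
        mi = counts[ti, order_ref]
        pick = np.argsort(mi, kind="stable")[:k_used]  # stable sort on id-ordered refs
        rows.append((t, float(mi[pick].mean()), k_used))
        for j in pick:
            prows.append((t, ref_sorted[j], int(mi[j]), int(co[ti, order_ref[j]])))
    table = pd.DataFrame(rows, columns=["target", "avtop10", "k_used"])
    pairs = pd.DataFrame(prows, columns=["target", "reference", "mi", "co_called"])
    return MIProfile(table, pairs, k)


def mds_cluster(
    gmat: GMatrix,
    groups,
    sample_per_group: int | None = None,
    dims: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Classical MDS (principal coordinates) on genomic distances.

    Distances are d_ij = sqrt(g_ii + g_jj - 2 g_ij).  ``groups`` maps animal
    id -> group label; ``sample_per_group`` animals are drawn per group
    (seeded) before ordination, mirroring per-breed subsampling of large
    cohorts.  Negative eigenvalues (non-Euclidean distances) are truncated;
    the returned frame's ``attrs['negative_eigenvalues']`` records this.
    """
    if dims < 1:
        raise ParameterError("dims must be >= 1")
    groups = dict(groups) if not isinstance(groups, pd.Series) else groups.to_dict()
    rng = np.random.default_rng(seed)
    chosen: list = []
    by_group: dict = {}
    for a in gmat.animals:
        if a in groups:
            by_group.setdefault(groups[a], []).append(a)
    for g in sorted(by_group, key=str):
        members = by_group[g]
        if sample_per_group is not None and len(members) > sample_per_group:
            take = rng.choice(len(members), size=sample_per_group, replace=False)
            members = [members[i] for i in sorted(take)]
        chosen.extend(members)
    if len(chosen) < 2:
        raise DataError("need at least 2 grouped animals for MDS")
    idx = {a: i for i, a in enumerate(gmat.animals)}
    sel = np.array([idx[a] for a in chosen])
    G = gmat.G[np.ix_(sel, sel)]
    diag = np.diag(G)
    d2 = np.maximum(diag[:, None] + diag[None, :] - 2.0 * G, 0.0)
    dist = np.sqrt(d2)
    np.fill_diagonal(dist, 0.0)

    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa

    ids = [str(i) for i in range(len(chosen))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = pcoa(DistanceMatrix((dist + dist.T) / 2.0, ids), method="eigh",
                   number_of_dimensions=min(dims, len(chosen) - 1))
    coords = res.samples.to_numpy()[:, :dims]
    if coords.shape[1] < dims:  # pad degenerate dimensions with zeros
        coords = np.hstack([coords, np.zeros((coords.shape[0], dims - coords.shape[1]))])
    # deterministic axis orientation: largest-|coordinate| entry positive
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    out = pd.DataFrame(coords, columns=[f"axis{j + 1}" for j in range(dims)])
    out.insert(0, "group", [groups[a] for a in chosen])
    out.insert(0, "animal", chosen)
    out.attrs["negative_eigenvalues"] = bool((np.asarray(res.eigvals) < -1e-8).any())
    return out
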