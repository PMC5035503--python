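"""Imputation accuracy: concordance rate, allelic r², profiles, scenarios.

Concordance rate (CR) is the percentage of imputed genotypes identical to
the true genotypes among entries called on both sides; allelic r² is the
squared Pearson correlation between true and imputed dosages, which is far
less dependent on allele frequency than CR.  Both are computed per animal
(over evaluated SNPs) and per SNP (over target animals).  By default only
masked entries — SNPs on the target panel absent from the source panel —
are evaluated, so pass-through observed genotypes cannot inflate accuracy;
``evaluated="all"`` switches to the whole target-panel frame.

A SNP (or animal) with zero dosage variance on either side has r² defined
as 0: a no-variation SNP carries no recoverable signal, and this convention
keeps MAF-bin means defined for the rarest bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    DataError,
    GenotypeMatrix,
    MarkerMap,
    PanelDef,
    ParameterError,
    Pedigree,
)
from .panels import mask_to_panel
from .relatedness import (
    AlleleFrequencies,
    allele_frequencies,
    compute_G,
    top_k_relationships,
)
from . import impute as _impute

__all__ = [
    "Scenario",
    "AccuracyReport",
    "MAFBinTable",
    "ChromEndReport",
    "concordance_rate",
    "allelic_r2",
    "maf_binned_r2",
    "chromosome_end_accuracy",
    "run_scenario",
]

TABLE7_EDGES = (0.0, 0.0001, 0.001, 0.01, 0.05)


def _aligned(true: GenotypeMatrix, imputed: GenotypeMatrix):
    if not np.array_equal(true.snps, imputed.snps):
        raise DataError("true and imputed SNP frames differ")
    if not np.array_equal(true.animals, imputed.animals):
        imputed = imputed.subset_animals(list(true.animals))
    return true.data, imputed.data


def _evaluated_columns(true: GenotypeMatrix, evaluated) -> np.ndarray:
    if evaluated is None:
        return np.ones(true.n_snps, dtype=bool)
    evaluated = np.asarray(evaluated)
    if evaluated.dtype == bool:
        if evaluated.shape != (true.n_snps,):
            raise ParameterError("evaluated mask length mismatch")
        return evaluated
    return np.isin(true.snps.astype(str), evaluated.astype(str))


def concordance_rate(
    true: GenotypeMatrix,
    imputed: GenotypeMatrix,
    axis: str = "animal",
    evaluated=None,
) -> np.ndarray:
    """Per-unit CR in percent; units with no comparable entries get NaN."""
    t, m = _aligned(true, imputed)
    cols = _evaluated_columns(true, evaluated)
    t, m = t[:, cols], m[:, cols]
    comparable = (t != MISSING) & (m != MISSING)
    agree = comparable & (t == m)
    if axis not in ("animal", "snp"):
        raise ParameterError(f"axis must be 'animal' or 'snp', got {axis!r}")
    ax = 1 if axis == "animal" else 0
    n = comparable.sum(axis=ax)
    with np.errstate(invalid="ignore", divide="ignore"):
        cr = np.where(n > 0, 100.0 * agree.sum(axis=ax) / np.maximum(n, 1), np.nan)
    if axis == "snp":  # scatter back onto the full SNP frame
        full = np.full(true.n_snps, np.nan)
        full[cols] = cr
        return full
    return cr


def allelic_r2(
    true: GenotypeMatrix,
    imputed: GenotypeMatrix,
    axis: str = "animal",
    evaluated=None,
) -> np.ndarray:
    """Per-unit squared Pearson correlation of true vs imputed dosages.

    Zero variance on either side -> 0; fewer than 2 comparable entries ->
    NaN (undefined).
    """
    t, m = _aligned(true, imputed)
    cols = _evaluated_columns(true, evaluated)
    t, m = t[:, cols].astype(float), m[:, cols].astype(float)
    if axis == "snp":
        t, m = t.T, m.T
    elif axis != "animal":
        raise ParameterError(f"axis must be 'animal' or 'snp', got {axis!r}")
    comparable = (t != MISSING) & (m != MISSING)
    t = np.where(comparable, t, np.nan)
    m = np.where(comparable, m, np.nan)
    n = comparable.sum(axis=1)
    out = np.full(t.shape[0], np.nan)
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.maximum(n, 1)
        mt = np.where(comparable, t, 0.0).sum(axis=1) / denom
        mm = np.where(comparable, m, 0.0).sum(axis=1) / denom
        dt = np.where(comparable, t - mt[:, None], 0.0)
        dm = np.where(comparable, m - mm[:, None], 0.0)
        cov = (dt * dm).sum(axis=1)
        vt = (dt * dt).sum(axis=1)
        vm = (dm * dm).sum(axis=1)
        r2 = np.where((vt > 0) & (vm > 0), (cov**2) / np.maximum(vt * vm, 1e-300), 0.0)
    out[ok] = r2[ok]
    if axis == "snp":  # scatter back onto the full SNP frame
        full = np.full(true.n_snps, np.nan)
        full[cols] = out
        return full
    return out


@dataclass
class MAFBinTable:
    """Mean per-SNP r² within left-open, right-closed MAF bins."""

    table: pd.DataFrame  # low, high, n_snps, mean_r2
    edges: tuple
    n_excluded: int  # MAF outside (0, max edge] or undefined


def maf_binned_r2(per_snp_r2, freqs, edges=TABLE7_EDGES) -> MAFBinTable:
    """Bin per-SNP r² by minor allele frequency.

    ``freqs`` is an :class:`AlleleFrequencies` (folded to MAF internally) or
    an array of MAF values aligned with ``per_snp_r2``.
    """
    r2 = np.asarray(per_snp_r2, dtype=float)
    if isinstance(freqs, AlleleFrequencies):
        p = freqs.p
        maf = np.minimum(p, 1.0 - p)
    else:
        maf = np.asarray(freqs, dtype=float)
    if len(maf) != len(r2):
        raise DataError("per-SNP r² and MAF are not aligned")
    edges = tuple(edges)
    inside = np.isfinite(maf) & (maf > edges[0]) & (maf <= edges[-1])
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        sel = inside & (maf > lo) & (maf <= hi)
        vals = r2[sel]
        vals = vals[np.isfinite(vals)]
        rows.append((lo, hi, int(sel.sum()), float(vals.mean()) if len(vals) else np.nan))
    table = pd.DataFrame(rows, columns=["low", "high", "n_snps", "mean_r2"])
    return MAFBinTable(table, edges, int((~inside).sum()))


@dataclass
class ChromEndReport:
    """Mean per-SNP r² over the first/last ``n`` SNPs of each chromosome."""

    table: pd.DataFrame  # chrom, n_snps, start_mean_r2, end_mean_r2, whole_mean_r2, truncated
    n: int


def chromosome_end_accuracy(per_snp_r2, marker_map: MarkerMap, n: int = 100) -> ChromEndReport:
    """End windows in map order; short chromosomes truncate at the midpoint."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    r2 = pd.Series(np.asarray(per_snp_r2, dtype=float), index=marker_map.snp_ids)
    rows = []
    for chrom in marker_map.chromosomes:
        ids = marker_map.table.loc[marker_map.table["chrom"] == chrom, "snp_id"]
        vals = r2.reindex(ids).to_numpy()
        if np.all(np.isnan(vals)):
            continue
        m = len(vals)
        truncated = m < 2 * n
        head = min(n, m // 2) if truncated else n
        tail = m - head if truncated else n

        def _mean(x):
            x = x[np.isfinite(x)]
            return float(x.mean()) if len(x) else np.nan

        rows.append((chrom, m, _mean(vals[:head]), _mean(vals[m - tail:]),
                     _mean(vals), truncated))
    table = pd.DataFrame(rows, columns=[
        "chrom", "n_snps", "start_mean_r2", "end_mean_r2", "whole_mean_r2", "truncated"])
    return ChromEndReport(table, n)


@dataclass
class Scenario:
    """One reference/target/panel configuration.

    ``reference``/``targets`` may be explicit id lists, or selection rules
    may pick them from a pedigree: oldest animals (by birth year) become the
    reference, youngest the targets, optionally restricted by dominant
    breed.  ``max_relationship`` drops reference animals whose genomic
    relationship to any target exceeds the cut-off (0.45 mirrors the
    parentage-level exclusion used to study relatedness impact).
    """

    name: str
    source_panel: PanelDef
    target_panel: PanelDef
    method: dict = field(default_factory=lambda: {"name": "window"})
    reference: list | None = None
    targets: list | None = None
    n_reference: int | None = None
    n_targets: int | None = None
    reference_breed: str | None = None
    target_breed: str | None = None
    max_relationship: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.source_panel.issubset(self.target_panel):
            raise ParameterError("source panel must be a subset of the target panel")
        if self.reference is not None and self.targets is not None:
            if set(self.reference) & set(self.targets):
                raise ParameterError("reference and target sets overlap")


@dataclass
class AccuracyReport:
    scenario: str
    per_animal: pd.DataFrame  # animal, cr, r2
    per_snp: pd.DataFrame  # snp_id, cr, r2, maf
    overall_cr: float
    overall_r2: float
    evaluated: str  # "masked" or "all"
    n_reference: int
    n_targets: int
    excluded_reference: list = field(default_factory=list)
    empty_evaluation: bool = False
    top10: object = None

    def per_animal_sorted(self) -> pd.DataFrame:
        """Per-animal CR sorted highest to lowest (figure convention)."""
        return self.per_animal.sort_values("cr", ascending=False).reset_index(drop=True)


def _select_by_year(pedigree: Pedigree, breed: str | None, n: int, oldest: bool,
                    exclude: set, rng: np.random.Generator) -> list:
    tab = pedigree.table
    dom = pedigree.dominant_breed()
    mask = ~tab["animal"].isin(exclude)
    if breed is not None:
        mask &= tab["animal"].map(dom) == breed
    cand = tab[mask]
    years = sorted(cand["year"].unique(), reverse=not oldest)
    chosen: list = []
    for y in years:
        group = cand.loc[cand["year"] == y, "animal"].tolist()
        need = n - len(chosen)
        if need <= 0:
            break
        if len(group) > need:  # sample randomly within the year group
            take = rng.choice(len(group), size=need, replace=False)
            group = [group[i] for i in sorted(take)]
        chosen.extend(group)
    if len(chosen) < n:
        raise DataError(f"only {len(chosen)} animals available, {n} requested")
    return chosen


def run_scenario(
    scenario: Scenario,
    truth: GenotypeMatrix,
    pedigree: Pedigree | None = None,
    evaluated: str = "masked",
    window: int = 40,
    overlap: int = 10,
    compute_top10: bool = True,
) -> AccuracyReport:
    """Mask targets to the source panel, impute, and evaluate against truth.

    The imputer is chosen by ``scenario.method["name"]``: ``"major"`` for
    the by-chance baseline or ``"window"`` for the window-haplotype
    reference imputer (``window``/``overlap`` overridable via the method
    dict).  All randomness (year-group sampling) is seeded by
    ``scenario.seed``, so reports are bit-identical across runs.
    """
    rng = np.random.default_rng(scenario.seed)
    reference = list(scenario.reference) if scenario.reference is not None else None
    targets = list(scenario.targets) if scenario.targets is not None else None
    if targets is None:
        if pedigree is None or scenario.n_targets is None:
            raise ParameterError("need explicit targets or a pedigree with n_targets")
        targets = _select_by_year(pedigree, scenario.target_breed, scenario.n_targets,
                                  oldest=False, exclude=set(), rng=rng)
    if reference is None:
        if pedigree is None or scenario.n_reference is None:
            raise ParameterError("need explicit reference or a pedigree with n_reference")
        reference = _select_by_year(pedigree, scenario.reference_breed,
                                    scenario.n_reference, oldest=True,
                                    exclude=set(targets), rng=rng)

    excluded: list = []
    if scenario.max_relationship is not None:
        union = reference + targets
        sub = truth.subset_animals(union).subset_snps(list(scenario.target_panel.snp_ids))
        freqs = allele_frequencies(sub)
        gmat = compute_G(sub, freqs)
        idx = {a: i for i, a in enumerate(gmat.animals)}
        t_idx = np.array([idx[a] for a in targets])
        for a in reference:
            if gmat.G[idx[a], t_idx].max() > scenario.max_relationship:
                excluded.append(a)
        reference = [a for a in reference if a not in set(excluded)]
        if not reference:
            raise DataError(
                f"relatedness cut-off {scenario.max_relationship} removed every "
                "reference animal")

    frame_ids = list(scenario.target_panel.snp_ids)
    truth_t = truth.subset_animals(targets).subset_snps(frame_ids)
    ref_g = truth.subset_animals(reference).subset_snps(frame_ids)
    masked = mask_to_panel(truth_t, scenario.source_panel)

    method = dict(scenario.method)
    name = method.get("name", "window")
    if name == "major":
        freqs = allele_frequencies(ref_g)
        result = _impute.impute_major_allele(masked, freqs)
    elif name == "window":
        result = _impute.impute_window_haplotype(
            masked, ref_g, scenario.source_panel, scenario.target_panel,
            window=int(method.get("window", window)),
            overlap=int(method.get("overlap", overlap)),
        )
    else:
        raise ParameterError(f"unknown imputation method {name!r}")

    source_set = set(scenario.source_panel.snp_ids)
    masked_cols = np.array([s not in source_set for s in truth_t.snps])
    if evaluated == "masked":
        eval_cols = masked_cols
    elif evaluated == "all":
        eval_cols = np.ones(truth_t.n_snps, dtype=bool)
    else:
        raise ParameterError("evaluated must be 'masked' or 'all'")

    empty = not eval_cols.any()
    if empty:
        per_animal = pd.DataFrame({"animal": truth_t.animals,
                                   "cr": 100.0, "r2": np.nan})
        per_snp = pd.DataFrame(columns=["snp_id", "cr", "r2", "maf"])
        overall_cr, overall_r2 = 100.0, np.nan
    else:
        cr_a = concordance_rate(truth_t, result.genotypes, "animal", eval_cols)
        r2_a = allelic_r2(truth_t, result.genotypes, "animal", eval_cols)
        cr_s = concordance_rate(truth_t, result.genotypes, "snp", eval_cols)
        r2_s = allelic_r2(truth_t, result.genotypes, "snp", eval_cols)
        union_freqs = allele_frequencies(truth.subset_snps(frame_ids),
                                         reference + targets)
        maf = np.minimum(union_freqs.p, 1 - union_freqs.p)[eval_cols]
        per_animal = pd.DataFrame({"animal": truth_t.animals, "cr": cr_a, "r2": r2_a})
        per_snp = pd.DataFrame({"snp_id": truth_t.snps[eval_cols],
                                "cr": cr_s[eval_cols], "r2": r2_s[eval_cols],
                                "maf": maf})
        overall_cr = float(np.nanmean(cr_a))
        overall_r2 = float(np.nanmean(r2_a))

    top10 = None
    if compute_top10 and not empty:
        sub = truth.subset_animals(reference + targets).subset_snps(frame_ids)
        freqs = allele_frequencies(sub)
        top10 = top_k_relationships(compute_G(sub, freqs), reference, targets, k=10)

    return AccuracyReport(
        scenario.name, per_animal, per_snp, overall_cr, overall_r2, evaluated,
        len(reference), len(targets), excluded, empty, top10,
    )
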