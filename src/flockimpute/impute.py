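"""Filling masked genotypes.

Two built-in imputers are provided:

* :func:`impute_major_allele` — the "imputation by chance" baseline that
  replaces every missing genotype with the homozygote of the more frequent
  allele.  Its expected concordance under Hardy–Weinberg is the mean
  major-homozygote genotype frequency, which anchors the accuracy scale.
* :func:`impute_window_haplotype` — a deliberately simple, fully
  deterministic reference imputer: in each overlapping window of the
  high-density SNP order it copies genotypes from the reference animal whose
  observed low-density genotypes best match the target.  It is NOT a
  re-implementation of any published imputation software; it exists so the
  evaluation and prediction machinery can be exercised end to end.

Two-step orchestration (low -> mid against a large mid-density reference,
then mid -> high) and export/import shims for external imputation tools
round out the module.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .core import (
    MISSING,
    DataError,
    GenotypeMatrix,
    PanelDef,
    ParameterError,
)
from .relatedness import AlleleFrequencies

__all__ = [
    "ImputationResult",
    "impute_major_allele",
    "impute_window_haplotype",
    "impute_two_step",
    "export_external",
    "import_external",
]


@dataclass
class ImputationResult:
    genotypes: GenotypeMatrix
    imputed_mask: np.ndarray  # True where a value was filled
    method: str
    step_trace: list = field(default_factory=list)


def impute_major_allele(masked: GenotypeMatrix, freqs: AlleleFrequencies) -> ImputationResult:
    """Fill every missing entry with the major-allele homozygote.

    p_i < 0.5 -> 0, p_i > 0.5 -> 2, p_i == 0.5 -> heterozygote (1).
    """
    idx = {s: i for i, s in enumerate(freqs.snps)}
    try:
        order = np.array([idx[s] for s in masked.snps])
    except KeyError as exc:
        raise DataError(f"no frequency for SNP {exc.args[0]!r}") from None
    p = freqs.p[order]
    defined = freqs.defined[order] & np.isfinite(p)
    missing = masked.missing_mask()
    need = missing.any(axis=0)
    bad = need & ~defined
    if bad.any():
        raise DataError(f"undefined frequency for SNPs to fill: {list(masked.snps[bad])[:5]}")
    fill = np.where(p < 0.5, 0, np.where(p > 0.5, 2, 1)).astype(np.int8)
    out = masked.copy()
    out.data[missing] = np.broadcast_to(fill, out.data.shape)[missing]
    return ImputationResult(out, missing, "major_allele")


def _window_starts(n: int, window: int, step: int) -> list:
    starts = list(range(0, max(n - window, 0) + 1, step))
    if not starts:
        starts = [0]
    if starts[-1] + window < n:  # cover the tail
        starts.append(n - window if n >= window else 0)
    return starts


def impute_window_haplotype(
    masked: GenotypeMatrix,
    reference: GenotypeMatrix,
    panel_low: PanelDef,
    panel_high: PanelDef,
    window: int = 40,
    overlap: int = 10,
) -> ImputationResult:
    """Deterministic sliding-window nearest-reference imputation.

    Windows are defined on the panel_high SNP order.  Within each window the
    reference animal minimising the mean absolute dosage difference on
    co-observed panel_low SNPs is selected (ties -> lower animal id) and its
    genotypes are copied into the target's missing entries.  Cells proposed
    by several overlapping windows are resolved by majority vote; remaining
    ties take the later window's value.
    """
    if window < 2:
        raise ParameterError("window must be >= 2 SNPs")
    if not (0 <= overlap < window):
        raise ParameterError("need window > overlap >= 0")
    if reference.n_animals == 0:
        raise DataError("empty reference set")
    if not panel_low.issubset(panel_high):
        raise ParameterError("panel_low must be a subset of panel_high")

    high_ids = [s for s in panel_high.snp_ids if s is not None]
    t_cols = masked.snp_indices(high_ids)
    r_cols = reference.snp_indices(high_ids)
    R = reference.data[:, r_cols]
    if (R == MISSING).any():
        raise DataError("reference must be fully genotyped on panel_high")
    # sort reference by animal id so argmin tie-breaks to the lowest id
    r_order = np.argsort(reference.animals.astype(str), kind="stable")
    R = R[r_order]
    low_set = set(panel_low.snp_ids)
    is_low = np.array([s in low_set for s in high_ids])

    T = masked.data[:, t_cols]
    nt, H = T.shape
    step = window - overlap
    n_states = 3
    votes = np.zeros((nt, H, n_states), dtype=np.int16)
    last = np.full((nt, H, n_states), -1, dtype=np.int32)
    Rf = R.astype(np.float64)

    starts = _window_starts(H, window, step)
    for w_i, start in enumerate(starts):
        stop = min(start + window, H)
        wl = np.arange(start, stop)[is_low[start:stop]]
        Tw = T[:, wl]
        Rw = Rf[:, wl]
        called = Tw != MISSING
        n_co = called.sum(axis=1).astype(np.float64)  # ref fully called
        # L1 distance through one-hot matmuls (mask-aware, no target copies)
        dist = np.zeros((nt, R.shape[0]))
        for v in (0, 1, 2):
            ind = (Tw == v).astype(np.float64)
            dist += ind @ np.abs(v - Rw).T
        with np.errstate(invalid="ignore", divide="ignore"):
            mismatch = np.where(n_co[:, None] > 0, dist / np.maximum(n_co[:, None], 1), np.inf)
        best = np.argmin(mismatch, axis=1)  # first minimum -> lowest ref id
        fill_zone = T[:, start:stop] == MISSING
        ti, cj = np.nonzero(fill_zone)
        if len(ti):
            vals = R[best[ti], start + cj]
            np.add.at(votes, (ti, start + cj, vals), 1)
            last[ti, start + cj, vals] = w_i

    score = votes.astype(np.int64) * (len(starts) + 1) + (last + 1)
    winner = score.argmax(axis=2).astype(np.int8)
    has_vote = votes.sum(axis=2) > 0
    out = masked.copy()
    filled = np.zeros(out.data.shape, dtype=bool)
    rows = np.repeat(np.arange(nt), H).reshape(nt, H)
    cols_full = np.broadcast_to(t_cols, (nt, H))
    fill_cells = has_vote
    out.data[rows[fill_cells], cols_full[fill_cells]] = winner[fill_cells]
    filled[rows[fill_cells], cols_full[fill_cells]] = True
    return ImputationResult(out, filled, f"window_haplotype(window={window},overlap={overlap})")


def impute_two_step(
    masked_low: GenotypeMatrix,
    reference_mid: GenotypeMatrix,
    reference_high: GenotypeMatrix,
    panels: tuple,
    window: int = 40,
    overlap: int = 10,
) -> ImputationResult:
    """Low -> mid against ``reference_mid``, then mid -> high against
    ``reference_high``; the step trace records both stages."""
    panel_low, panel_mid, panel_high = panels
    if not (panel_low.issubset(panel_mid) and panel_mid.issubset(panel_high)):
        raise ParameterError("panels must be nested low <= mid <= high")
    step1 = impute_window_haplotype(
        masked_low, reference_mid, panel_low, panel_mid, window=window, overlap=overlap
    )
    step2 = impute_window_haplotype(
        step1.genotypes, reference_high, panel_mid, panel_high, window=window, overlap=overlap
    )
    trace = [
        {"step": 1, "from": panel_low.name, "to": panel_mid.name,
         "reference_size": reference_mid.n_animals, "method": step1.method},
        {"step": 2, "from": panel_mid.name, "to": panel_high.name,
         "reference_size": reference_high.n_animals, "method": step2.method},
    ]
    return ImputationResult(
        step2.genotypes, step1.imputed_mask | step2.imputed_mask, "two_step", trace
    )


# ---------------------------------------------------------------- external tools

_FIMPUTE_MISSING = "5"
_BEAGLE_MISSING = "?"


def export_external(
    masked: GenotypeMatrix,
    reference: GenotypeMatrix,
    format: str,
    outdir,
    marker_map=None,
) -> dict:
    """Write genotype + marker-info files in an external tool's dialect.

    ``fimpute_dialect``: one genotype file (ID, chip index, dosage string
    with '5' for missing) plus a SNP-info file; reference animals carry chip
    1, targets chip 2.  ``beagle3_dialect``: one unphased genotype file per
    chip (rows ``M snp a1 a2 ...``) plus a marker file.
    """
    os.makedirs(outdir, exist_ok=True)
    if not np.array_equal(masked.snps, reference.snps):
        raise DataError("masked and reference SNP frames differ")
    snps = masked.snps
    if format == "fimpute_dialect":
        geno_path = os.path.join(outdir, "genotypes.txt")
        snp_path = os.path.join(outdir, "snp_info.txt")
        with open(geno_path, "w") as fh:
            fh.write("ID Chip Call...\n")
            for chip, g in ((1, reference), (2, masked)):
                for i, animal in enumerate(g.animals):
                    s = "".join(_FIMPUTE_MISSING if d == MISSING else str(int(d))
                                for d in g.data[i])
                    fh.write(f"{animal} {chip} {s}\n")
        with open(snp_path, "w") as fh:
            fh.write("SNP_ID Chr Pos Chip1 Chip2\n")
            for j, s in enumerate(snps, start=1):
                chrom, pos = "1", j
                if marker_map is not None:
                    row = marker_map.table.set_index("snp_id").loc[s]
                    chrom, pos = row["chrom"], int(row["pos"])
                fh.write(f"{s} {chrom} {pos} {j} {j}\n")
        return {"genotypes": geno_path, "snp_info": snp_path}
    if format == "beagle3_dialect":
        marker_path = os.path.join(outdir, "markers.txt")
        with open(marker_path, "w") as fh:
            for j, s in enumerate(snps, start=1):
                fh.write(f"{s} {j} A B\n")
        paths = {"markers": marker_path}
        allele = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"),
                  MISSING: (_BEAGLE_MISSING, _BEAGLE_MISSING)}
        for label, g in (("reference", reference), ("target", masked)):
            path = os.path.join(outdir, f"{label}.bgl")
            with open(path, "w") as fh:
                fh.write("I id " + " ".join(f"{a} {a}" for a in g.animals) + "\n")
                for j, s in enumerate(snps):
                    pairs = (allele[int(d)] for d in g.data[:, j])
                    fh.write(f"M {s} " + " ".join(f"{x} {y}" for x, y in pairs) + "\n")
            paths[label] = path
        return paths
    raise ParameterError(f"unknown external dialect {format!r}")


def import_external(files: dict, format: str) -> ImputationResult:
    """Map an external tool's (possibly untouched) output back onto the
    internal frame.  Returns all animals found; chip/role labels are kept in
    the step trace.  Round-trips losslessly for non-missing entries."""
    if format == "fimpute_dialect":
        snps = []
        with open(files["snp_info"]) as fh:
            next(fh)
            for line in fh:
                if line.strip():
                    snps.append(line.split()[0])
        animals, chips, rows = [], [], []
        with open(files["genotypes"]) as fh:
            next(fh)
            for line in fh:
                if not line.strip():
                    continue
                aid, chip, calls = line.split()
                animals.append(aid)
                chips.append(int(chip))
                rows.append([MISSING if ch == _FIMPUTE_MISSING else int(ch) for ch in calls])
        geno = GenotypeMatrix(np.array(animals, dtype=object),
                              np.array(snps, dtype=object),
                              np.array(rows, dtype=np.int8))
        trace = [{"chips": dict(zip(animals, chips))}]
        return ImputationResult(geno, geno.missing_mask() & False, "external:fimpute", trace)
    if format == "beagle3_dialect":
        snps = []
        with open(files["markers"]) as fh:
            for line in fh:
                if line.strip():
                    snps.append(line.split()[0])
        all_animals, all_rows, roles = [], [], {}
        for label in ("reference", "target"):
            if label not in files:
                continue
            with open(files[label]) as fh:
                header = next(fh).split()
                animals = header[2::2]
                cols = {s: [] for s in range(len(animals))}
                mat = np.full((len(snps), len(animals)), MISSING, dtype=np.int8)
                for r, line in enumerate(fh):
                    parts = line.split()
                    alleles = parts[2:]
                    for a_i in range(len(animals)):
                        x, y = alleles[2 * a_i], alleles[2 * a_i + 1]
                        if x == _BEAGLE_MISSING or y == _BEAGLE_MISSING:
                            continue
                        mat[r, a_i] = (x == "B") + (y == "B")
            all_animals.extend(animals)
            all_rows.append(mat.T)
            roles.update({a: label for a in animals})
        geno = GenotypeMatrix(np.array(all_animals, dtype=object),
                              np.array(snps, dtype=object),
                              np.vstack(all_rows))
        return ImputationResult(geno, geno.missing_mask() & False, "external:beagle3",
                                [{"roles": roles}])
    raise ParameterError(f"unknown external dialect {format!r}")
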