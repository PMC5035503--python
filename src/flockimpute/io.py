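"""Reading and writing genotype, marker, pedigree and panel files.

Supported genotype formats are PLINK-style text (.ped/.map) and VCF v4.x
(GT field only).  Dosages count copies of the B allele; for VCF the B
allele is ALT (so REF = A), for PLINK text the A allele is the first allele
listed in the file for that SNP unless a :class:`~flockimpute.core.MarkerMap`
with allele labels is supplied.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    DataError,
    GenotypeMatrix,
    MarkerMap,
    ParameterError,
    Pedigree,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
    "write_vcf",
    "read_plink",
    "write_plink",
    "read_pedigree",
    "write_pedigree",
    "read_panel",
    "write_panel",
]


def read_genotypes(path, format: str, marker_map: MarkerMap | None = None):
    """Dispatch to :func:`read_vcf` or :func:`read_plink` by ``format``."""
    if format == "vcf":
        return read_vcf(path)
    if format == "plink_text":
        return read_plink(path, marker_map=marker_map)
    raise ParameterError(f"unknown genotype format {format!r}")


def write_genotypes(path, genotypes: GenotypeMatrix, marker_map: MarkerMap, format: str):
    if format == "vcf":
        return write_vcf(path, genotypes, marker_map)
    if format == "plink_text":
        return write_plink(path, genotypes, marker_map)
    raise ParameterError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------- VCF

def write_vcf(path, genotypes: GenotypeMatrix, marker_map: MarkerMap) -> str:
    """Plain-text VCF v4.2 with GT only; REF = allele A, ALT = allele B."""
    geno = genotypes.subset_snps(marker_map.snp_ids)
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in marker_map.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(a) for a in geno.animals) + "\n")
        for j, row in enumerate(marker_map.table.itertuples(index=False)):
            calls = "\t".join(gt_code[int(d)] for d in geno.data[:, j])
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{row.snp_id}\t{row.allele_a}\t"
                f"{row.allele_b}\t.\t.\t.\tGT\t{calls}\n"
            )
    return str(path)


def read_vcf(path):
    """Read a VCF (plain or bgzipped) into (GenotypeMatrix, MarkerMap)."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises opaque OSError subclasses
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    animals = np.array(vcf.samples, dtype=object)
    ids, rows, recs = [], [], []
    # cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for line_no, v in enumerate(vcf, start=1):
        snp_id = v.ID or f"{v.CHROM}:{v.POS}"
        alt = v.ALT[0] if v.ALT else "B"
        ids.append(snp_id)
        recs.append((snp_id, v.CHROM, v.POS, v.REF, alt))
        gt = np.asarray(v.gt_types)
        if gt.shape[0] != len(animals):
            raise DataError(f"malformed VCF record at variant {line_no} of {path}")
        rows.append(code[gt])
    if len(set(ids)) != len(ids):
        raise DataError(f"duplicated snp_id in {path}")
    mmap = MarkerMap(pd.DataFrame(recs, columns=["snp_id", "chrom", "pos", "allele_a", "allele_b"]))
    data = np.column_stack(rows) if rows else np.zeros((len(animals), 0), dtype=np.int8)
    geno = GenotypeMatrix(animals, np.array(ids, dtype=object), data)
    return geno.subset_snps(mmap.snp_ids), mmap


# ---------------------------------------------------------------- PLINK text

def write_plink(prefix, genotypes: GenotypeMatrix, marker_map: MarkerMap) -> tuple:
    """Write ``<prefix>.ped`` and ``<prefix>.map`` (4-column map)."""
    geno = genotypes.subset_snps(marker_map.snp_ids)
    map_path, ped_path = f"{prefix}.map", f"{prefix}.ped"
    tab = marker_map.table
    with open(map_path, "w") as fh:
        for row in tab.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{int(row.pos)}\n")
    a = tab["allele_a"].to_numpy(dtype=object)
    b = tab["allele_b"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(geno.animals):
            fields = [str(animal), str(animal), "0", "0", "0", "-9"]
            d = geno.data[i]
            for j in range(geno.n_snps):
                if d[j] == 0:
                    fields += [a[j], a[j]]
                elif d[j] == 1:
                    fields += [a[j], b[j]]
                elif d[j] == 2:
                    fields += [b[j], b[j]]
                else:
                    fields += ["0", "0"]
            fh.write(" ".join(map(str, fields)) + "\n")
    return ped_path, map_path


def read_plink(prefix, marker_map: MarkerMap | None = None):
    """Read ``<prefix>.ped``/``<prefix>.map`` into (GenotypeMatrix, MarkerMap).

    Without a supplied marker map the A allele at each SNP is the first
    allele listed in the file, which fixes dosage polarity only up to the
    order animals appear; pass the writing map to round-trip exactly.
    """
    map_path, ped_path = f"{prefix}.map", f"{prefix}.ped"
    for p in (map_path, ped_path):
        if not os.path.exists(p):
            raise DataError(f"missing PLINK file {p}")
    mtab = pd.read_csv(map_path, sep=r"\s+", header=None,
                       names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str})
    if mtab["snp_id"].duplicated().any():
        raise DataError(f"duplicated snp_id in {map_path}")
    n_snps = len(mtab)
    snp_order = mtab["snp_id"].to_numpy(dtype=object)

    if marker_map is not None:
        lab = marker_map.table.set_index("snp_id")
        missing_ids = [s for s in snp_order if s not in lab.index]
        if missing_ids:
            raise DataError(f"marker map lacks SNPs from {map_path}: {missing_ids[:5]}")
        allele_a = np.array([lab.at[s, "allele_a"] for s in snp_order], dtype=object)
        allele_b = np.array([lab.at[s, "allele_b"] for s in snp_order], dtype=object)
    else:
        allele_a = np.array([None] * n_snps, dtype=object)
        allele_b = np.array([None] * n_snps, dtype=object)

    animals, rows = [], []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise DataError(
                    f"{ped_path} line {line_no}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)}"
                )
            animals.append(parts[1])
            alleles = parts[6:]
            dosages = np.full(n_snps, MISSING, dtype=np.int8)
            for j in range(n_snps):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    continue
                for al in (a1, a2):
                    if allele_a[j] is None:
                        allele_a[j] = al
                    elif allele_b[j] is None and al != allele_a[j]:
                        allele_b[j] = al
                    elif al not in (allele_a[j], allele_b[j]):
                        raise DataError(
                            f"{ped_path} line {line_no}: SNP {snp_order[j]} has a "
                            f"third allele {al!r}"
                        )
                dosages[j] = (a1 == allele_b[j]) + (a2 == allele_b[j])
            rows.append(dosages)

    allele_a = np.array([a if a is not None else "A" for a in allele_a], dtype=object)
    allele_b = np.array(
        [b if b is not None else ("B" if a != "B" else "A2")
         for a, b in zip(allele_a, allele_b)], dtype=object)
    mmap = MarkerMap(pd.DataFrame({
        "snp_id": snp_order, "chrom": mtab["chrom"].to_numpy(dtype=object),
        "pos": mtab["pos"].to_numpy(), "allele_a": allele_a, "allele_b": allele_b,
    }))
    data = np.vstack(rows) if rows else np.zeros((0, n_snps), dtype=np.int8)
    geno = GenotypeMatrix(np.array(animals, dtype=object), snp_order, data)
    return geno.subset_snps(mmap.snp_ids), mmap


# ---------------------------------------------------------------- pedigree / panels

def write_pedigree(path, pedigree: Pedigree) -> str:
    tab = pedigree.table.copy()
    tab["sire"] = tab["sire"].fillna("0")
    tab["dam"] = tab["dam"].fillna("0")
    tab.to_csv(path, sep="\t", index=False)
    return str(path)


def read_pedigree(path, breeds=None) -> Pedigree:
    tab = pd.read_csv(path, sep="\t", dtype={"animal": str, "sire": str, "dam": str})
    if breeds is None:
        fixed = {"animal", "sire", "dam", "year", "sex"}
        breeds = [c for c in tab.columns if c not in fixed]
    tab["sire"] = tab["sire"].where(tab["sire"] != "0", None)
    tab["dam"] = tab["dam"].where(tab["dam"] != "0", None)
    return Pedigree(tab, tuple(breeds))


def write_panel(path, panel) -> str:
    with open(path, "w") as fh:
        for s in panel.snp_ids:
            fh.write(f"{s}\n")
    return str(path)


def read_panel(path, name: str | None = None):
    from .core import PanelDef

    with open(path) as fh:
        ids = tuple(line.strip() for line in fh if line.strip())
    return PanelDef(name or os.path.basename(str(path)), ids)
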