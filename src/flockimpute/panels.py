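"""Nested SNP panel construction and panel masking.

Low-density panels are modelled by masking: SNPs outside a panel are set to
missing while the full-density SNP frame is retained, so true and imputed
matrices stay column-aligned for evaluation.
"""

from __future__ import annotations

import numpy as np

from .core import MISSING, DataError, GenotypeMatrix, MarkerMap, PanelDef

__all__ = ["build_panels", "mask_to_panel", "evenly_spaced_panels"]


def build_panels(marker_map: MarkerMap, definitions, nested: bool = True) -> list:
    """Intersect each named SNP-id list with the map, preserving list order.

    ``definitions``: mapping name -> iterable of SNP ids (insertion order is
    the low-to-high panel order) or an iterable of (name, ids) pairs.  With
    ``nested=True`` each earlier panel must be a subset of every later one.
    """
    if hasattr(definitions, "items"):
        pairs = list(definitions.items())
    else:
        pairs = list(definitions)
    in_map = set(marker_map.snp_ids)
    panels = []
    for name, ids in pairs:
        ids = list(ids)
        if not ids:
            raise DataError(f"panel definition {name!r} is empty")
        retained = tuple(s for s in ids if s in in_map)
        if not retained:
            raise DataError(f"panel {name!r} has no SNPs left after map intersection")
        panels.append(PanelDef(name, retained))
    if nested:
        for low, high in zip(panels, panels[1:]):
            if not low.issubset(high):
                raise DataError(f"panel {low.name!r} is not nested within {high.name!r}")
    return panels


def evenly_spaced_panels(marker_map: MarkerMap, sizes: dict) -> list:
    """Nested panels by even subsampling of the map, lowest density first.

    ``sizes`` maps panel name -> target SNP count, in increasing order.
    Each panel is drawn from the next denser one, which guarantees nesting.
    """
    names = list(sizes)
    all_ids = list(marker_map.snp_ids)
    top = names[-1]
    if sizes[top] >= len(all_ids):
        panels_ids = {top: all_ids}
    else:
        take = np.unique(np.linspace(0, len(all_ids) - 1, sizes[top]).astype(int))
        panels_ids = {top: [all_ids[i] for i in take]}
    prev_name = top
    for name in reversed(names[:-1]):
        parent = panels_ids[prev_name]
        take = np.unique(np.linspace(0, len(parent) - 1, min(sizes[name], len(parent))).astype(int))
        panels_ids[name] = [parent[i] for i in take]
        prev_name = name
    return build_panels(marker_map, [(n, panels_ids[n]) for n in names], nested=True)


def informative_panels(
    marker_map: MarkerMap,
    genotypes: GenotypeMatrix,
    sizes: dict,
    min_maf: float = 0.1,
) -> list:
    """Nested panels whose lower densities prefer common SNPs.

    Commercial low-density chips are designed around informative (high-MAF)
    markers; this helper mirrors that.  The densest panel takes the whole
    map; each lower panel is evenly spaced (by map order) among the SNPs of
    the next denser panel with sample MAF >= ``min_maf``, falling back to
    the full parent panel if too few common SNPs exist.
    """
    from .qc import snp_statistics

    names = list(sizes)
    stats = snp_statistics(genotypes.subset_snps(marker_map.snp_ids))
    maf = dict(zip(stats["snp_id"], stats["maf"]))
    panels_ids = {names[-1]: list(marker_map.snp_ids)}
    prev = names[-1]
    for name in reversed(names[:-1]):
        parent = panels_ids[prev]
        pool = [s for s in parent if maf.get(s, 0) >= min_maf]
        if len(pool) < sizes[name]:
            pool = parent
        take = np.unique(np.linspace(0, len(pool) - 1, min(sizes[name], len(pool))).astype(int))
        panels_ids[name] = [pool[i] for i in take]
        prev = name
    return build_panels(marker_map, [(n, panels_ids[n]) for n in names], nested=True)


def mask_to_panel(genotypes: GenotypeMatrix, panel: PanelDef) -> GenotypeMatrix:
    """Set SNPs outside ``panel`` to missing; frame and order unchanged."""
    present = set(genotypes.snps)
    absent = [s for s in panel.snp_ids if s not in present]
    if absent:
        raise DataError(f"panel SNPs absent from genotypes: {absent[:5]}")
    out = genotypes.copy()
    keep = np.isin(out.snps.astype(str), np.array([str(s) for s in panel.snp_ids]))
    out.data[:, ~keep] = MISSING
    return out
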