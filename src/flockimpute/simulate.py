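"""Synthetic multi-breed pedigreed SNP data.

The generator produces the study conditions every downstream stage is
exercised under: several purebred groups with Balding–Nichols divergence
from a shared base population, composite crosses, one weakly related
terminal group, gene-dropped genotypes with Haldane (no-interference)
recombination, and nested panel densities.  Founder haplotypes are drawn
independently per SNP, so linkage disequilibrium beyond family sharing is
not modelled (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import (
    MISSING,
    DataError,
    GenotypeMatrix,
    MarkerMap,
    ParameterError,
    Pedigree,
)

__all__ = [
    "CrossRule",
    "BreedPlan",
    "GeneticMap",
    "HaplotypeSet",
    "default_breed_plan",
    "plan_from_yaml",
    "plan_to_yaml",
    "uniform_genetic_map",
    "simulate_founder_frequencies",
    "simulate_pedigree",
    "founder_haplotypes",
    "draw_crossovers",
    "gene_drop",
    "add_noise",
    "simulate_population",
    "SimulatedPopulation",
]


@dataclass(frozen=True)
class CrossRule:
    """One mating group within a generation.

    Dams (sires) are drawn from earlier-born females (males) whose dominant
    breed-composition entry equals ``dam_breed`` (``sire_breed``).  A small
    sire pool (default about one sire per ten offspring) yields the
    half-sib-dominated family structure typical of sheep flocks.
    """

    dam_breed: str
    sire_breed: str
    n_offspring: int
    n_sires: int | None = None


@dataclass
class BreedPlan:
    """Breeds, their divergence from the base population, and mating rules."""

    breeds: list
    divergence: dict
    founders: dict
    crosses: list  # one list[CrossRule] per generation

    def __post_init__(self) -> None:
        self.breeds = list(self.breeds)
        for b in self.breeds:
            c = self.divergence.get(b, 0.0)
            if not (0.0 <= c < 1.0):
                raise ParameterError(f"divergence for {b!r} must be in [0, 1): {c}")
        for b, n in self.founders.items():
            if b not in self.breeds:
                raise ParameterError(f"founder count for unknown breed {b!r}")
            if n < 2:
                raise ParameterError(f"breed {b!r} needs >= 2 founders, got {n}")
        for gen in self.crosses:
            for rule in gen:
                for b in (rule.dam_breed, rule.sire_breed):
                    if b not in self.breeds:
                        raise ParameterError(f"crossing rule references unknown breed {b!r}")
                if rule.n_offspring < 1:
                    raise ParameterError("n_offspring must be >= 1")

    @property
    def generations(self) -> int:
        return len(self.crosses)


def default_breed_plan(scale: float = 1.0, generations: int = 3) -> BreedPlan:
    """Multi-breed default: three related maternal breeds, a Romney x
    Coopworth composite stream, and an unrelated terminal group (primera)
    that never crosses into the others.
    """

    def n(x: int) -> int:
        return max(2, int(round(x * scale)))

    rules = [
        CrossRule("romney", "romney", n(120)),
        CrossRule("coopworth", "coopworth", n(60)),
        CrossRule("perendale", "perendale", n(40)),
        CrossRule("primera", "primera", n(60)),
        CrossRule("romney", "coopworth", n(40)),
    ]
    return BreedPlan(
        breeds=["romney", "coopworth", "perendale", "primera"],
        divergence={"romney": 0.05, "coopworth": 0.05, "perendale": 0.06, "primera": 0.3},
        founders={"romney": n(80), "coopworth": n(40), "perendale": n(30), "primera": n(40)},
        crosses=[list(rules) for _ in range(generations)],
    )


def plan_from_yaml(path) -> BreedPlan:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    crosses = [
        [CrossRule(r["dam_breed"], r["sire_breed"], r["n_offspring"], r.get("n_sires"))
         for r in gen]
        for gen in doc["crosses"]
    ]
    return BreedPlan(doc["breeds"], doc["divergence"], doc["founders"], crosses)


def plan_to_yaml(plan: BreedPlan, path) -> None:
    doc = {
        "breeds": list(plan.breeds),
        "divergence": dict(plan.divergence),
        "founders": dict(plan.founders),
        "crosses": [
            [{"dam_breed": r.dam_breed, "sire_breed": r.sire_breed,
              "n_offspring": r.n_offspring, "n_sires": r.n_sires} for r in gen]
            for gen in plan.crosses
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class GeneticMap:
    """Physical positions (bp) and genetic lengths (Morgans) per chromosome."""

    chromosomes: list
    positions: dict  # chrom -> strictly increasing bp array
    lengths: dict  # chrom -> Morgans

    def __post_init__(self) -> None:
        for c in self.chromosomes:
            pos = np.asarray(self.positions[c], dtype=np.int64)
            if len(pos) == 0:
                raise ParameterError(f"chromosome {c!r} has no SNPs")
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ParameterError(f"positions not strictly increasing on {c!r}")
            if self.lengths[c] < 0:
                raise ParameterError(f"genetic length of {c!r} must be >= 0")
            self.positions[c] = pos

    @property
    def n_snps(self) -> int:
        return sum(len(self.positions[c]) for c in self.chromosomes)

    def marker_map(self) -> MarkerMap:
        rows = []
        for c in self.chromosomes:
            for p in self.positions[c]:
                rows.append((f"snp_{c}_{p}", c, int(p), "A", "B"))
        return MarkerMap(pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "allele_a", "allele_b"]))

    def genetic_positions(self, chrom) -> np.ndarray:
        """Genetic position (Morgans) of each SNP, linear in bp."""
        pos = self.positions[chrom]
        span = pos[-1] - pos[0]
        if span == 0:
            return np.zeros(len(pos), dtype=float)
        return self.lengths[chrom] * (pos - pos[0]) / span


def uniform_genetic_map(
    n_chromosomes: int = 3,
    snps_per_chromosome: int = 500,
    chromosome_bp: int = 100_000_000,
    morgans: float = 1.0,
) -> GeneticMap:
    """Evenly spaced SNPs; one Morgan per chromosome by default."""
    chroms = [str(i + 1) for i in range(n_chromosomes)]
    step = chromosome_bp // (snps_per_chromosome + 1)
    pos = {c: np.arange(1, snps_per_chromosome + 1) * step for c in chroms}
    return GeneticMap(chroms, pos, {c: morgans for c in chroms})


@dataclass
class HaplotypeSet:
    """Phased binary alleles: animals x 2 x SNPs (1 = B allele)."""

    animals: np.ndarray
    snps: np.ndarray
    haplotypes: np.ndarray  # uint8, shape (n, 2, S)

    def __post_init__(self) -> None:
        self.animals = np.asarray(self.animals, dtype=object)
        self.snps = np.asarray(self.snps, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (len(self.animals), 2, len(self.snps)):
            raise DataError("haplotype array shape mismatch")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise DataError("haplotype alleles must be 0/1")

    def to_genotypes(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            self.animals.copy(), self.snps.copy(), self.haplotypes.sum(axis=1).astype(np.int8)
        )


def simulate_founder_frequencies(
    n_snps: int,
    plan: BreedPlan,
    base_maf_distribution: tuple = ("beta", 0.2, 0.2),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-breed B-allele frequencies under the Balding–Nichols model.

    A base frequency vector is drawn from ``base_maf_distribution`` (a
    ``("beta", a, b)`` tuple; Beta(0.2, 0.2) puts substantial mass on rare
    variants, MAF <= 0.001 included).  Each breed with divergence ``c`` then
    redraws frequency p_b ~ Beta(p(1-c)/c, (1-p)(1-c)/c), so E[p_b] = p and
    the breeds separate like distinct clusters; c = 0 copies the base.

    Draw order (relied on by reproducibility tests): base first, then each
    breed in ``plan.breeds`` order, all from one ``default_rng(seed)``.
    """
    if n_snps < 1:
        raise ParameterError("n_snps must be >= 1")
    kind, *params = base_maf_distribution
    if kind != "beta":
        raise ParameterError(f"unknown base MAF distribution {kind!r}")
    a, b = params
    rng = np.random.default_rng(seed)
    eps = 5e-5  # keep Balding-Nichols beta parameters finite and SNPs polymorphic
    base = np.clip(rng.beta(a, b, size=n_snps), eps, 1.0 - eps)
    table = {"base": base}
    for breed in plan.breeds:
        c = float(plan.divergence.get(breed, 0.0))
        if c == 0.0:
            table[breed] = base.copy()
        else:
            table[breed] = rng.beta(base * (1.0 - c) / c, (1.0 - base) * (1.0 - c) / c)
    return pd.DataFrame(table)


def simulate_pedigree(plan: BreedPlan, seed: int = 0, base_year: int = 2000) -> Pedigree:
    """Founders plus ``plan.generations`` generations of rule-driven matings.

    Birth year = base_year + generation index, so "oldest animals" selection
    used by scenario construction is well defined.  Offspring breed
    composition is the parental mean.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"A{counter:06d}"

    nb = len(plan.breeds)
    for bi, breed in enumerate(plan.breeds):
        n = plan.founders.get(breed, 0)
        comp = np.zeros(nb)
        comp[bi] = 1.0
        for j in range(n):
            sex = "M" if j % 2 == 0 else "F"
            rows.append([new_id(), None, None, base_year, sex, *comp])

    cols = ["animal", "sire", "dam", "year", "sex", *plan.breeds]
    for g, rules in enumerate(plan.crosses, start=1):
        year = base_year + g
        born = pd.DataFrame(rows, columns=cols)
        frac = born[list(plan.breeds)].to_numpy(dtype=float)
        dominant = np.array(plan.breeds, dtype=object)[frac.argmax(axis=1)]
        for rule in rules:
            dams = born[(born["sex"] == "F") & (dominant == rule.dam_breed)]
            sires = born[(born["sex"] == "M") & (dominant == rule.sire_breed)]
            if dams.empty or sires.empty:
                raise DataError(
                    f"no eligible {'dams' if dams.empty else 'sires'} for rule "
                    f"{rule.dam_breed} x {rule.sire_breed} in generation {g}"
                )
            n_sires = rule.n_sires or max(1, math.ceil(rule.n_offspring / 10))
            n_sires = min(n_sires, len(sires))
            sire_pool = sires.iloc[rng.choice(len(sires), size=n_sires, replace=False)]
            dam_idx = rng.integers(len(dams), size=rule.n_offspring)
            sire_idx = rng.integers(len(sire_pool), size=rule.n_offspring)
            sexes = rng.integers(2, size=rule.n_offspring)
            for k in range(rule.n_offspring):
                dam = dams.iloc[dam_idx[k]]
                sire = sire_pool.iloc[sire_idx[k]]
                comp = (dam[list(plan.breeds)].to_numpy(dtype=float)
                        + sire[list(plan.breeds)].to_numpy(dtype=float)) / 2.0
                rows.append([new_id(), sire["animal"], dam["animal"], year,
                             "M" if sexes[k] else "F", *comp])

    return Pedigree(pd.DataFrame(rows, columns=cols), tuple(plan.breeds))


@dataclass(frozen=True)
class LDModel:
    """Ancestral-haplotype mosaic giving founders block-wise LD.

    Each breed owns ``n_ancestral`` haplotypes drawn from its allele
    frequencies; every founder haplotype is a mosaic of those ancestors
    with Poisson(``switch_per_morgan`` x length) segment switches placed
    uniformly on the genetic map.  SNPs whose within-breed MAF is below
    ``rare_maf`` bypass the pool and are drawn independently per founder
    haplotype, mimicking recent mutations that ride on family haplotypes
    only.  This is deliberately not coalescent-accurate LD; it supplies the
    limited haplotype diversity that makes population imputation work.
    """

    n_ancestral: int = 20
    switch_per_morgan: float = 5.0
    rare_maf: float = 0.01


def founder_haplotypes(
    freqs: pd.DataFrame,
    pedigree: Pedigree,
    gmap: GeneticMap,
    seed: int = 0,
    ld: LDModel | None = LDModel(),
) -> HaplotypeSet:
    """Draw founder haplotypes from the breed of origin.

    With ``ld=None`` every allele is an independent Bernoulli(p_breed)
    draw (Hardy–Weinberg, no LD).  With an :class:`LDModel` (the default)
    common SNPs come from a breed-specific ancestral-haplotype mosaic and
    rare SNPs remain independent draws.
    """
    snps = gmap.marker_map().snp_ids
    founders = pedigree.founders()
    dom = pedigree.dominant_breed()
    rng = np.random.default_rng(seed)
    haps = np.zeros((len(founders), 2, len(snps)), dtype=np.uint8)
    if ld is None:
        for i, animal in enumerate(founders):
            p = freqs[dom[animal]].to_numpy()
            haps[i] = rng.random((2, len(snps))) < p
        return HaplotypeSet(founders, snps, haps)

    breeds = sorted({dom[a] for a in founders}, key=str)
    pools: dict = {}
    common_mask: dict = {}
    for b in breeds:  # ancestral pools first, in sorted breed order (seed-stable)
        p = freqs[b].to_numpy()
        common_mask[b] = np.minimum(p, 1.0 - p) >= ld.rare_maf
        pools[b] = (rng.random((ld.n_ancestral, len(snps))) < p).astype(np.uint8)
    for i, animal in enumerate(founders):
        b = dom[animal]
        p = freqs[b].to_numpy()
        common = common_mask[b]
        for h in (0, 1):
            idx = np.empty(len(snps), dtype=np.int32)
            offset = 0
            for c in gmap.chromosomes:
                gpos = gmap.genetic_positions(c)
                m = len(gpos)
                length = gmap.lengths[c]
                n_switch = rng.poisson(ld.switch_per_morgan * length)
                cuts = np.sort(rng.uniform(0.0, length, size=n_switch)) if n_switch else np.empty(0)
                seg_anc = rng.integers(ld.n_ancestral, size=n_switch + 1)
                idx[offset:offset + m] = seg_anc[np.searchsorted(cuts, gpos, side="left")]
                offset += m
            hap = np.where(common, pools[b][idx, np.arange(len(snps))], 0).astype(np.uint8)
            rare = ~common
            hap[rare] = rng.random(int(rare.sum())) < p[rare]
            haps[i, h] = hap
    return HaplotypeSet(founders, snps, haps)


def draw_crossovers(rng: np.random.Generator, morgans: float) -> np.ndarray:
    """Haldane model: Poisson(L) crossovers placed uniformly on (0, L)."""
    k = rng.poisson(morgans)
    return np.sort(rng.uniform(0.0, morgans, size=k)) if k else np.empty(0)


def _gamete(haps: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Recombinant mosaic of a parent's two haplotypes, one chromosome at a time."""
    out = np.empty(haps.shape[1], dtype=np.uint8)
    offset = 0
    for c in gmap.chromosomes:
        gpos = gmap.genetic_positions(c)
        m = len(gpos)
        xo = draw_crossovers(rng, gmap.lengths[c])
        start = rng.integers(2)
        phase = (start + np.searchsorted(xo, gpos, side="left")) % 2
        out[offset:offset + m] = haps[phase, np.arange(offset, offset + m)]
        offset += m
    return out


def gene_drop(
    pedigree: Pedigree, founders: HaplotypeSet, gmap: GeneticMap, seed: int = 0
) -> HaplotypeSet:
    """Drop founder haplotypes down the pedigree with Haldane recombination.

    Output genotypes are Mendelian-consistent: an error-free parent and
    offspring can never be opposing homozygotes.
    """
    snps = founders.snps
    animals = pedigree.animals
    founder_pos = {a: i for i, a in enumerate(founders.animals)}
    rng = np.random.default_rng(seed)
    haps = np.zeros((len(animals), 2, len(snps)), dtype=np.uint8)
    index = {a: i for i, a in enumerate(animals)}
    order = pedigree.table.sort_values("year", kind="stable")
    for _, row in order.iterrows():
        i = index[row["animal"]]
        if row["sire"] is None and row["dam"] is None:
            if row["animal"] not in founder_pos:
                raise DataError(f"founder {row['animal']!r} has no haplotypes")
            haps[i] = founders.haplotypes[founder_pos[row["animal"]]]
        else:
            dam_h = haps[index[row["dam"]]]
            sire_h = haps[index[row["sire"]]]
            haps[i, 0] = _gamete(dam_h, gmap, rng)
            haps[i, 1] = _gamete(sire_h, gmap, rng)
    return HaplotypeSet(animals, snps, haps)


def add_noise(
    genotypes: GenotypeMatrix,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Perturb called dosages and knock entries out to missing.

    Each called entry is replaced, with probability ``error_rate``, by one of
    the two other genotype states (uniformly); independently, each entry is
    set missing with probability ``missing_rate``.  The input is unmodified.
    """
    for name, r in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not (0.0 <= r <= 1.0):
            raise ParameterError(f"{name} must be in [0, 1]: {r}")
    rng = np.random.default_rng(seed)
    out = genotypes.copy()
    data = out.data
    called = data != MISSING
    if error_rate > 0:
        flip = called & (rng.random(data.shape) < error_rate)
        shift = rng.integers(1, 3, size=data.shape).astype(np.int8)  # +1 or +2 mod 3
        data[flip] = (data[flip] + shift[flip]) % 3
    if missing_rate > 0:
        drop = rng.random(data.shape) < missing_rate
        data[drop] = MISSING
    return out


@dataclass
class SimulatedPopulation:
    """Bundle returned by :func:`simulate_population`."""

    pedigree: Pedigree
    haplotypes: HaplotypeSet
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    frequencies: pd.DataFrame
    genetic_map: GeneticMap


def simulate_population(
    plan: BreedPlan,
    gmap: GeneticMap,
    seed: int = 0,
    base_maf_distribution: tuple = ("beta", 0.2, 0.2),
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    ld: LDModel | None = LDModel(),
) -> SimulatedPopulation:
    """Full generator: frequencies -> pedigree -> gene drop -> noisy genotypes.

    Sub-seeds are derived deterministically from ``seed`` so the whole bundle
    is bit-identical across runs for a fixed seed.
    """
    s = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    freqs = simulate_founder_frequencies(gmap.n_snps, plan, base_maf_distribution, int(s[0]))
    pedigree = simulate_pedigree(plan, int(s[1]))
    fh = founder_haplotypes(freqs, pedigree, gmap, int(s[2]), ld=ld)
    haps = gene_drop(pedigree, fh, gmap, int(s[3]))
    geno = haps.to_genotypes()
    if error_rate > 0 or missing_rate > 0:
        geno = add_noise(geno, error_rate, missing_rate, int(s[3]) ^ 0x5A5A)
    return SimulatedPopulation(pedigree, haps, geno, gmap.marker_map(), freqs, gmap)
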