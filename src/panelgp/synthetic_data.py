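"""Simulated genotype maps, LD-structured genotypes and EBV-like phenotypes.

The generator emulates the structural features a marker-density study needs:
multi-chromosome maps with uniform or clustered (heavy-tailed) spacing,
pairwise LD that decays exponentially with physical distance, and polygenic
traits with one of three architectures — a few major genes plus a polygenic
background (fat-percentage-like), moderate plus small effects (milk-yield-
like), or purely small effects (somatic-cell-score-like).

LD model: haplotypes follow a first-order Markov chain along each chromosome.
The allele at marker j is a copy of the allele at marker j-1 with a copy
probability chosen so that the correlation between adjacent haplotype alleles
equals ``exp(-gap_bp / ld_decay_lambda_bp)``; the chain restarts at every
chromosome boundary.  A genotype dosage is the sum of two independent
haplotypes, which gives adjacent-dosage r² that falls off with physical
distance — the property the pruning strategies differentiate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, MarkerMap, PhenotypeTable


@dataclass(frozen=True)
class SimulationConfig:
    """Genotype-simulation settings.

    Parameters
    ----------
    n_individuals, n_markers
        Dataset dimensions; markers are allocated to chromosomes
        proportionally to length.
    chromosome_lengths_bp
        Physical length of each chromosome.
    spacing_model
        ``"uniform"`` for equal gaps, ``"clustered"`` for log-normal gaps
        (heavy-tailed, producing the gap-variance contrasts dense real chips
        show).
    spacing_sigma
        Log-scale SD of the clustered gap distribution.
    ld_decay_lambda_bp
        Distance at which adjacent-haplotype allele correlation drops to 1/e.
    maf_low, maf_high
        Bounds of the uniform allele-frequency spectrum (counted allele).
    n_families
        0 simulates unrelated individuals (two fresh haplotypes each).
        n > 0 simulates a paternal half-sib design, the family structure of
        progeny-tested dairy bulls: each individual receives one recombined
        gamete from one of ``n_families`` sires (crossover probability
        ``recombination_rate_per_bp`` x gap per marker interval) and one
        fresh population haplotype.
    """

    n_individuals: int = 500
    n_markers: int = 5000
    chromosome_lengths_bp: tuple[int, ...] = (50_000_000,) * 5
    spacing_model: str = "clustered"
    spacing_sigma: float = 0.8
    ld_decay_lambda_bp: float = 500_000.0
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_families: int = 0
    recombination_rate_per_bp: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise ValueError("n_markers must be >= 2")
        if self.ld_decay_lambda_bp <= 0:
            raise ValueError("ld_decay_lambda_bp must be > 0")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if self.spacing_model not in ("uniform", "clustered"):
            raise ValueError(f"unknown spacing model {self.spacing_model!r}")


@dataclass(frozen=True)
class TraitArchitecture:
    """QTL-effect tiers and heritability for one simulated trait.

    Effect sizes within a tier are N(0, sd²).  ``heritability`` is the target
    ratio Var(genetic) / Var(phenotype); the residual SD is calibrated against
    the realized genetic variance of each simulated cohort.
    """

    name: str
    n_major_qtl: int = 0
    major_sd: float = 0.0
    n_moderate_qtl: int = 0
    moderate_sd: float = 0.0
    n_small_qtl: int = 0
    small_sd: float = 1.0
    heritability: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must be in (0, 1]")
        if self.n_qtl_total == 0:
            raise ValueError("architecture has no QTL")

    @property
    def n_qtl_total(self) -> int:
        return self.n_major_qtl + self.n_moderate_qtl + self.n_small_qtl


def fp_like(heritability: float = 0.5, n_small_qtl: int = 300) -> TraitArchitecture:
    """One or few major genes plus many loci of small effect."""
    return TraitArchitecture("FP_like", n_major_qtl=2, major_sd=10.0,
                             n_small_qtl=n_small_qtl, small_sd=1.0,
                             heritability=heritability)


def my_like(heritability: float = 0.5, n_small_qtl: int = 300) -> TraitArchitecture:
    """Some loci of moderate effect plus many loci of small effect."""
    return TraitArchitecture("MY_like", n_moderate_qtl=20, moderate_sd=3.0,
                             n_small_qtl=n_small_qtl, small_sd=1.0,
                             heritability=heritability)


def scs_like(heritability: float = 0.5, n_small_qtl: int = 300) -> TraitArchitecture:
    """Many loci of small effect only."""
    return TraitArchitecture("SCS_like", n_small_qtl=n_small_qtl, small_sd=1.0,
                             heritability=heritability)


ARCHITECTURES = {"FP_like": fp_like, "MY_like": my_like, "SCS_like": scs_like}


def simulate_marker_map(config: SimulationConfig) -> MarkerMap:
    """Draw a multi-chromosome marker map under the configured spacing model."""
    rng = np.random.default_rng(config.seed)
    lengths = np.asarray(config.chromosome_lengths_bp, dtype=np.int64)
    # proportional allocation, remainders to the longest chromosomes
    frac = lengths / lengths.sum()
    counts = np.floor(frac * config.n_markers).astype(int)
    for i in np.argsort(-lengths)[: config.n_markers - counts.sum()]:
        counts[i] += 1

    rows = []
    for chrom_idx, (length, m) in enumerate(zip(lengths, counts), start=1):
        if m == 0:
            continue
        if length < m:
            raise ValueError(
                f"chromosome {chrom_idx} ({length} bp) too short for {m} markers"
            )
        if config.spacing_model == "uniform":
            gap = length // m
            pos = gap * np.arange(1, m + 1, dtype=np.int64)
        else:
            gaps = rng.lognormal(mean=0.0, sigma=config.spacing_sigma, size=m)
            pos = np.cumsum(gaps)
            pos = np.round(pos / pos[-1] * length).astype(np.int64)
            # enforce strictly increasing integer positions
            pos = np.maximum.accumulate(np.maximum(pos, 1))
            ties = np.flatnonzero(np.diff(pos) == 0)
            while ties.size:
                pos[ties + 1] += 1
                pos = np.maximum.accumulate(pos)
                ties = np.flatnonzero(np.diff(pos) == 0)
            if pos[-1] > length:
                raise ValueError(
                    f"chromosome {chrom_idx} ({length} bp) too short for {m} markers"
                )
        rows.append(pd.DataFrame({
            "marker_id": [f"snp_{chrom_idx}_{p}" for p in pos],
            "chromosome": chrom_idx,
            "position_bp": pos,
            "allele_a": "A",
            "allele_b": "B",
        }))
    table = pd.concat(rows, ignore_index=True)
    return MarkerMap(table)


def _haplotype_chain(
    rng: np.random.Generator,
    n_haplotypes: int,
    freqs: np.ndarray,
    copy_prob: np.ndarray,
) -> np.ndarray:
    """Markov-chain haplotypes: copy previous allele w.p. copy_prob, else fresh."""
    m = freqs.size
    haps = np.empty((n_haplotypes, m), dtype=np.int8)
    haps[:, 0] = rng.random(n_haplotypes) < freqs[0]
    for j in range(1, m):
        fresh = (rng.random(n_haplotypes) < freqs[j]).astype(np.int8)
        copy = rng.random(n_haplotypes) < copy_prob[j]
        haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    return haps


def simulate_genotypes(marker_map: MarkerMap, config: SimulationConfig) -> GenotypeDataset:
    """Simulate dosages whose adjacent-pair r² decays with physical distance.

    The target adjacent-haplotype allele correlation is
    ``rho_j = exp(-gap_j / ld_decay_lambda_bp)``; the copy probability is
    scaled for unequal allele frequencies and clipped to [0, 1].  The chain
    restarts at chromosome boundaries.
    """
    rng = np.random.default_rng(config.seed + 1)
    m = len(marker_map)
    freqs = rng.uniform(config.maf_low, config.maf_high, size=m)

    chrom = marker_map.chromosomes
    pos = marker_map.positions.astype(float)
    gaps = np.empty(m)
    gaps[0] = np.inf
    gaps[1:] = np.diff(pos)
    gaps[np.r_[False, chrom[1:] != chrom[:-1]]] = np.inf  # chain restart

    rho = np.exp(-gaps / config.ld_decay_lambda_bp)
    var = freqs * (1.0 - freqs)
    copy_prob = np.zeros(m)
    copy_prob[1:] = np.clip(
        rho[1:] * np.sqrt(var[1:] / var[:-1]), 0.0, 1.0
    )

    n = config.n_individuals
    if config.n_families <= 0:
        haps = _haplotype_chain(rng, 2 * n, freqs, copy_prob)
        dosages = haps[0::2] + haps[1::2]
    else:
        sire_haps = _haplotype_chain(rng, 2 * config.n_families, freqs, copy_prob)
        maternal = _haplotype_chain(rng, n, freqs, copy_prob)
        sire_of = np.arange(n) % config.n_families
        # crossover parity per interval; restart with a random phase per chromosome
        switch_p = np.minimum(0.5, gaps * config.recombination_rate_per_bp)
        new_chrom = ~np.isfinite(gaps)
        switch_p[new_chrom] = 0.0
        switches = rng.random((n, m)) < switch_p
        switches[:, new_chrom] = False
        phase = np.zeros((n, m), dtype=np.int64)
        chrom_starts = np.flatnonzero(new_chrom)
        for s, e in zip(chrom_starts, np.append(chrom_starts[1:], m)):
            seg = np.cumsum(switches[:, s:e], axis=1)
            seg += rng.integers(0, 2, size=(n, 1))
            phase[:, s:e] = seg
        phase %= 2
        paternal = np.where(phase == 0,
                            sire_haps[2 * sire_of],
                            sire_haps[2 * sire_of + 1])
        dosages = paternal + maternal

    samples = [f"ind_{i:05d}" for i in range(n)]
    return GenotypeDataset(samples, marker_map, dosages.astype(np.int8))


def simulate_trait(
    dataset: GenotypeDataset,
    architecture: TraitArchitecture,
    seed: int,
    trait_name: str | None = None,
) -> tuple[PhenotypeTable, np.ndarray]:
    """Simulate an EBV-like phenotype y = mu + sum_k w_k a_k + e.

    QTL are sampled without replacement from the dataset's markers; effects
    are drawn per tier; the residual variance is set from the realized genetic
    variance so that Var(genetic)/Var(y) matches the target heritability.
    Returns the phenotype table and the true breeding values (genetic values).
    """
    if architecture.n_qtl_total > dataset.n_markers:
        raise ValueError("more QTL requested than markers available")
    rng = np.random.default_rng(seed)
    p = dataset.allele_frequencies()

    g = None
    for _ in range(10):
        qtl = rng.choice(dataset.n_markers, size=architecture.n_qtl_total,
                         replace=False)
        effects = np.concatenate([
            rng.normal(0.0, architecture.major_sd, architecture.n_major_qtl),
            rng.normal(0.0, architecture.moderate_sd, architecture.n_moderate_qtl),
            rng.normal(0.0, architecture.small_sd, architecture.n_small_qtl),
        ])
        w = dataset.dosages[:, qtl].astype(float)
        w = np.where(w == -1, 2.0 * p[qtl], w)  # mean-impute missing
        w -= 2.0 * p[qtl]
        g = w @ effects
        if np.var(g) > 0:
            break
    else:
        raise RuntimeError("all sampled QTL sets were monomorphic (10 attempts)")

    var_g = np.var(g, ddof=1)
    h2 = architecture.heritability
    var_e = var_g * (1.0 - h2) / h2
    e = rng.normal(0.0, np.sqrt(var_e), size=dataset.n_individuals) if var_e > 0 \
        else np.zeros(dataset.n_individuals)
    y = g - g.mean() + e

    name = trait_name or architecture.name
    pheno = PhenotypeTable(pd.DataFrame({"sample_id": dataset.samples, name: y}))
    return pheno, g
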