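"""Marker-density statistics: adjacent physical gaps and adjacent-pair r².

For a panel, four statistics summarize "marker density" beyond the bare SNP
count: the mean and variance of the physical distance between adjacent
markers (d̄, σd²) and the mean and variance of the dosage r² between adjacent
markers (r²̄, σr²²).  Gaps and pairs are formed only within chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeDataset, MarkerMap
from .marker_pruning import _pairwise_r2

#: Table-style scale for reporting gap variances (units of 1e10 bp²).
SIGMA_D2_SCALE = 1e10


@dataclass(frozen=True)
class DensityMeasures:
    """The four density statistics of one panel plus bookkeeping counts."""

    d_mean: float          # bp
    d_var: float           # bp², sample variance (n-1)
    r2_mean: float
    r2_var: float
    n_gaps: int
    n_r2_pairs: int
    n_monomorphic_skipped: int = 0

    @property
    def sigma_d2_1e10(self) -> float:
        """Gap variance in 1e10 bp² units (summary-table convention)."""
        return self.d_var / SIGMA_D2_SCALE


def adjacent_gaps(marker_map: MarkerMap) -> np.ndarray:
    """bp gaps between consecutive markers on the same chromosome."""
    chrom = marker_map.chromosomes
    pos = marker_map.positions
    if len(marker_map) < 2:
        warnings.warn("fewer than 2 markers: no adjacent gaps")
        return np.empty(0, dtype=np.int64)
    same = chrom[1:] == chrom[:-1]
    gaps = np.diff(pos)[same]
    if gaps.size == 0:
        warnings.warn("no chromosome holds 2 or more markers: no adjacent gaps")
    return gaps


def adjacent_r2(dataset: GenotypeDataset) -> tuple[np.ndarray, int]:
    """Dosage r² for each adjacent within-chromosome pair.

    Pairs where either column is monomorphic (undefined correlation) are
    skipped; the skipped count is returned alongside the values.
    """
    chrom = dataset.map.chromosomes
    same = np.flatnonzero(chrom[1:] == chrom[:-1])
    vals = []
    n_skipped = 0
    for i in same:
        r2 = _pairwise_r2(dataset.dosages[:, i], dataset.dosages[:, i + 1])
        if np.isnan(r2):
            n_skipped += 1
        else:
            vals.append(r2)
    return np.asarray(vals, dtype=float), n_skipped


def density_measures(dataset: GenotypeDataset) -> DensityMeasures:
    """Compute d̄, σd², r²̄ and σr²² for a panel (sample variances, n-1)."""
    gaps = adjacent_gaps(dataset.map)
    if gaps.size < 2:
        raise ValueError("need at least 2 adjacent gaps for a variance")
    r2, n_skipped = adjacent_r2(dataset)
    if r2.size < 2:
        raise ValueError("need at least 2 defined adjacent r2 values")
    return DensityMeasures(
        d_mean=float(gaps.mean()),
        d_var=float(gaps.var(ddof=1)),
        r2_mean=float(r2.mean()),
        r2_var=float(r2.var(ddof=1)),
        n_gaps=int(gaps.size),
        n_r2_pairs=int(r2.size),
        n_monomorphic_skipped=n_skipped,
    )
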