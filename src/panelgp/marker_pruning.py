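"""SNP-panel construction by physical distance, LD pruning or random sampling.

Three strategies build panels of markers ("chips") from a dense genotype set:

* PhyD — greedy thinning that enforces a minimum physical gap (bp) between
  adjacent kept markers,
* GenD — sliding-window LD pruning that removes one member of any pair whose
  dosage r² exceeds a threshold (window/step in kb, PLINK-style),
* RanD — uniform random sampling without replacement.

``prune_to_count`` searches the PhyD/GenD threshold so the panel hits an
exact target size, and ``scenario_gap_sample`` builds index-gap panels with a
controlled gap variance at fixed mean gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeDataset, MarkerMap


class TargetUnreachableError(ValueError):
    """Raised when no threshold can produce a panel of the requested size."""

    def __init__(self, message: str, achievable_max: int):
        super().__init__(message)
        self.achievable_max = achievable_max


@dataclass(frozen=True)
class PanelSelection:
    """An ordered marker subset produced by one pruning run.

    ``indices`` are 0-based positions into the genome-ordered marker list,
    sorted and unique.  ``threshold`` is the bp gap (PhyD), the r² ceiling
    (GenD) or None (RanD / scenario).
    """

    method: str
    indices: np.ndarray
    threshold: float | None = None
    target_count: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1 or idx.size == 0:
            raise ValueError("selection must contain at least one marker index")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("selection indices must be sorted and unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size

    def write_ids(self, marker_map: MarkerMap, path) -> None:
        """Write the selected marker ids, one per line (extract-list format)."""
        ids = marker_map.marker_ids[self.indices]
        with open(path, "w") as fh:
            fh.write("\n".join(ids) + "\n")


def prune_phyd(marker_map: MarkerMap, min_gap_bp: int) -> PanelSelection:
    """Greedy left-to-right thinning enforcing a minimum adjacent gap.

    Per chromosome the first marker is always kept; each subsequent marker is
    kept iff its distance from the last kept marker is >= ``min_gap_bp``.
    """
    if min_gap_bp < 0:
        raise ValueError("min_gap_bp must be >= 0")
    chrom = marker_map.chromosomes
    pos = marker_map.positions
    keep: list[int] = []
    last_chrom = None
    last_pos = 0
    for i in range(len(marker_map)):
        if chrom[i] != last_chrom or pos[i] - last_pos >= min_gap_bp:
            keep.append(i)
            last_chrom, last_pos = chrom[i], pos[i]
    return PanelSelection("PhyD", np.array(keep), threshold=float(min_gap_bp))


def _window_starts(pos: np.ndarray, window_bp: int, step_bp: int) -> list[tuple[int, int]]:
    """Half-open index ranges [i, j) of each window position over one chromosome."""
    out = []
    start = int(pos[0])
    end = int(pos[-1])
    while start <= end:
        i = int(np.searchsorted(pos, start, side="left"))
        j = int(np.searchsorted(pos, start + window_bp, side="right"))
        if j - i >= 2:
            out.append((i, j))
        start += step_bp
    return out


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over non-missing pairs."""
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def prune_gend(
    dataset: GenotypeDataset,
    r2_max: float,
    window_kb: float = 50.0,
    step_kb: float = 5.0,
) -> PanelSelection:
    """Sliding-window LD pruning of pairs with dosage r² above ``r2_max``.

    Windows are defined by physical span (kb) and never cross chromosome
    boundaries.  Within each window position, pairs of surviving markers with
    r² > ``r2_max`` lose one member — the one with the smaller minor-allele
    frequency (tie: the later marker).  A final verification pass re-scans all
    window positions; the output contains no violating pair.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must be in (0, 1]")
    if window_kb < step_kb:
        raise ValueError("window must be at least as large as the step")
    window_bp, step_bp = int(window_kb * 1000), int(step_kb * 1000)

    chrom = dataset.map.chromosomes
    pos = dataset.map.positions
    p = dataset.allele_frequencies()
    maf = np.fmin(p, 1.0 - p)
    alive = np.ones(dataset.n_markers, dtype=bool)

    def prune_window(lo: int, hi: int) -> None:
        idx = [k for k in range(lo, hi) if alive[k]]
        changed = True
        while changed:
            changed = False
            for a in range(len(idx)):
                i = idx[a]
                if not alive[i]:
                    continue
                for b in range(a + 1, len(idx)):
                    j = idx[b]
                    if not alive[j]:
                        continue
                    r2 = _pairwise_r2(dataset.dosages[:, i], dataset.dosages[:, j])
                    if np.isnan(r2) or r2 <= r2_max:
                        continue
                    if maf[i] < maf[j]:
                        alive[i] = False
                    else:  # equal MAF ties remove the later (higher-position) member
                        alive[j] = False
                    changed = True
                    if not alive[i]:
                        break

    for c in np.unique(chrom):
        span = np.flatnonzero(chrom == c)
        cpos = pos[span]
        for i, j in _window_starts(cpos, window_bp, step_bp):
            prune_window(span[0] + i, span[0] + j)

    # verification pass: no surviving pair within any window may exceed r2_max
    for c in np.unique(chrom):
        span = np.flatnonzero(chrom == c)
        cpos = pos[span]
        for i, j in _window_starts(cpos, window_bp, step_bp):
            live = [k for k in range(span[0] + i, span[0] + j) if alive[k]]
            for a in range(len(live)):
                for b in range(a + 1, len(live)):
                    r2 = _pairwise_r2(dataset.dosages[:, live[a]],
                                      dataset.dosages[:, live[b]])
                    if not np.isnan(r2) and r2 > r2_max:
                        raise AssertionError(
                            "LD pruning left a violating pair "
                            f"({live[a]}, {live[b]}): r2={r2:.4f}"
                        )

    return PanelSelection("GenD", np.flatnonzero(alive), threshold=float(r2_max))


def prune_rand(marker_map: MarkerMap, n_target: int, seed: int) -> PanelSelection:
    """Uniform sample of ``n_target`` markers without replacement."""
    m = len(marker_map)
    if not 1 <= n_target <= m:
        raise ValueError(f"n_target must be in [1, {m}], got {n_target}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m, size=n_target, replace=False))
    return PanelSelection("RanD", idx, target_count=n_target, seed=seed)


def _thin_to_count(sel: PanelSelection, n_target: int, seed: int,
                   method: str, threshold: float) -> PanelSelection:
    """Seeded uniform removal of surplus markers down to the exact target."""
    surplus = len(sel) - n_target
    if surplus == 0:
        return PanelSelection(method, sel.indices, threshold=threshold,
                              target_count=n_target, seed=seed)
    rng = np.random.default_rng(seed)
    drop = rng.choice(len(sel), size=surplus, replace=False)
    keep = np.delete(sel.indices, drop)
    return PanelSelection(method, keep, threshold=threshold,
                          target_count=n_target, seed=seed)


def prune_to_count(
    dataset: GenotypeDataset,
    method: str,
    n_target: int,
    seed: int = 0,
    window_kb: float = 50.0,
    step_kb: float = 5.0,
) -> PanelSelection:
    """Bisect the PhyD/GenD threshold until the panel hits ``n_target`` exactly.

    The threshold-count relation is monotone (PhyD: count non-increasing in
    the gap; GenD: count non-decreasing in the r² ceiling).  Bisection finds
    the tightest threshold whose panel is at least the target size; any
    surplus is then removed by seeded uniform thinning.  Raises
    :class:`TargetUnreachableError` when even the loosest threshold cannot
    reach the target (reporting the achievable maximum).
    """
    m = dataset.n_markers
    if not 1 <= n_target <= m:
        raise ValueError(f"n_target must be in [1, {m}], got {n_target}")

    if method == "PhyD":
        marker_map = dataset.map
        lo, hi = 0, int(marker_map.positions.max()) + 1
        # count(lo=0) = m >= target; find the largest gap with count >= target
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if len(prune_phyd(marker_map, mid)) >= n_target:
                lo = mid
            else:
                hi = mid
        sel = prune_phyd(marker_map, lo)
        return _thin_to_count(sel, n_target, seed, "PhyD", float(lo))

    if method == "GenD":
        # cap just below 1 so perfectly correlated duplicates always prune
        cap = 1.0 - 1e-6
        sel_cap = prune_gend(dataset, cap, window_kb, step_kb)
        if len(sel_cap) < n_target:
            raise TargetUnreachableError(
                f"GenD cannot reach {n_target} markers; achievable maximum "
                f"is {len(sel_cap)} (r2 ceiling {cap})",
                achievable_max=len(sel_cap),
            )
        lo, hi = 1e-6, cap  # count(hi) >= target; find smallest r2 with count >= target
        if len(prune_gend(dataset, lo, window_kb, step_kb)) >= n_target:
            hi = lo
        else:
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                if len(prune_gend(dataset, mid, window_kb, step_kb)) >= n_target:
                    hi = mid
                else:
                    lo = mid
        sel = prune_gend(dataset, hi, window_kb, step_kb)
        return _thin_to_count(sel, n_target, seed, "GenD", float(hi))

    raise ValueError(f"unknown method {method!r}; expected 'PhyD' or 'GenD'")


def scenario_gap_sample(
    n_markers_total: int,
    mean_gap: int = 67,
    gap_variance: float = 0.0,
    seed: int = 0,
) -> PanelSelection:
    """Walk the ranked marker list with controlled index-gap variance.

    Starting at the first marker, repeatedly step forward by ``mean_gap``
    (``gap_variance`` = 0) or by a normal draw with the given mean and
    variance, rounded to the nearest integer and truncated below at 1, until
    the walk leaves the marker list.  All panels built this way share the
    same mean gap but differ in gap variance.
    """
    if mean_gap < 1:
        raise ValueError("mean_gap must be >= 1")
    if gap_variance < 0:
        raise ValueError("gap_variance must be >= 0")
    if mean_gap >= n_markers_total:
        raise ValueError("mean_gap must be smaller than the marker count")

    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(gap_variance))
    idx = [0]
    while True:
        gap = mean_gap if sd == 0 else max(1, int(np.rint(rng.normal(mean_gap, sd))))
        nxt = idx[-1] + gap
        if nxt >= n_markers_total:
            break
        idx.append(nxt)
    return PanelSelection("scenario", np.array(idx), seed=seed)


def verify_phyd(selection: PanelSelection, marker_map: MarkerMap,
                min_gap_bp: int) -> bool:
    """Check that every adjacent kept within-chromosome gap is >= the threshold."""
    chrom = marker_map.chromosomes[selection.indices]
    pos = marker_map.positions[selection.indices]
    same = chrom[1:] == chrom[:-1]
    gaps = np.diff(pos)[same]
    return bool(gaps.size == 0 or gaps.min() >= min_gap_bp)
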