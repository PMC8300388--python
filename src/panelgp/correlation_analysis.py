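"""Within-level standardization and pooled density-accuracy correlation tests.

Panels at the same SNP-count level but built by different strategies differ
in their density measures and in GEBV accuracy.  To ask whether a density
measure relates to accuracy *at fixed SNP count*, each measure and each
trait's accuracies are standardized to mean 0 / sample SD 1 within every
SNP-count level (z = (x - mean(x)) / sd(x) over the level's three methods),
then all (measure, accuracy) pairs are pooled across levels and traits and
tested with a plain Pearson correlation; the t statistic with n-2 df gives
the two-sided p-value.

A reference panel summary table (11 SNP-count levels x 3 methods, with gap
variance in 1e10 bp² units, adjacent-r² mean/variance and per-trait
accuracies from a 10x10 CV on a dairy-cattle cohort) ships with the package
so the pooled tests can be reproduced without any external data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

MEASURES = ("sigma_d2_1e10", "r2_mean", "r2_var")
TRAITS = ("FP", "MY", "SCS")
METHODS = ("PhyD", "GenD", "RanD")

_FIXTURE_NAME = "panel_summary_table.csv"
_FIXTURE_SHA256 = "bacd50d90ea622e2d1125e1fd0e1fa93a4861d759e53d8e410316baa80643786"


class FixtureIntegrityError(RuntimeError):
    """Raised when the packaged summary table fails its checksum."""


@dataclass(frozen=True)
class CorrelationTestResult:
    """Pearson correlation with its t statistic and two-sided p-value."""

    r: float
    t_value: float
    p_value: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.r) or abs(self.r) > 1 + 1e-12:
            raise ValueError(f"invalid correlation {self.r}")


def validate_summary_table(table: pd.DataFrame) -> None:
    """Check the (level x method) structure of a panel summary table."""
    required = {"snp_level", "method", *MEASURES,
                *(f"acc_{t}" for t in TRAITS)}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    counts = table.groupby("snp_level")["method"].nunique()
    if (counts != len(METHODS)).any():
        bad = counts[counts != len(METHODS)].index.tolist()
        raise ValueError(f"levels without exactly {len(METHODS)} methods: {bad}")
    if table.duplicated(["snp_level", "method"]).any():
        raise ValueError("duplicated (snp_level, method) rows")


def standardize_within_level(
    values: np.ndarray, levels: np.ndarray
) -> np.ndarray:
    """z-score each value against the mean/sample SD of its level's values.

    Every level must contain at least two distinct values; a zero-SD level
    raises with the offending level named.
    """
    values = np.asarray(values, dtype=float)
    levels = np.asarray(levels)
    out = np.empty_like(values)
    for lev in np.unique(levels):
        m = levels == lev
        sd = values[m].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"zero standard deviation within level {lev}")
        out[m] = (values[m] - values[m].mean()) / sd
    return out


def pooled_correlation(
    table: pd.DataFrame,
    measure: str,
    traits: tuple[str, ...] = TRAITS,
    levels: tuple[int, ...] | None = None,
) -> CorrelationTestResult:
    """Pooled Pearson test between a standardized measure and accuracies.

    The measure column and each selected trait's accuracy column are
    standardized within every SNP-count level; each row then contributes one
    pair per selected trait.  Pairs are pooled and tested with
    t = r·sqrt((n-2)/(1-r²)), two-sided p from the t distribution.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    sub = table if levels is None else table[table["snp_level"].isin(levels)]
    if sub.empty:
        raise ValueError("no rows at the requested levels")
    lev = sub["snp_level"].to_numpy()

    z_measure = standardize_within_level(sub[measure].to_numpy(), lev)
    xs, ys = [], []
    for trait in traits:
        z_acc = standardize_within_level(sub[f"acc_{trait}"].to_numpy(), lev)
        xs.append(z_measure)
        ys.append(z_acc)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")

    r = float(np.corrcoef(x, y)[0, 1])
    t = r * np.sqrt((n - 2) / (1.0 - r * r)) if abs(r) < 1 else np.inf * np.sign(r)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationTestResult(r, float(t), p, n)


def load_reference_table() -> pd.DataFrame:
    """Load the packaged 33-row panel summary table (checksum-verified)."""
    ref = resources.files("panelgp") / "data" / _FIXTURE_NAME
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"summary-table fixture checksum mismatch: {digest}"
        )
    from io import BytesIO

    table = pd.read_csv(BytesIO(raw))
    validate_summary_table(table)
    return table


MODERATE_LEVELS = (15, 20, 30, 50)


def reference_correlations() -> dict[str, CorrelationTestResult]:
    """The pooled tests on the packaged table: all-level tests for the three
    measures against all traits, plus the moderate-density (15-50 k) tests
    against the polygenic trait (SCS) only."""
    table = load_reference_table()
    out: dict[str, CorrelationTestResult] = {}
    for measure in MEASURES:
        out[f"{measure}_all_levels"] = pooled_correlation(table, measure)
        out[f"{measure}_scs_15_50k"] = pooled_correlation(
            table, measure, traits=("SCS",), levels=MODERATE_LEVELS
        )
    return out
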