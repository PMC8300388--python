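"""PLINK v1 binary genotype I/O, phenotype tables and marker quality control.

Dosages count copies of ``allele_b`` (the second .bim allele), so the PLINK
2-bit codes map to 0 (hom ``allele_a``), 1 (het), 2 (hom ``allele_b``) and
:data:`MISSING` (-1).  Positions are 1-based base pairs, as stored in .bim.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = bytes([0x01])

# PLINK v1 2-bit genotype codes (SNP-major), little-endian within a byte:
# 00 -> hom allele_a (dosage 0), 01 -> missing, 10 -> het, 11 -> hom allele_b.
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam trio is malformed or inconsistent."""


class EmptyPanelError(ValueError):
    """Raised when a filter or selection leaves no markers."""


@dataclass(frozen=True)
class MarkerMap:
    """Marker metadata: id, chromosome, 1-based bp position and alleles.

    ``table`` has columns ``marker_id, chromosome, position_bp, allele_a,
    allele_b`` sorted by (chromosome, position); positions are strictly
    increasing within each chromosome and marker ids are unique.
    """

    table: pd.DataFrame

    REQUIRED_COLUMNS = ("marker_id", "chromosome", "position_bp", "allele_a", "allele_b")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        t = self.table
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicated marker id: {dup!r}")
        for _, grp in t.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within a chromosome")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[indices].reset_index(drop=True))


@dataclass
class GenotypeDataset:
    """An individuals x markers dosage matrix with its marker map.

    ``dosages`` is int8 with entries in {0, 1, 2, MISSING}; column k holds the
    count of ``allele_b`` at marker k.
    """

    samples: list[str]
    map: MarkerMap
    dosages: np.ndarray
    qc_report: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        if self.dosages.shape != (len(self.samples), len(self.map)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.map)} markers"
            )
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.dosages[~valid].flat[0]
            raise ValueError(f"invalid dosage value {bad}; expected 0/1/2/{MISSING}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of allele_b per marker, over non-missing calls (NaN if none)."""
        d = self.dosages
        obs = d != MISSING
        n_called = obs.sum(axis=0)
        totals = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, totals / (2.0 * n_called), np.nan)

    def call_rates(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=0)


@dataclass
class PhenotypeTable:
    """Sample ids with one numeric column per trait (EBVs used as phenotypes)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns:
            raise ValueError("phenotype table requires a 'sample_id' column")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicated sample ids in phenotype table")
        if len(self.traits) == 0:
            raise ValueError("phenotype table has no trait columns")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.table.columns if c != "sample_id"]

    def values_for(self, trait: str, samples: list[str]) -> np.ndarray:
        """Phenotype vector for ``trait`` aligned to ``samples`` order."""
        sub = self.table.set_index("sample_id")
        missing = [s for s in samples if s not in sub.index]
        if missing:
            raise KeyError(f"samples without phenotype: {missing[:5]}")
        return sub.loc[samples, trait].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# PLINK v1 binary trio


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK v1 SNP-major .bed/.bim/.fam trio into a dataset.

    The returned map is sorted by (chromosome, position); dosage columns are
    reordered to match.
    """
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)

    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chromosome", "marker_id", "cm", "position_bp", "allele_a", "allele_b"],
        dtype={"chromosome": int, "marker_id": str, "position_bp": int,
               "allele_a": str, "allele_b": str},
    )
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"iid": str},
    )
    n_markers, n_samples = len(bim_df), len(fam_df)

    raw = bed.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise PlinkFormatError(f"{bed}: not SNP-major (mode byte {raw[2]:#x})")
    bytes_per_marker = (n_samples + 3) // 4
    expected = 3 + bytes_per_marker * n_markers
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed}: payload {len(raw) - 3} bytes, expected {expected - 3} "
            f"for {n_samples} samples x {n_markers} markers"
        )

    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    payload = payload.reshape(n_markers, bytes_per_marker)
    # unpack 2-bit codes, low bits first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (payload[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_markers, -1)[:, :n_samples]
    dosages = _CODE_TO_DOSAGE[codes].T  # samples x markers

    order = np.lexsort((bim_df["position_bp"].to_numpy(), bim_df["chromosome"].to_numpy()))
    bim_df = bim_df.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order]

    marker_map = MarkerMap(bim_df[list(MarkerMap.REQUIRED_COLUMNS)])
    return GenotypeDataset(list(fam_df["iid"]), marker_map, dosages)


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write a dataset as a PLINK v1 SNP-major .bed with matching .bim/.fam."""
    if dataset.n_markers == 0:
        raise EmptyPanelError("refusing to write a zero-marker PLINK file set")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    n = dataset.n_individuals
    buf = io.BytesIO()
    buf.write(_BED_MAGIC)
    buf.write(_BED_SNP_MAJOR)
    code_lut = np.zeros(4, dtype=np.uint8)
    for dose, code in _DOSAGE_TO_CODE.items():
        code_lut[dose % 4] = code  # MISSING=-1 maps to index 3
    pad = (-n) % 4
    for k in range(dataset.n_markers):
        codes = code_lut[dataset.dosages[:, k] % 4]
        if pad:
            codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
        codes = codes.reshape(-1, 4)
        packed = (codes[:, 0] | (codes[:, 1] << 2) | (codes[:, 2] << 4)
                  | (codes[:, 3] << 6)).astype(np.uint8)
        buf.write(packed.tobytes())
    prefix.with_suffix(".bed").write_bytes(buf.getvalue())

    bim = dataset.map.table
    pd.DataFrame({
        "chromosome": bim["chromosome"],
        "marker_id": bim["marker_id"],
        "cm": 0,
        "position_bp": bim["position_bp"],
        "allele_a": bim["allele_a"],
        "allele_b": bim["allele_b"],
    }).to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    pd.DataFrame({
        "fid": dataset.samples,
        "iid": dataset.samples,
        "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
    }).to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a delimited phenotype table (header: sample_id, trait columns)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df["sample_id"] = df["sample_id"].astype(str)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quality control


def hwe_chisq_pvalues(dataset: GenotypeDataset) -> np.ndarray:
    """Hardy-Weinberg chi-square (1 df) p-value per marker.

    Observed genotype counts are tested against n*(q^2, 2pq, p^2) expected
    under equilibrium, over non-missing calls.  Monomorphic markers get p=1.
    """
    d = dataset.dosages
    obs = d != MISSING
    n = obs.sum(axis=0).astype(float)
    n_het = ((d == 1) & obs).sum(axis=0)
    n_hom_b = ((d == 2) & obs).sum(axis=0)
    n_hom_a = ((d == 0) & obs).sum(axis=0)
    p = dataset.allele_frequencies()
    q = 1.0 - p
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_aa, exp_ab, exp_bb = n * q * q, 2 * n * p * q, n * p * p
        chi2 = np.zeros(dataset.n_markers)
        for o, e in ((n_hom_a, exp_aa), (n_het, exp_ab), (n_hom_b, exp_bb)):
            term = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
            chi2 += term
    pvals = stats.chi2.sf(chi2, df=1)
    mono = np.isnan(p) | (p <= 0) | (p >= 1)
    pvals[mono] = 1.0
    return pvals


def qc_filter(
    dataset: GenotypeDataset,
    maf_min: float = 0.005,
    call_rate_min: float = 0.9,
    hwe_p_min: float = 0.01,
) -> GenotypeDataset:
    """Drop markers failing MAF, call-rate or Hardy-Weinberg thresholds.

    A marker is removed when MAF < ``maf_min``, call rate < ``call_rate_min``
    or its HWE chi-square p-value < ``hwe_p_min``.  The removal counts per
    criterion are attached as ``qc_report`` on the returned dataset.
    """
    for name, v in (("maf_min", maf_min), ("call_rate_min", call_rate_min),
                    ("hwe_p_min", hwe_p_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")

    p = dataset.allele_frequencies()
    maf = np.fmin(p, 1.0 - p)
    fail_maf = np.isnan(maf) | (maf < maf_min)
    fail_call = dataset.call_rates() < call_rate_min
    fail_hwe = hwe_chisq_pvalues(dataset) < hwe_p_min

    keep = ~(fail_maf | fail_call | fail_hwe)
    if not keep.any():
        raise EmptyPanelError("all markers removed by QC filters")
    idx = np.flatnonzero(keep)
    out = GenotypeDataset(list(dataset.samples), dataset.map.subset(idx),
                          dataset.dosages[:, idx])
    out.qc_report = {
        "n_input": dataset.n_markers,
        "n_retained": int(keep.sum()),
        "removed_maf": int(fail_maf.sum()),
        "removed_call_rate": int(fail_call.sum()),
        "removed_hwe": int(fail_hwe.sum()),
    }
    return out


def subset_markers(dataset: GenotypeDataset, indices: np.ndarray) -> GenotypeDataset:
    """Restrict the dataset to the given sorted marker column indices."""
    indices = np.asarray(indices, dtype=np.intp)
    if indices.size == 0:
        raise EmptyPanelError("empty marker selection")
    if indices.min() < 0 or indices.max() >= dataset.n_markers:
        raise IndexError(
            f"marker index out of range [0, {dataset.n_markers}): "
            f"{indices.min()}..{indices.max()}"
        )
    if np.any(np.diff(indices) <= 0):
        raise ValueError("marker indices must be sorted and unique")
    return GenotypeDataset(list(dataset.samples), dataset.map.subset(indices),
                           dataset.dosages[:, indices])
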