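"""Shared data model for spike-in amplicon analysis.

The central container is :class:`CountTable`, a samples × sequence-variants
(SV) matrix of non-negative integer read counts. Samples are rows throughout
the package; helper types carry per-sample metadata, SV sequences, mock
community (MC) references and downstream results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SVSequenceSet",
    "MCReference",
    "MCAssignment",
    "MCQCMetrics",
    "GCNEstimate",
    "DoseRecommendation",
    "OutlierFlag",
    "DistanceMatrix",
    "PermanovaResult",
    "validate_metadata",
    "REQUIRED_METADATA_COLUMNS",
    "OPTIONAL_METADATA_COLUMNS",
]


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


REQUIRED_METADATA_COLUMNS = ("sample_id", "biomass_mass", "mc_dose_fraction")
OPTIONAL_METADATA_COLUMNS = ("pool_id", "replicate_label", "condition")


@dataclass
class CountTable:
    """Samples × SVs matrix of non-negative integer read counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns SVs, values non-negative integers.

    Invariants: unique sample and SV identifiers; integral counts >= 0.
    ``totals`` is always the exact row sum (the per-library quality-filtered
    read count when the table still contains MC reads).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("count table must have at least one sample and one SV")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample identifiers")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate SV identifiers")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0):
            raise ValidationError("negative counts")
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError("fractional counts")
        self.data = df.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def totals(self) -> pd.Series:
        """Per-sample read sum (N_total_reads_j)."""
        return self.data.sum(axis=1)

    def drop_svs(self, sv_ids: Iterable[str]) -> "CountTable":
        keep = [c for c in self.data.columns if c not in set(sv_ids)]
        if not keep:
            raise ValidationError("dropping all SVs would leave an empty table")
        return CountTable(self.data[keep].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class SVSequenceSet:
    """Mapping of SV identifier to an uppercase IUPAC nucleotide sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for sv_id, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"empty sequence for {sv_id}")
            clean[str(sv_id)] = seq.upper()
        self.sequences = clean

    def __getitem__(self, sv_id: str) -> str:
        return self.sequences[sv_id]

    def __contains__(self, sv_id: str) -> bool:
        return sv_id in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()


@dataclass(frozen=True)
class MCReference:
    """A mock-community reference taxon.

    ``copies_per_dose`` is the number of 16S rRNA gene copies contributed by
    one manufacturer dose, ``cells_per_dose`` the corresponding cell count;
    their ratio is the (integral) per-cell 16S copy number.
    """

    name: str
    gram: str  # "positive" | "negative"
    sequence: str
    copies_per_dose: float
    cells_per_dose: float

    def __post_init__(self) -> None:
        if self.gram not in ("positive", "negative"):
            raise ValidationError("gram status must be 'positive' or 'negative'")
        if self.copies_per_dose <= 0 or self.cells_per_dose <= 0:
            raise ValidationError("dose copy/cell numbers must be positive")
        per_cell = self.copies_per_dose / self.cells_per_dose
        if abs(per_cell - round(per_cell)) > 1e-9:
            raise ValidationError("copies_per_dose / cells_per_dose must be integral")

    @property
    def copies_per_cell(self) -> int:
        return int(round(self.copies_per_dose / self.cells_per_dose))


@dataclass
class MCAssignment:
    """SV → MC taxon assignment with identity and primary/secondary status.

    ``table`` has one row per assigned SV with columns
    ``sv_id, taxon, identity, status, reads`` (reads summed over samples).
    ``per_sample_taxon_reads`` is a samples × taxa DataFrame of MC read
    totals (primary + secondary SVs of each taxon).
    """

    table: pd.DataFrame
    per_sample_taxon_reads: pd.DataFrame

    def __post_init__(self) -> None:
        for taxon, sub in self.table.groupby("taxon"):
            n_primary = int((sub["status"] == "primary").sum())
            if n_primary > 1:
                raise ValidationError(f"multiple primary SVs for {taxon}")

    @property
    def mc_sv_ids(self) -> list[str]:
        return list(self.table["sv_id"])

    def svs_for(self, taxon: str) -> list[str]:
        return list(self.table.loc[self.table["taxon"] == taxon, "sv_id"])

    def taxon_reads(self, taxon: str) -> pd.Series:
        """Per-sample read total for one MC taxon (0 if taxon absent)."""
        if taxon in self.per_sample_taxon_reads.columns:
            return self.per_sample_taxon_reads[taxon]
        return pd.Series(0, index=self.per_sample_taxon_reads.index)


@dataclass
class MCQCMetrics:
    """Per-sample spike-in QC: MC read fraction, taxon-pair ratio, dose band.

    ``per_sample`` columns: ``mc_fraction`` in [0, 1] (NaN for zero-read
    samples), ``gram_ratio`` (NaN when the gram-positive taxon has no
    reads), ``band_verdict`` in {below, in-band, above}.
    """

    per_sample: pd.DataFrame
    ratio_mean: float
    ratio_sd: float
    expected_ratio: float
    band: tuple[float, float] = (0.01, 0.10)


@dataclass
class GCNEstimate:
    """Per-sample absolute 16S gene-copy-number estimates.

    ``table`` columns: ``sample_id, ih_reads, total_reads, dose_copies,
    gcn, log2_gcn, flag`` — ``gcn`` is NaN where not estimable (no MC dose)
    and ``flag`` records QC failures (spike dosed but not detected).
    """

    table: pd.DataFrame

    def gcn(self) -> pd.Series:
        return self.table.set_index("sample_id")["gcn"]

    def log2_gcn(self) -> pd.Series:
        return self.table.set_index("sample_id")["log2_gcn"]


@dataclass
class DoseRecommendation:
    """Dose-fraction bounds that keep the expected MC read share in-band."""

    sample_label: str
    sample_copies: float
    band: tuple[float, float]
    dose_low: float
    dose_high: float

    def __post_init__(self) -> None:
        if not (0 < self.band[0] < self.band[1] < 1):
            raise ValidationError("target band must satisfy 0 < low < high < 1")
        if not self.dose_low < self.dose_high:
            raise ValidationError("dose bounds must be ordered")


@dataclass
class OutlierFlag:
    sample_id: str
    group: str
    fold_deviation: float
    flagged: bool


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("distance matrix must be square")
        if d.shape[0] != len(self.sample_ids):
            raise ValidationError("sample ids do not match matrix size")
        if np.any(d < 0):
            raise ValidationError("negative distances")
        # enforce exact symmetry and zero diagonal
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        self.data = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PermanovaResult:
    """Sequential (Type-I) PERMANOVA table.

    ``table`` has one row per term plus a Residual row with columns
    ``df, sum_sq, F, R2, p``; term and residual R² partition 1.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        r2 = self.table["R2"].to_numpy(dtype=float)
        if not np.isclose(np.nansum(r2), 1.0, atol=1e-12):
            raise ValidationError("R² values must partition the total variance")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a per-sample metadata table.

    Requires ``sample_id``, ``biomass_mass`` (mg, >= 0) and
    ``mc_dose_fraction`` (fraction of one manufacturer dose, >= 0; 0 encodes
    "no MC added"). Missing optional columns are filled with null labels.
    """
    meta = meta.copy()
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValidationError(f"metadata missing required column '{col}'")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    meta["biomass_mass"] = meta["biomass_mass"].astype(float)
    meta["mc_dose_fraction"] = meta["mc_dose_fraction"].astype(float)
    if (meta["biomass_mass"] < 0).any():
        raise ValidationError("negative biomass_mass")
    if (meta["mc_dose_fraction"] < 0).any():
        raise ValidationError("negative mc_dose_fraction")
    for col in OPTIONAL_METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = None
    meta["no_mc"] = meta["mc_dose_fraction"] == 0
    return meta.set_index("sample_id", drop=False)
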