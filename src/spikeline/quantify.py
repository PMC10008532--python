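"""Absolute 16S copy-number estimation from the spike-in and downstream use.

The estimator scales the spiked gram-negative reference taxon's input
copies by the inverse of its read share:

    GCN_j = (N_total_reads_j / ih_reads_j) × dose_copies_j

where ``dose_copies_j = mc_dose_fraction_j × copies_per_dose`` of the
reference taxon (the units then cancel to total 16S gene copies in the
library) and ``ih_reads_j`` includes primary and secondary SVs of that
taxon. The count transformation rescales sample-SV counts to that absolute
scale while discounting the spike's own read share:

    norm_ij = (SV_ij / counts_j) × GCN_j × (1 − ih_reads_j / counts_j)

with ``counts_j`` the pre-stripping (quality-filtered) library total.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import (
    CountTable,
    DoseRecommendation,
    GCNEstimate,
    MCAssignment,
    MCReference,
    OutlierFlag,
    ValidationError,
)

__all__ = [
    "estimate_gcn",
    "transform_counts",
    "flag_outliers",
    "recommend_dose",
    "ddpcr_crossval",
]


def _reference_taxon(refs: Sequence[MCReference], name: str | None = None) -> MCReference:
    if name is not None:
        return next(r for r in refs if r.name == name)
    return next(r for r in refs if r.gram == "negative")


def estimate_gcn(
    table: CountTable,
    assignment: MCAssignment,
    metadata: pd.DataFrame,
    refs: Sequence[MCReference],
    reference_taxon: str | None = None,
) -> GCNEstimate:
    """Estimate total 16S gene copies per library from the spike read share.

    ``table`` must still contain the MC reads (totals are the quality-
    filtered read counts). The gram-negative taxon is the default
    reference; pass ``reference_taxon`` to use the other taxon instead.
    Samples with dose 0 get NaN (not estimable); samples with a positive
    dose but zero reference reads get NaN plus a QC-failure flag.
    """
    ref = _reference_taxon(refs, reference_taxon)
    ih_reads = assignment.taxon_reads(ref.name)
    totals = table.totals
    rows = []
    for sample_id in table.sample_ids:
        dose = float(metadata.loc[sample_id, "mc_dose_fraction"])
        n_total = int(totals[sample_id])
        ih = int(ih_reads.get(sample_id, 0))
        dose_copies = dose * ref.copies_per_dose
        flag = ""
        if dose == 0:
            gcn = np.nan
            flag = "no-dose"
        elif ih == 0:
            gcn = np.nan
            flag = "spike-not-detected"
        else:
            gcn = (n_total / ih) * dose_copies
        rows.append(
            {
                "sample_id": sample_id,
                "ih_reads": ih,
                "total_reads": n_total,
                "dose_copies": dose_copies,
                "gcn": gcn,
                "log2_gcn": np.log2(gcn) if gcn and gcn > 0 else np.nan,
                "flag": flag,
            }
        )
    return GCNEstimate(table=pd.DataFrame(rows))


def transform_counts(
    stripped_table: CountTable,
    original_totals: pd.Series,
    assignment: MCAssignment,
    gcn: GCNEstimate,
    refs: Sequence[MCReference],
    reference_taxon: str | None = None,
) -> pd.DataFrame:
    """Rescale sample-SV counts to the absolute copy scale.

    Entry (j, i) becomes ``(SV_ij / counts_j) × GCN_j × (1 − ih_j /
    counts_j)`` with ``counts_j`` the pre-stripping total. Samples without
    a copy-number estimate are dropped with a warning. Zero counts map to
    zero; within-sample proportions among sample-SVs are preserved exactly
    (the factor is a per-sample constant).
    """
    ref = _reference_taxon(refs, reference_taxon)
    ih_reads = assignment.taxon_reads(ref.name)
    gcn_series = gcn.gcn()
    keep = []
    values = []
    for sample_id in stripped_table.sample_ids:
        g = gcn_series.get(sample_id, np.nan)
        if not np.isfinite(g):
            import warnings

            warnings.warn(f"no copy-number estimate for {sample_id}; sample dropped", stacklevel=2)
            continue
        counts_j = float(original_totals[sample_id])
        ih = float(ih_reads.get(sample_id, 0))
        factor = g * (1.0 - ih / counts_j) / counts_j
        values.append(stripped_table.data.loc[sample_id].to_numpy(dtype=float) * factor)
        keep.append(sample_id)
    return pd.DataFrame(values, index=keep, columns=stripped_table.sv_ids)


def flag_outliers(
    gcn: GCNEstimate,
    grouping: Mapping[str, str] | pd.Series,
    fold_threshold: float = 2.5,
) -> list[OutlierFlag]:
    """Flag samples whose copy-number estimate deviates from the group median.

    Fold deviation = ``2 ** |log2 GCN − group median log2 GCN|``; a sample
    is flagged when that exceeds ``fold_threshold``. Groups with fewer
    than three estimable members are skipped with a warning.
    """
    import warnings

    grouping = pd.Series(dict(grouping)) if not isinstance(grouping, pd.Series) else grouping
    log2 = gcn.log2_gcn().dropna()
    flags: list[OutlierFlag] = []
    for group, members in grouping.groupby(grouping):
        ids = [s for s in members.index if s in log2.index]
        if len(ids) < 3:
            warnings.warn(f"group {group!r} has < 3 estimable samples; skipped", stacklevel=2)
            continue
        median = float(np.median(log2[ids]))
        for sample_id in ids:
            fold = float(2.0 ** abs(log2[sample_id] - median))
            flags.append(
                OutlierFlag(
                    sample_id=sample_id,
                    group=str(group),
                    fold_deviation=fold,
                    flagged=fold > fold_threshold,
                )
            )
    return flags


def recommend_dose(
    sample_copies: float,
    refs: Sequence[MCReference],
    band: tuple[float, float] = (0.01, 0.10),
    gram_pos_efficiency: float = 1.0,
    sample_label: str = "sample",
) -> DoseRecommendation:
    """Dose-fraction bounds keeping the expected MC read share inside a band.

    The expected MC read fraction at dose ``d`` is
    ``f(d) = E(d) / (E(d) + sample_copies)`` with ``E(d) = d × Σ effective
    copies per dose`` (gram-positive copies scaled by
    ``gram_pos_efficiency``). Inverting for each band edge gives
    ``d = sample_copies × f / ((1 − f) × E(1))``.
    """
    if sample_copies <= 0:
        raise ValidationError("sample_copies must be > 0")
    if not (0 < band[0] < band[1] < 1):
        raise ValidationError("band must lie inside (0, 1)")
    per_dose = sum(
        r.copies_per_dose * (gram_pos_efficiency if r.gram == "positive" else 1.0)
        for r in refs
    )
    doses = [sample_copies * f / ((1.0 - f) * per_dose) for f in band]
    return DoseRecommendation(
        sample_label=sample_label,
        sample_copies=sample_copies,
        band=band,
        dose_low=doses[0],
        dose_high=doses[1],
    )


def ddpcr_crossval(gcn: GCNEstimate, ddpcr: pd.Series | Mapping[str, float]) -> dict[str, float]:
    """Regress log2 ddPCR copy measurements on log2 sequencing estimates.

    Unmatched sample ids are reported and excluded; at least three paired
    measurements are required. Returns slope, intercept, adjusted R² and
    the number of pairs used.
    """
    ddpcr = pd.Series(dict(ddpcr)) if not isinstance(ddpcr, pd.Series) else ddpcr
    est = gcn.gcn().dropna()
    shared = [s for s in est.index if s in ddpcr.index]
    excluded = sorted(set(ddpcr.index) ^ set(est.index))
    if len(shared) < 3:
        raise ValidationError("need >= 3 paired ddPCR / sequencing measurements")
    x = np.log2(est[shared].to_numpy(dtype=float))
    y = np.log2(ddpcr[shared].to_numpy(dtype=float))
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "adj_r_squared": float(fit.rsquared_adj),
        "n": len(shared),
        "excluded": excluded,
    }
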