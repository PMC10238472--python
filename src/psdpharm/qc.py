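"""Peptide-level QC and normalization.

The chain, in study order: zeros-to-missing -> sample loading normalization
-> pooled-control presence filter -> multi-mapped peptide removal -> outlier
sample removal -> internal reference scaling (IRS) -> median normalization
-> present-call filtering. All operations are pure (they return new
matrices) and optionally log into a :class:`NormalizationReport`.

IRS is the cross-plex correction specific to multiplexed designs: for each
peptide and plex, every channel of the plex is multiplied by
(overall mean of pooled-control values) / (within-plex pooled mean), so that
after the step each peptide's pooled-control mean agrees across plexes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import NormalizationReport, PeptideMatrix

MAD_SCALE = 1.4826  # consistency constant for normally distributed data


def zeros_to_missing(
    m: PeptideMatrix, report: NormalizationReport | None = None
) -> PeptideMatrix:
    """Treat exactly-zero abundances as missing (NaN)."""
    vals = m.abundance.to_numpy()
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative abundance encountered")
    out = m.abundance.mask(m.abundance == 0.0)
    if report is not None:
        report.record_stage("zeros_to_missing")
        miss = out.isna().mean(axis=0)
        report.missing_rate_per_channel = miss.to_dict()
    return m.with_abundance(out)


def sample_loading_normalize(
    m: PeptideMatrix, report: NormalizationReport | None = None
) -> PeptideMatrix:
    """Scale each channel so total abundance is equal across channels.

    The common target is the grand mean of the per-channel totals (computed
    over present values).
    """
    totals = m.abundance.sum(axis=0, skipna=True)
    empty = totals.index[m.abundance.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"channel(s) with no present values: {list(empty)}")
    target = totals.mean()
    factors = target / totals
    out = m.abundance * factors
    if report is not None:
        report.record_stage("sample_loading_normalize")
        report.totals_before = totals.to_dict()
        report.totals_after = out.sum(axis=0, skipna=True).to_dict()
        report.factors["loading"] = factors.to_dict()
    return m.with_abundance(out)


def filter_pooled_missing(
    m: PeptideMatrix, report: NormalizationReport | None = None
) -> tuple[PeptideMatrix, list[str]]:
    """Remove peptides missing in ALL pooled channels of >= half the plexes."""
    plexes = m.plexes
    n_plexes = len(plexes)
    both_missing = pd.DataFrame(index=m.peptides, columns=plexes, dtype=bool)
    for plex in plexes:
        pooled = m.channels_in_plex(plex, pooled=True)
        if len(pooled) == 0:
            raise ValueError(f"plex {plex} has no pooled channels")
        both_missing[plex] = m.abundance[pooled].isna().all(axis=1)
    n_bad = both_missing.sum(axis=1)
    removed = list(m.peptides[n_bad >= n_plexes / 2])
    kept = m.subset_peptides(m.peptides[n_bad < n_plexes / 2])
    if report is not None:
        report.record_stage("filter_pooled_missing")
        report.record_removed(removed, "pooled-missing")
    return kept, removed


def drop_multimapped(
    m: PeptideMatrix, report: NormalizationReport | None = None
) -> tuple[PeptideMatrix, list[str]]:
    """Remove peptides mapped to more than one protein/gene."""
    n_map = m.pep2prot.map(len)
    if (n_map == 0).any():
        bad = list(m.pep2prot.index[n_map == 0])
        raise ValueError(f"peptide(s) with no protein mapping: {bad}")
    removed = list(m.peptides[n_map > 1])
    kept = m.subset_peptides(m.peptides[n_map == 1])
    if report is not None:
        report.record_stage("drop_multimapped")
        report.record_removed(removed, "multi-mapped")
    return kept, removed


def detect_outlier_samples(
    m: PeptideMatrix, k: float = 3.0, report: NormalizationReport | None = None
) -> list[str]:
    """Flag subject channels with aberrant total abundance.

    A channel is an outlier when its log2 total deviates from the median of
    subject-channel log2 totals by more than ``k`` scaled MADs (the
    reproducible analogue of the study's visual total-abundance screen).
    Pooled channels are never flagged. Call this on raw (pre-loading-
    normalization) data: loading normalization equalizes the totals.
    """
    subj = m.subject_channels
    if len(subj) < 3:
        raise ValueError("need at least 3 subject channels")
    totals = np.log2(m.abundance[subj].sum(axis=0, skipna=True))
    med = totals.median()
    mad = (totals - med).abs().median() * MAD_SCALE
    if mad == 0:
        if not np.allclose(totals, med):
            warnings.warn("zero MAD with unequal totals; flagging nothing")
        flagged: list[str] = []
    else:
        flagged = list(totals.index[(totals - med).abs() > k * mad])
    if report is not None:
        report.record_stage("detect_outlier_samples")
        report.flagged_outliers = [str(f) for f in flagged]
    return flagged


def irs_normalize(
    m: PeptideMatrix, report: NormalizationReport | None = None
) -> PeptideMatrix:
    """Internal reference scaling across plexes, per peptide.

    factor(peptide, plex) = mean(all present pooled values across plexes)
    / mean(present pooled values within the plex). If a surviving peptide has
    no present pooled value in some plex, no valid factor exists and the
    peptide's values in that plex are set missing.
    """
    pooled_all = m.abundance[m.pooled_channels]
    overall = pooled_all.mean(axis=1, skipna=True)
    out = m.abundance.copy()
    factor_summary: dict[str, dict[str, float]] = {}
    for plex in m.plexes:
        pooled = m.channels_in_plex(plex, pooled=True)
        plex_mean = m.abundance[pooled].mean(axis=1, skipna=True)
        factor = overall / plex_mean  # NaN where pooled mean undefined
        cols = m.channels_in_plex(plex)
        out[cols] = out[cols].mul(factor, axis=0)
        factor_summary[plex] = {
            "median_factor": float(np.nanmedian(factor.to_numpy())),
            "n_undefined": int(factor.isna().sum()),
        }
    if report is not None:
        report.record_stage("irs_normalize")
        report.factors["irs"] = factor_summary
    return m.with_abundance(out)


def median_normalize(
    m: PeptideMatrix, report: NormalizationReport | None = None
) -> PeptideMatrix:
    """Scale each channel so its median equals the overall pre-scaling median."""
    medians = m.abundance.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"channel(s) with no present values: {bad}")
    target = float(np.nanmedian(m.abundance.to_numpy()))
    factors = target / medians
    out = m.abundance * factors
    if report is not None:
        report.record_stage("median_normalize")
        report.factors["median"] = factors.to_dict()
    return m.with_abundance(out)


def present_call_filter(
    m: PeptideMatrix, threshold: float, report: NormalizationReport | None = None
) -> PeptideMatrix:
    """Retain peptides present in >= threshold of subject (non-pooled) channels."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    subj = m.subject_channels
    frac = m.abundance[subj].notna().mean(axis=1)
    kept = m.subset_peptides(m.peptides[frac >= threshold])
    if report is not None:
        report.record_stage(f"present_call_filter({threshold})")
    return kept


PIPELINE_ORDER = [
    "zeros_to_missing",
    "sample_loading_normalize",
    "filter_pooled_missing",
    "drop_multimapped",
    "detect_outlier_samples",
    "irs_normalize",
    "median_normalize",
]


def normalize_pipeline(
    m: PeptideMatrix,
    present_call: float = 1.0,
    outlier_k: float = 3.0,
) -> tuple[PeptideMatrix, NormalizationReport]:
    """Run the full QC/normalization chain in study order.

    Outlier flags are computed from the raw totals (before loading
    normalization, which would equalize them) but the flagged channels are
    removed at the stated position in the chain.
    """
    report = NormalizationReport()
    raw_flags = detect_outlier_samples(zeros_to_missing(m), k=outlier_k)
    out = zeros_to_missing(m, report)
    out = sample_loading_normalize(out, report)
    out, _ = filter_pooled_missing(out, report)
    out, _ = drop_multimapped(out, report)
    report.record_stage("detect_outlier_samples")
    report.flagged_outliers = [str(f) for f in raw_flags]
    if raw_flags:
        out = out.drop_channels(raw_flags)
    out = irs_normalize(out, report)
    out = median_normalize(out, report)
    out = present_call_filter(out, present_call, report)
    assert report.stages[: len(PIPELINE_ORDER)] == PIPELINE_ORDER, (
        "normalization stages ran out of order"
    )
    return out, report
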