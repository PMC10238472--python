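"""Evaluation of a drug-treatment experiment against a disease signature.

Per-protein treated-vs-vehicle log2 fold changes are tested for a net shift
(one-sample t-test against 0) over (a) all proteins shared with the full
disease signature and (b) the shared top differentially-expressed subset,
and the drug-effect sign pattern is scored against the disease signature
with the Signed Jaccard Index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ProteinMatrix, SignedSignature
from .pharmacology import signed_jaccard


def treatment_log2fc(pm: ProteinMatrix, labels: pd.Series) -> pd.Series:
    """Per-protein mean(treated) - mean(vehicle) on rolled-up values.

    ``labels`` maps sample id -> "treated"/"vehicle". Missing values are
    handled complete-case per protein; each arm needs >= 2 samples.
    """
    labels = labels.reindex(pm.values.columns)
    treated = pm.values.columns[labels == "treated"]
    vehicle = pm.values.columns[labels == "vehicle"]
    if len(treated) < 2 or len(vehicle) < 2:
        raise ValueError("need at least 2 samples per arm")
    fc = pm.values[treated].mean(axis=1, skipna=True) - pm.values[vehicle].mean(
        axis=1, skipna=True
    )
    fc.name = "log2fc"
    return fc


@dataclass
class TreatmentResult:
    """Shift tests and reversal score of a treatment experiment."""

    log2fc: pd.Series
    full_overlap: pd.Index
    top_overlap: pd.Index
    t_full: float
    df_full: int
    p_full: float
    t_top: float
    df_top: int
    p_top: float
    signed_jaccard: float

    def summary(self) -> dict:
        return {
            "n_full_overlap": int(len(self.full_overlap)),
            "n_top_overlap": int(len(self.top_overlap)),
            "mean_log2fc_full": float(self.log2fc.loc[self.full_overlap].mean()),
            "mean_log2fc_top": float(self.log2fc.loc[self.top_overlap].mean()),
            "t_full": self.t_full,
            "df_full": self.df_full,
            "p_full": self.p_full,
            "t_top": self.t_top,
            "df_top": self.df_top,
            "p_top": self.p_top,
            "signed_jaccard": self.signed_jaccard,
        }


def _one_sample_t(values: np.ndarray) -> tuple[float, int, float]:
    if len(values) < 2:
        raise ValueError("need >= 2 values for the shift test")
    if np.allclose(values, values[0]):
        raise ValueError("zero-variance fold-change vector")
    res = stats.ttest_1samp(values, 0.0)
    return float(res.statistic), len(values) - 1, float(res.pvalue)


def reversal_test(
    fc: pd.Series,
    disease_full: SignedSignature,
    disease_top: SignedSignature,
    threshold: float | None = None,
) -> TreatmentResult:
    """Score a drug effect against the disease signature.

    The drug-effect signature uses every overlap protein with nonzero fold
    change (no significance filter by default, mirroring the use of all
    quantified overlap proteins; ``threshold`` optionally requires
    |log2FC| > threshold).
    """
    fc = fc[np.isfinite(fc)]
    full_overlap = fc.index.intersection(disease_full.entities)
    if len(full_overlap) < 2:
        raise ValueError("need >= 2 proteins overlapping the disease signature")
    top_overlap = full_overlap.intersection(disease_top.entities)

    t_full, df_full, p_full = _one_sample_t(fc.loc[full_overlap].to_numpy())
    if len(top_overlap) >= 2:
        t_top, df_top, p_top = _one_sample_t(fc.loc[top_overlap].to_numpy())
    else:
        t_top, df_top, p_top = np.nan, 0, np.nan

    drug_fc = fc.loc[full_overlap]
    if threshold is not None:
        drug_fc = drug_fc[drug_fc.abs() > threshold]
    drug_fc = drug_fc[drug_fc != 0]
    drug_sig = SignedSignature(
        sign=np.sign(drug_fc).astype(int),
        magnitude=drug_fc.abs(),
        label="drug-effect",
    )
    j = signed_jaccard(drug_sig, disease_full)
    return TreatmentResult(
        log2fc=fc,
        full_overlap=full_overlap,
        top_overlap=top_overlap,
        t_full=t_full,
        df_full=df_full,
        p_full=p_full,
        t_top=t_top,
        df_top=df_top,
        p_top=p_top,
        signed_jaccard=j,
    )
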