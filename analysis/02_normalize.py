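#!/usr/bin/env python
"""QC and normalization of the simulated peptide data.

Walks the chain in study order — zeros-to-missing, sample loading
normalization, pooled-control presence filter, multi-mapped removal,
outlier-sample removal, internal reference scaling (IRS), median
normalization, 100% present-call filter — verifying each step's
postcondition where it holds (loading equalizes totals, IRS equalizes
per-peptide pooled means across plexes, median normalization equalizes
channel medians).

Reads results/data/peptides.*; writes results/normalized/*.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from psdpharm import qc, tsv
from psdpharm.containers import NormalizationReport

IN = Path("results/data")
OUT = Path("results/normalized")


def main() -> None:
    matrix = tsv.read_peptide_matrix(IN / "peptides")
    report = NormalizationReport()

    raw_outliers = qc.detect_outlier_samples(qc.zeros_to_missing(matrix), k=3.0)
    m = qc.zeros_to_missing(matrix, report)
    m = qc.sample_loading_normalize(m, report)
    totals = m.abundance.sum(axis=0, skipna=True)
    print(f"loading: channel totals equalized "
          f"(max rel dev {(totals / totals.mean() - 1).abs().max():.1e})")

    m, removed_pooled = qc.filter_pooled_missing(m, report)
    m, removed_multi = qc.drop_multimapped(m, report)
    report.record_stage("detect_outlier_samples")
    report.flagged_outliers = list(raw_outliers)
    if raw_outliers:
        m = m.drop_channels(raw_outliers)
    print(f"filters: {len(removed_pooled)} pooled-missing, "
          f"{len(removed_multi)} multi-mapped peptides removed; "
          f"outlier channels: {raw_outliers or 'none'}")

    m = qc.irs_normalize(m, report)
    pooled_means = pd.concat(
        {
            plex: m.abundance[m.channels_in_plex(plex, pooled=True)].mean(
                axis=1, skipna=True
            )
            for plex in m.plexes
        },
        axis=1,
    )
    spread = pooled_means.max(axis=1) / pooled_means.min(axis=1) - 1
    print(f"IRS: per-peptide pooled means equal across plexes "
          f"(max rel spread {np.nanmax(spread.to_numpy()):.1e})")

    m = qc.median_normalize(m, report)
    medians = m.abundance.median(axis=0, skipna=True)
    print(f"median: channel medians equalized "
          f"(max rel dev {(medians / medians.iloc[0] - 1).abs().max():.1e})")

    n_before = len(m.peptides)
    m = qc.present_call_filter(m, 1.0, report)
    print(f"present call 100%: {n_before} -> {len(m.peptides)} peptides")

    OUT.mkdir(parents=True, exist_ok=True)
    tsv.write_peptide_matrix(m, OUT / "peptides")
    tsv.write_json(report.to_dict(), OUT / "normalization_report.json")


if __name__ == "__main__":
    main()
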