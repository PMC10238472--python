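"""Peptide-to-protein roll-up with uncorrelated-peptide detection.

After normalization, each subject channel is multiplied by its sample's PSD
yield (restoring the biological signal removed by equal-amount labeling),
peptides whose condition effect deviates from their protein-mates are
flagged by a PeCorA-style interaction test, and protein values are formed by
averaging peptide z-scores on the log2 scale. Flagged peptides are split out
as separate ``"<protein>|<peptide>"`` entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import PeptideMatrix, ProteinMatrix


def yield_adjust(m: PeptideMatrix, meta: pd.DataFrame) -> PeptideMatrix:
    """Multiply each subject channel by that sample's PSD yield.

    Pooled channels are left unchanged. ``meta`` must hold a positive
    ``psd_yield`` for every subject sample in the matrix.
    """
    out = m.abundance.copy()
    for key in m.subject_channels:
        sid = m.channel_meta.loc[key, "sample_id"]
        if sid not in meta.index:
            raise ValueError(f"no metadata for sample {sid!r} (channel {key})")
        y = meta.loc[sid, "psd_yield"]
        if not np.isfinite(y) or y <= 0:
            raise ValueError(f"nonpositive or missing PSD yield for sample {sid!r}")
        out[key] = out[key] * float(y)
    return m.with_abundance(out)


@dataclass
class PecoraFlags:
    """Per-peptide interaction-test results.

    ``table`` columns: protein, peptide, f_stat, p, p_adj, flagged.
    Peptides of single-peptide proteins are untested and absent.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def flagged_peptides(self) -> pd.Index:
        t = self.table
        return pd.Index(t.loc[t["flagged"], "peptide"])


def _interaction_f_test(
    y: np.ndarray, group_codes: np.ndarray, is_target: np.ndarray
) -> tuple[float, float]:
    """F-test of the group x is_target interaction in a linear model.

    Full model: intercept + group dummies + is_target + group:is_target;
    reduced model drops the interaction columns. Returns (F, p).
    """
    n = len(y)
    groups = np.unique(group_codes)
    g_dummies = np.column_stack(
        [(group_codes == g).astype(float) for g in groups[1:]]
    ) if len(groups) > 1 else np.empty((n, 0))
    base = np.column_stack([np.ones(n), g_dummies, is_target.astype(float)])
    inter = g_dummies * is_target[:, None].astype(float)
    full = np.column_stack([base, inter])

    def rss_rank(X: np.ndarray) -> tuple[float, int]:
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), rank

    rss_f, rank_f = rss_rank(full)
    rss_r, rank_r = rss_rank(base)
    q = rank_f - rank_r
    dof = n - rank_f
    if q <= 0 or dof <= 0 or rss_f <= 0:
        return np.nan, np.nan
    f = ((rss_r - rss_f) / q) / (rss_f / dof)
    return f, float(stats.f.sf(f, q, dof))


def pecora_flag(
    m: PeptideMatrix, meta: pd.DataFrame, alpha: float = 0.01
) -> PecoraFlags:
    """Flag peptides whose group effect deviates from their protein-mates.

    For each peptide p of a multi-peptide protein, all of the protein's
    peptide observations (peptide-centered log2 values, one observation per
    peptide x subject) are modeled as value ~ group + is_p + group:is_p and
    the interaction is F-tested. p-values are BH-adjusted across all tested
    peptides; flagged iff adjusted p < ``alpha``.
    """
    subj = m.subject_channels
    sids = m.channel_meta.loc[subj, "sample_id"]
    groups = meta.loc[sids, "group"].to_numpy()
    codes = pd.factorize(groups)[0]
    log2 = np.log2(m.abundance[subj])
    centered = log2.sub(log2.mean(axis=1, skipna=True), axis=0)

    prot_of = m.pep2prot.map(lambda t: t[0])
    rows = []
    for protein, peps in prot_of.groupby(prot_of).groups.items():
        peps = pd.Index(peps)
        if len(peps) < 2:
            continue
        sub = centered.loc[peps]
        long_vals = sub.to_numpy().ravel()  # peptide-major
        pep_idx = np.repeat(np.arange(len(peps)), len(subj))
        grp_long = np.tile(codes, len(peps))
        ok = np.isfinite(long_vals)
        for i, pep in enumerate(peps):
            f, p = _interaction_f_test(
                long_vals[ok], grp_long[ok], (pep_idx == i)[ok]
            )
            rows.append((protein, pep, f, p))
    table = pd.DataFrame(rows, columns=["protein", "peptide", "f_stat", "p"])
    if len(table):
        ok = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                table.loc[ok, "p"].to_numpy(), method="fdr_bh"
            )[1]
        table["p_adj"] = adj
        table["flagged"] = table["p_adj"] < alpha
    else:
        table["p_adj"] = []
        table["flagged"] = []
    return PecoraFlags(table=table, alpha=alpha)


def rollup_protein(
    m: PeptideMatrix, flags: PecoraFlags | None = None
) -> ProteinMatrix:
    """Average per-peptide log2 z-scores into protein values.

    Each peptide's log2 values are z-scored across subject channels (sample
    SD, present values only); the protein value per subject is the mean of
    available peptide z-scores. Flagged (uncorrelated) peptides are removed
    from their parent and emitted as separate ``"<protein>|<peptide>"``
    entries. Zero-variance peptides are excluded with a warning.
    """
    subj = m.subject_channels
    sids = m.channel_meta.loc[subj, "sample_id"]
    log2 = np.log2(m.abundance[subj])
    mu = log2.mean(axis=1, skipna=True)
    sd = log2.std(axis=1, ddof=1, skipna=True)
    degenerate = sd.index[(sd == 0) | sd.isna()]
    if len(degenerate):
        warnings.warn(
            f"{len(degenerate)} peptide(s) with undefined z-scores excluded"
        )
    z = log2.sub(mu, axis=0).div(sd, axis=0)
    z = z.drop(index=degenerate)

    flagged = set(flags.flagged_peptides) if flags is not None else set()
    prot_of = m.pep2prot.map(lambda t: t[0])
    out_rows: dict[str, np.ndarray] = {}
    provenance: dict[str, list[str]] = {}
    for protein, peps in prot_of.groupby(prot_of).groups.items():
        peps = [p for p in peps if p in z.index]
        parent = [p for p in peps if p not in flagged]
        if parent:
            out_rows[protein] = z.loc[parent].mean(axis=0, skipna=True).to_numpy()
            provenance[protein] = list(parent)
        for p in peps:
            if p in flagged:
                name = f"{protein}|{p}"
                out_rows[name] = z.loc[[p]].mean(axis=0).to_numpy()
                provenance[name] = [p]
    values = pd.DataFrame.from_dict(out_rows, orient="index", columns=list(sids))
    values.index.name = "protein"
    return ProteinMatrix(values=values, provenance=provenance)
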