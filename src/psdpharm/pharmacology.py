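"""Signed-signature drug repurposing chain.

From a differential result: build the signed disease signature; screen a
knockdown atlas for upstream genes whose silencing signature correlates
with the disease signature; nominate drugs whose action on such a gene is
predicted to push the proteome the other way (negative correlation ->
inhibitor/antagonist-class, positive correlation -> agonist/potentiator-
class, the pattern of the study's candidate table); drop genes whose
correlation flips sign on the top differentially-expressed subset (the
MTOR-style inconsistency); validate candidates against LINCS-style Z-score
profiles filtered to CNS cell lines and doses >= 1 uM with mean |Z| > 1;
and score reversal with the Signed Jaccard Index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import KnockdownAtlas, SignedSignature

# DrugBank-style action strings normalized to the closed vocabulary
ACTION_ALIASES = {
    "blocker": "antagonist",
    "inverse agonist": "antagonist",
    "suppressor": "inhibitor",
    "activator": "agonist",
    "inducer": "agonist",
    "stimulator": "agonist",
}
NEGATIVE_ACTIONS = {"inhibitor", "antagonist", "negative modulator"}
POSITIVE_ACTIONS = {"agonist", "potentiator", "positive modulator"}
KNOWN_ACTIONS = NEGATIVE_ACTIONS | POSITIVE_ACTIONS | {"other"}


def normalize_action(action: str) -> str:
    a = str(action).strip().lower()
    return ACTION_ALIASES.get(a, a)


def build_signature(
    result: pd.DataFrame, mode: str = "full", alpha: float = 0.05
) -> SignedSignature:
    """Signed disease signature from a differential result.

    ``mode="full"``: every protein with nonzero log2FC; ``mode="top"``:
    restricted to raw p < ``alpha`` (the nominally-significant subset).
    Magnitudes (|log2FC|) are carried for correlation.
    """
    if mode not in {"full", "top"}:
        raise ValueError("mode must be 'full' or 'top'")
    if result.empty:
        raise ValueError("empty differential result")
    sub = result[np.isfinite(result["log2fc"])]
    if mode == "top":
        sub = sub[sub["p"] < alpha]
    zero = sub.index[sub["log2fc"] == 0]
    if len(zero):
        warnings.warn(f"{len(zero)} zero-log2FC protein(s) dropped from signature")
        sub = sub.drop(index=zero)
    return SignedSignature(
        sign=np.sign(sub["log2fc"]).astype(int),
        magnitude=sub["log2fc"].abs(),
        label=f"disease:{mode}",
        provenance=str(result.attrs.get("contrast", "")),
    )


def correlate_knockdown(
    atlas: KnockdownAtlas,
    sig: SignedSignature,
    min_shared: int = 10,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate each knockdown signature with the disease signature.

    Returns a frame indexed by gene with rho, p, n_shared, sign and a
    ``skipped`` reason where the correlation is undefined (too few shared
    entities or a constant vector).
    """
    disease = sig.values_for_correlation()
    rows = []
    for gene in atlas.genes:
        ksig = atlas.signature(gene)
        shared = ksig.entities.intersection(disease.index)
        if len(shared) < min_shared:
            rows.append((gene, np.nan, np.nan, len(shared), 0, "too-few-shared"))
            continue
        x = ksig.values_for_correlation().loc[shared].to_numpy()
        y = disease.loc[shared].to_numpy()
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            rows.append((gene, np.nan, np.nan, len(shared), 0, "constant-vector"))
            continue
        if method == "spearman":
            rho, p = stats.spearmanr(x, y)
        elif method == "pearson":
            rho, p = stats.pearsonr(x, y)
        else:
            raise ValueError("method must be 'spearman' or 'pearson'")
        rows.append((gene, float(rho), float(p), len(shared), int(np.sign(rho)), ""))
    return pd.DataFrame(
        rows, columns=["gene", "rho", "p", "n_shared", "sign", "skipped"]
    ).set_index("gene")


def nominate_drugs(
    correlations: pd.DataFrame,
    drugs: pd.DataFrame,
    corr_alpha: float = 0.01,
) -> pd.DataFrame:
    """Candidate drugs whose target action aligns with the correlation sign.

    A (drug, gene) pair is nominated iff the gene's knockdown correlation is
    significant (p < ``corr_alpha``, standing in for the curated atlas's own
    inclusion screen) and either [rho < 0 and the action is in the
    inhibitor/antagonist class] or [rho > 0 and the action is in the
    agonist/potentiator class]. Each candidate carries its rule.
    """
    rows = []
    for _, r in drugs.iterrows():
        gene = r["gene"]
        if gene not in correlations.index:
            continue
        c = correlations.loc[gene]
        if c["skipped"] or not np.isfinite(c["rho"]) or c["p"] >= corr_alpha:
            continue
        action = normalize_action(r["action"])
        if action not in KNOWN_ACTIONS:
            warnings.warn(f"unknown action {r['action']!r} for drug {r['drug']!r}")
            continue
        if c["rho"] < 0 and action in NEGATIVE_ACTIONS:
            rule = "negative-correlation+inhibitory-action"
        elif c["rho"] > 0 and action in POSITIVE_ACTIONS:
            rule = "positive-correlation+potentiating-action"
        else:
            continue
        rows.append(
            (r["drug"], gene, action, float(c["rho"]), float(c["p"]), rule)
        )
    return pd.DataFrame(
        rows, columns=["drug", "gene", "action", "rho", "rho_p", "rule"]
    )


def subset_consistency_filter(
    atlas: KnockdownAtlas,
    full_sig: SignedSignature,
    top_sig: SignedSignature,
    candidates: pd.DataFrame,
    min_shared: int = 10,
    method: str = "spearman",
) -> pd.DataFrame:
    """Drop candidates whose correlation sign flips on the top-DE subset.

    For each candidate gene the knockdown correlation is recomputed against
    the top (nominally significant) signature; candidates whose top-subset
    correlation sign differs from the full-signature sign are removed (the
    MTOR-style exclusion). Genes untestable on the subset (overlap below
    ``min_shared``) are retained with a flag.
    """
    if candidates.empty:
        out = candidates.copy()
        out["rho_top"] = pd.Series(dtype=float)
        out["subset_consistent"] = pd.Series(dtype=object)
        return out
    top_corr = correlate_knockdown(
        atlas, top_sig, min_shared=min_shared, method=method
    )
    rho_top = []
    status = []
    keep = []
    for _, r in candidates.iterrows():
        gene = r["gene"]
        c = top_corr.loc[gene] if gene in top_corr.index else None
        if c is None or c["skipped"] or not np.isfinite(c["rho"]):
            rho_top.append(np.nan)
            status.append("untestable")
            keep.append(True)
        else:
            rho_top.append(float(c["rho"]))
            consistent = np.sign(c["rho"]) == np.sign(r["rho"])
            status.append("consistent" if consistent else "inconsistent")
            keep.append(bool(consistent))
    out = candidates.copy()
    out["rho_top"] = rho_top
    out["subset_consistent"] = status
    return out[np.array(keep)].reset_index(drop=True)


def lincs_signature(
    profiles: pd.DataFrame,
    drug: str,
    cns_only: bool = True,
    min_dose: float = 1.0,
    z_thresh: float = 1.0,
) -> tuple[SignedSignature, str]:
    """Per-gene averaged-Z signature of a drug from LINCS-style profiles.

    Rows are filtered to CNS cell lines (if ``cns_only``) and dose >=
    ``min_dose`` uM; Z scores for the same gene are averaged across the
    remaining tests and genes with mean |Z| > ``z_thresh`` form the
    signature. Returns (signature, status); status distinguishes drugs
    absent from the table ("not found") from drugs tested only outside the
    CNS ("not tested in CNS cells").
    """
    sub = profiles[profiles["drug"] == drug]
    if sub.empty:
        return SignedSignature(pd.Series(dtype=int), label=f"lincs:{drug}"), "not found"
    if cns_only:
        cns = sub[sub["is_cns"].astype(bool)]
        if cns.empty:
            return (
                SignedSignature(pd.Series(dtype=int), label=f"lincs:{drug}"),
                "not tested in CNS cells",
            )
        sub = cns
    sub = sub[sub["dose_um"] >= min_dose]
    if sub.empty:
        return (
            SignedSignature(pd.Series(dtype=int), label=f"lincs:{drug}"),
            "no qualifying dose",
        )
    mean_z = sub.groupby("gene")["z"].mean()
    sig_genes = mean_z[mean_z.abs() > z_thresh]
    return (
        SignedSignature(
            sign=np.sign(sig_genes).astype(int),
            magnitude=sig_genes.abs(),
            label=f"lincs:{drug}",
        ),
        "ok",
    )


def signed_jaccard(a: SignedSignature, b: SignedSignature) -> float:
    """Signed Jaccard Index between two signed entity sets, in [-1, +1].

    J = (|A+ n B+| + |A- n B-| - |A+ n B-| - |A- n B+|) / |supp(A) u supp(B)|;
    +1 for an identical direction pattern, -1 for a fully inverted one,
    0 for an empty union.
    """
    union = a.entities.union(b.entities)
    if len(union) == 0:
        return 0.0
    shared = a.entities.intersection(b.entities)
    sa = a.sign.loc[shared].to_numpy()
    sb = b.sign.loc[shared].to_numpy()
    net = int((sa == sb).sum()) - int((sa != sb).sum())
    return net / len(union)


@dataclass
class NominationResult:
    """Full chain output for reporting: candidates with LINCS validation."""

    table: pd.DataFrame  # drug, gene, action, rho, rho_top, lincs_status, lincs_j


def run_pharmacology(
    atlas: KnockdownAtlas,
    drugs: pd.DataFrame,
    lincs: pd.DataFrame,
    full_sig: SignedSignature,
    top_sig: SignedSignature,
    min_shared: int = 10,
    corr_alpha: float = 0.01,
    method: str = "spearman",
) -> NominationResult:
    """Correlate -> nominate -> subset-filter -> LINCS-validate, end to end.

    Output rows are ordered by Signed Jaccard ascending (strongest predicted
    reversal first), ties broken by drug name.
    """
    corr = correlate_knockdown(atlas, full_sig, min_shared=min_shared, method=method)
    cand = nominate_drugs(corr, drugs, corr_alpha=corr_alpha)
    cand = subset_consistency_filter(
        atlas, full_sig, top_sig, cand, min_shared=min_shared, method=method
    )
    statuses = []
    js = []
    for _, r in cand.iterrows():
        sig, status = lincs_signature(lincs, r["drug"])
        statuses.append(status)
        js.append(signed_jaccard(sig, full_sig) if status == "ok" else np.nan)
    out = cand.copy()
    out["lincs_status"] = statuses
    out["lincs_j"] = js
    out = out.sort_values(
        ["lincs_j", "drug"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return NominationResult(table=out)
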