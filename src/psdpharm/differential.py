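"""Covariate-adjusted differential abundance with variance moderation.

Per protein, an ordinary least-squares fit of the rolled-up value on a
group indicator plus covariates gives the model-based log2 fold change and
its standard error; residual variances are then shrunk toward a common
prior by empirical-Bayes moderation (the standard squeeze: posterior
variance = (d0*s0^2 + d*s2)/(d0 + d) with the prior df d0 and prior
variance s0^2 estimated from the observed variance distribution by the
method of moments on log variances). Benjamini-Hochberg adjustment is
applied across proteins within each contrast; all tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ProteinMatrix


@dataclass
class ContrastSpec:
    """A two-group comparison with covariate adjustment.

    log2FC is reported as group_a minus group_b.
    """

    name: str
    group_a: str
    group_b: str
    covariates: list[str] = field(default_factory=list)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of residual variances.

    Returns (posterior variances, prior df d0, prior variance s0^2); d0 may
    be inf when the observed variances are no more dispersed than sampling
    alone predicts, in which case every posterior variance equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return s2.copy(), 0.0, float("nan")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df[ok] / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
        post = s2.copy()
        post[ok] = (d0 * s0_2 + df[ok] * s2[ok]) / (d0 + df[ok])
    else:
        # no excess dispersion beyond sampling: shrink to the common
        # (geometric-mean) observed variance, so identical variances pass
        # through unchanged
        d0 = float("inf")
        s0_2 = float(np.exp(np.mean(z)))
        post = s2.copy()
        post[ok] = s0_2
    return post, d0, s0_2


def fit_contrast(
    pm: ProteinMatrix,
    meta: pd.DataFrame,
    spec: ContrastSpec,
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-protein differential abundance for one contrast.

    Complete-case OLS per protein of value ~ 1[group_a] + covariates; the
    group coefficient is the log2 fold change (group_a - group_b). With
    ``moderate``, residual variances are squeezed and t/df adjusted. Returns
    a frame indexed by protein with columns log2fc, se, t, df, p, p_adj and
    attrs n_a / n_b.
    """
    for cov in spec.covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} not in sample metadata")
    in_contrast = meta["group"].isin([spec.group_a, spec.group_b])
    sub = meta[in_contrast]
    samples = pm.values.columns.intersection(sub.index)
    sub = sub.loc[samples]
    n_a = int((sub["group"] == spec.group_a).sum())
    n_b = int((sub["group"] == spec.group_b).sum())
    if min(n_a, n_b) < 2:
        raise ValueError("need at least 2 subjects per group")

    ind = (sub["group"] == spec.group_a).to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub)), ind]
        + [sub[c].to_numpy(dtype=float) for c in spec.covariates]
    )
    Y = pm.values[samples].to_numpy(dtype=float)
    n_prot = Y.shape[0]
    p_cols = X.shape[1]

    log2fc = np.full(n_prot, np.nan)
    se = np.full(n_prot, np.nan)
    s2 = np.full(n_prot, np.nan)
    dof = np.full(n_prot, np.nan)

    # group proteins by missingness pattern so the normal equations are
    # solved once per pattern (the no-missing pattern dominates)
    finite = np.isfinite(Y)
    patterns: dict[bytes, list[int]] = {}
    for i in range(n_prot):
        patterns.setdefault(finite[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        Xm = X[mask]
        nm = int(mask.sum())
        if nm <= p_cols:
            continue
        rank = np.linalg.matrix_rank(Xm)
        if rank < p_cols:
            continue  # rank-deficient design: leave stats missing
        XtX_inv = np.linalg.inv(Xm.T @ Xm)
        H = XtX_inv @ Xm.T
        Ym = Y[np.ix_(rows, np.where(mask)[0])]
        B = Ym @ H.T  # proteins x p_cols
        resid = Ym - B @ Xm.T
        rss = np.einsum("ij,ij->i", resid, resid)
        d = nm - p_cols
        s2_rows = rss / d
        log2fc[rows] = B[:, 1]
        s2[rows] = s2_rows
        se[rows] = np.sqrt(s2_rows * XtX_inv[1, 1])
        dof[rows] = d

    if moderate:
        post, d0, _ = squeeze_variances(s2, dof)
        with np.errstate(invalid="ignore", divide="ignore"):
            se_mod = se * np.sqrt(post / s2)
        t = log2fc / se_mod
        t_df = dof + d0
        se_out = se_mod
    else:
        t = log2fc / se
        t_df = dof
        se_out = se
    with np.errstate(invalid="ignore"):
        p = np.where(
            np.isfinite(t),
            2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(t_df), 1e12, t_df)),
            np.nan,
        )

    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se_out,
            "t": t,
            "df": t_df,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=pm.values.index,
    )
    result.attrs["contrast"] = spec.name
    result.attrs["n_a"] = n_a
    result.attrs["n_b"] = n_b
    return result


def global_shift_test(result: pd.DataFrame) -> tuple[float, int, float]:
    """One-sample two-sided t-test of the log2FC vector against mean 0.

    The statistic asks whether the proteome as a whole is shifted (the
    global-reduction signal), with df = #proteins - 1.
    """
    fc = result["log2fc"].to_numpy(dtype=float)
    fc = fc[np.isfinite(fc)]
    if len(fc) < 2:
        raise ValueError("need at least 2 finite log2FC values")
    if np.allclose(fc, fc[0]):
        raise ValueError("zero variance of log2FC values")
    res = stats.ttest_1samp(fc, 0.0)
    return float(res.statistic), len(fc) - 1, float(res.pvalue)


def de_set(
    result: pd.DataFrame, alpha: float = 0.05, adjusted: bool = False
) -> set[str]:
    """Proteins with (raw or BH-adjusted) p below alpha."""
    col = "p_adj" if adjusted else "p"
    return set(result.index[result[col] < alpha])
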