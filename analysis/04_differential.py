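#!/usr/bin/env python
"""Covariate-adjusted differential abundance, AD+P vs AD-P.

Fits the moderated per-protein regression (group indicator + age, PMI,
sex, APOE*e4, Lewy body, log2 phospho-tau area), BH-adjusts across
proteins, tests the proteome-wide shift of the log2FC distribution, and
builds the full and top (nominal p < 0.05) signed disease signatures.

Reads results/proteins/proteins.tsv and results/data/cohort.tsv; writes
results/differential/*.
"""

from pathlib import Path

from psdpharm import (
    ContrastSpec,
    build_signature,
    de_set,
    fit_contrast,
    global_shift_test,
    tsv,
)
from psdpharm.containers import GROUP_ADNP, GROUP_ADP

OUT = Path("results/differential")
COVARIATES = ["age", "pmi", "sex", "apoe4", "lewy_body", "log2_ptau"]


def main() -> None:
    pm = tsv.read_protein_matrix(Path("results/proteins") / "proteins.tsv")
    cohort = tsv.read_sample_meta(Path("results/data") / "cohort.tsv")

    spec = ContrastSpec("adp_vs_adnp", GROUP_ADP, GROUP_ADNP, COVARIATES)
    result = fit_contrast(pm, cohort, spec)
    t, df, p = global_shift_test(result)
    full_sig = build_signature(result, mode="full")
    top_sig = build_signature(result, mode="top", alpha=0.05)

    OUT.mkdir(parents=True, exist_ok=True)
    tsv.write_table(result, OUT / "adp_vs_adnp.tsv")
    tsv.write_signature(full_sig, OUT / "signature_full.tsv")
    tsv.write_signature(top_sig, OUT / "signature_top.tsv")
    tsv.write_json({"t": t, "df": df, "p": p}, OUT / "global_shift.json")

    nominal = de_set(result, alpha=0.05)
    adjusted = de_set(result, alpha=0.05, adjusted=True)
    print(f"proteins tested: {len(result)} "
          f"(n={result.attrs['n_a']} AD+P vs n={result.attrs['n_b']} AD-P)")
    print(f"global shift: t = {t:.1f}, df = {df}, p = {p:.3g}")
    print(f"nominally significant (p<0.05): {len(nominal)}; "
          f"BH-adjusted significant: {len(adjusted)}")
    print(f"signature sizes: full {len(full_sig)} "
          f"({(full_sig.sign < 0).mean():.0%} reduced), top {len(top_sig)}")


if __name__ == "__main__":
    main()
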