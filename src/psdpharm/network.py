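"""Interaction enrichment of differentially expressed proteins.

Given a protein-protein interaction edge list and a seed set (e.g. the
kinases recovered by functional annotation), tests whether differentially
expressed proteins are more likely than the background to interact with at
least one seed member, by a Pearson chi-square on the 2x2 table
{DE, non-DE} x {interacts, does not} without continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class InteractionGraph:
    """Undirected edge list with optional per-edge confidence score."""

    edges: pd.DataFrame  # columns protein_a, protein_b[, score]

    def __post_init__(self) -> None:
        if not {"protein_a", "protein_b"}.issubset(self.edges.columns):
            raise ValueError("edge table needs columns protein_a, protein_b")

    def filtered(self, min_score: float | None = None) -> pd.DataFrame:
        e = self.edges
        if min_score is not None and "score" in e.columns:
            e = e[e["score"] >= min_score]
        return e

    def partners_of(
        self, seed: set[str], min_score: float | None = None
    ) -> set[str]:
        """All proteins with >=1 edge to a seed member (self-loops ignored)."""
        e = self.filtered(min_score)
        a = e["protein_a"].to_numpy()
        b = e["protein_b"].to_numpy()
        not_self = a != b
        out: set[str] = set()
        out.update(b[not_self & np.isin(a, list(seed))])
        out.update(a[not_self & np.isin(b, list(seed))])
        return out


def chi_square_2x2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("empty table row")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        warnings.warn("expected cell count below 1; chi-square unreliable")
    return float(chi2), int(dof), float(p)


def interaction_enrichment(
    graph: InteractionGraph,
    seed: Iterable[str],
    de: Iterable[str],
    background: Iterable[str],
    min_score: float | None = None,
) -> dict:
    """Enrichment of seed interaction among DE proteins.

    ``background`` is the analyzed-protein universe; seed members are
    excluded from both DE and non-DE rows. Returns the 2x2 counts, the
    interacting proportions, chi-square, df and p.
    """
    seed = set(seed)
    bg = set(background) - seed
    de = (set(de) & bg) - seed
    non_de = bg - de
    if not de or not non_de:
        raise ValueError("DE and non-DE sets must both be non-empty")
    partners = graph.partners_of(seed, min_score=min_score)
    de_int = len(de & partners)
    nde_int = len(non_de & partners)
    table = np.array(
        [[de_int, len(de) - de_int], [nde_int, len(non_de) - nde_int]], dtype=float
    )
    chi2, dof, p = chi_square_2x2(table)
    return {
        "table": table,
        "chi2": chi2,
        "df": dof,
        "p": p,
        "prop_de": de_int / len(de),
        "prop_non_de": nde_int / len(non_de),
        "n_de": len(de),
        "n_non_de": len(non_de),
    }
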