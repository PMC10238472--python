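"""Core in-memory containers shared across the pipeline.

The quantitative substrate is a peptides x channels abundance table on the
linear scale (reporter-ion-like intensities), annotated with the multiplex
design: every channel belongs to one plex, and each plex carries two
pooled-control channels alongside 10-11 subject channels. Missing values are
NaN; raw input files encode missing as zero and are converted explicitly by
:func:`psdpharm.qc.zeros_to_missing`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

GROUP_ADP = "AD+P"
GROUP_ADNP = "AD-P"
GROUP_CN = "CN"


@dataclass
class PeptideMatrix:
    """Peptide-level abundance matrix plus multiplex annotations.

    Parameters
    ----------
    abundance
        peptides x channels, linear scale, NaN = missing. Columns are channel
        keys of the form ``"<plex>.<channel>"``.
    channel_meta
        One row per channel (index = channel key) with columns ``plex``,
        ``channel``, ``sample_id`` (NaN for pooled channels) and ``is_pooled``.
    pep2prot
        Mapping peptide id -> tuple of protein/gene ids (one or more).
    """

    abundance: pd.DataFrame
    channel_meta: pd.DataFrame
    pep2prot: pd.Series

    def __post_init__(self) -> None:
        if not self.abundance.columns.equals(self.channel_meta.index):
            # allow meta in any order but require the same channel set
            if set(self.abundance.columns) != set(self.channel_meta.index):
                raise ValueError("abundance columns and channel_meta index disagree")
            self.channel_meta = self.channel_meta.loc[self.abundance.columns]
        vals = self.abundance.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("abundance must be nonnegative where present")

    @property
    def peptides(self) -> pd.Index:
        return self.abundance.index

    @property
    def subject_channels(self) -> pd.Index:
        return self.channel_meta.index[~self.channel_meta["is_pooled"]]

    @property
    def pooled_channels(self) -> pd.Index:
        return self.channel_meta.index[self.channel_meta["is_pooled"]]

    @property
    def plexes(self) -> list[str]:
        return list(pd.unique(self.channel_meta["plex"]))

    def channels_in_plex(self, plex: str, pooled: bool | None = None) -> pd.Index:
        meta = self.channel_meta
        mask = meta["plex"] == plex
        if pooled is not None:
            mask &= meta["is_pooled"] == pooled
        return meta.index[mask]

    def sample_ids(self) -> pd.Series:
        """sample_id per subject channel (channel key -> sample id)."""
        return self.channel_meta.loc[self.subject_channels, "sample_id"]

    def with_abundance(self, abundance: pd.DataFrame) -> "PeptideMatrix":
        meta = self.channel_meta.loc[abundance.columns]
        p2p = self.pep2prot.loc[abundance.index]
        return PeptideMatrix(abundance=abundance, channel_meta=meta, pep2prot=p2p)

    def subset_peptides(self, peptides: Iterable[str]) -> "PeptideMatrix":
        idx = pd.Index(peptides)
        return PeptideMatrix(
            abundance=self.abundance.loc[idx],
            channel_meta=self.channel_meta,
            pep2prot=self.pep2prot.loc[idx],
        )

    def drop_channels(self, channels: Iterable[str]) -> "PeptideMatrix":
        drop = pd.Index(channels)
        keep = self.abundance.columns.difference(drop, sort=False)
        return PeptideMatrix(
            abundance=self.abundance[keep],
            channel_meta=self.channel_meta.loc[keep],
            pep2prot=self.pep2prot,
        )


@dataclass
class ProteinMatrix:
    """Rolled-up protein values (mean of peptide z-scores) per subject.

    ``values`` is proteins x subjects (sample ids as columns). Entries split
    out for uncorrelated peptides are named ``"<protein>|<peptide>"``.
    ``provenance`` records the contributing peptides per output row.
    """

    values: pd.DataFrame
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def proteins(self) -> pd.Index:
        return self.values.index


@dataclass
class SignedSignature:
    """Signed entity set: entity -> sign in {-1, +1}, optional magnitude.

    The common currency of disease, knockdown, LINCS and drug-effect
    signatures. Zero signs are disallowed (drop such entities upstream).
    """

    sign: pd.Series
    magnitude: pd.Series | None = None
    label: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        s = self.sign
        if s.index.has_duplicates:
            raise ValueError("signature entities must be unique")
        if len(s) and not np.isin(s.to_numpy(), [-1, 1]).all():
            raise ValueError("signs must be -1 or +1")
        self.sign = s.astype(int)
        if self.magnitude is not None:
            self.magnitude = self.magnitude.reindex(s.index)

    def __len__(self) -> int:
        return len(self.sign)

    @property
    def entities(self) -> pd.Index:
        return self.sign.index

    def values_for_correlation(self) -> pd.Series:
        """Signed magnitudes if available, else the bare signs."""
        if self.magnitude is not None:
            signed = self.magnitude * self.sign
            return signed.where(self.magnitude.notna(), self.sign.astype(float))
        return self.sign.astype(float)

    def restrict(self, entities: Iterable[str]) -> "SignedSignature":
        keep = self.entities.intersection(pd.Index(entities))
        mag = None if self.magnitude is None else self.magnitude.loc[keep]
        return replace(self, sign=self.sign.loc[keep], magnitude=mag)

    def flipped(self) -> "SignedSignature":
        return replace(self, sign=-self.sign, label=f"-({self.label})")


@dataclass
class KnockdownAtlas:
    """Long table of knockdown signatures: columns gene, entity, value.

    ``value`` is the signed transcriptome change of ``entity`` when ``gene``
    is silenced; sign(value) is the direction, |value| the magnitude.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "entity", "value"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"atlas table needs columns {sorted(required)}")
        if self.table.duplicated(["gene", "entity"]).any():
            raise ValueError("duplicate (gene, entity) rows in atlas")

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.table["gene"]))

    def signature(self, gene: str) -> SignedSignature:
        sub = self.table[self.table["gene"] == gene]
        vals = sub.set_index("entity")["value"].astype(float)
        vals = vals[vals != 0]
        return SignedSignature(
            sign=np.sign(vals).astype(int),
            magnitude=vals.abs(),
            label=f"knockdown:{gene}",
        )


@dataclass
class NormalizationReport:
    """Audit trail of the QC/normalization chain."""

    stages: list[str] = field(default_factory=list)
    removed_peptides: list[dict] = field(default_factory=list)
    flagged_outliers: list[str] = field(default_factory=list)
    missing_rate_per_channel: dict[str, float] = field(default_factory=dict)
    totals_before: dict[str, float] = field(default_factory=dict)
    totals_after: dict[str, float] = field(default_factory=dict)
    factors: dict[str, dict] = field(default_factory=dict)

    def record_stage(self, name: str) -> None:
        self.stages.append(name)

    def record_removed(self, peptides: Iterable[str], reason: str) -> None:
        if reason not in {"pooled-missing", "multi-mapped"}:
            raise ValueError(f"unknown removal reason {reason!r}")
        for p in peptides:
            self.removed_peptides.append({"peptide": str(p), "reason": reason})

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "removed_peptides": self.removed_peptides,
            "flagged_outliers": self.flagged_outliers,
            "missing_rate_per_channel": self.missing_rate_per_channel,
            "totals_before": self.totals_before,
            "totals_after": self.totals_after,
            "factors": self.factors,
        }
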