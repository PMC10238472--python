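"""Synthetic-data generators with known ground truth.

Emulates the study design end to end: a three-group postmortem cohort
(AD with psychosis, AD without psychosis, cognitively normal) assayed as
TMT-style plexes of 10-11 subjects plus two pooled-control channels; peptide
abundances with plex batch effects, covariate structure, zero-encoded
missingness and a global down-shift in a fraction ``pi_altered`` of proteins
in AD+P; reduced PSD yield in AD+P; knockdown-atlas and drug-target fixtures
for the pharmacology chain; and a two-arm drug-treatment experiment with a
partial reversal effect.

All generators are deterministic given ``SimulationConfig.rng_seed`` (or an
explicit ``rng``).

Model for a subject-channel log2 abundance of peptide p (protein g) in
subject s, plex b:

    y = baseline_g + offset_p + effect_p * 1[s in AD+P]
        + sum_c beta_c * (x_cs - mean(x_c)) + batch_{b,p} + N(0, log2_sd)

where effect_p = -log2(mean_ratio_altered) for peptides of altered proteins
(so AD+P is shifted DOWN), an independent discordant effect for designated
"uncorrelated" peptides, and 0 otherwise. Pooled-control channels carry the
across-subject mean of the true (noise-free) profile plus the plex batch
effect and a small independent noise. Values are exponentiated to the linear
scale and a configurable fraction is zeroed out (zero = missing downstream).
Equal protein amounts are labeled per channel, so PSD yield does NOT enter
the abundances; it lives in the sample metadata and is multiplied back in by
:func:`psdpharm.rollup.yield_adjust`, as in the study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    GROUP_ADNP,
    GROUP_ADP,
    GROUP_CN,
    KnockdownAtlas,
    PeptideMatrix,
    SignedSignature,
)

DEFAULT_COVARIATE_EFFECTS = {
    "age": -0.005,
    "pmi": 0.0,
    "sex": 0.05,
    "apoe4": 0.0,
    "lewy_body": 0.0,
    "log2_ptau": -0.02,
}

DEFAULT_YIELD_MEANS = {GROUP_ADP: 0.8, GROUP_ADNP: 1.0, GROUP_CN: 1.05}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: group sizes 59/47/19, plexes of
    10-11 subjects with 2 pooled channels, altered-protein fraction
    ``pi_altered`` with linear-scale mean group ratio 1.17 (AD+P lower),
    residual SD 1.0 on the log2 scale, and lower mean PSD yield in AD+P.
    """

    n_adp: int = 59
    n_adnp: int = 47
    n_cn: int = 19
    n_proteins: int = 300
    peptides_per_protein: tuple[int, int] = (1, 4)
    plex_size_min: int = 10
    plex_size_max: int = 11
    n_pooled_channels: int = 2
    pi_altered: float = 0.15
    mean_ratio_altered: float = 1.17
    log2_sd: float = 1.0
    missing_rate: float = 0.05
    missing_peptide_frac: float = 0.3
    batch_sd: float = 0.5
    yield_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_YIELD_MEANS)
    )
    yield_sd: float = 0.12
    frac_uncorrelated_peptides: float = 0.01
    uncorrelated_effect: float = 1.0
    frac_multimapped: float = 0.02
    covariate_effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    pooled_noise_sd: float = 0.1
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_adp", "n_adnp", "n_cn", "n_proteins"):
            if getattr(self, name) < 0 or (name == "n_proteins" and self.n_proteins <= 0):
                raise ValueError(f"{name} must be positive")
        for name in (
            "pi_altered",
            "missing_rate",
            "missing_peptide_frac",
            "frac_uncorrelated_peptides",
            "frac_multimapped",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mean_ratio_altered <= 0:
            raise ValueError("mean_ratio_altered must be > 0")
        if not (self.plex_size_min, self.plex_size_max) == (10, 11):
            if not (1 <= self.plex_size_min <= self.plex_size_max):
                raise ValueError("invalid plex size range")
        lo, hi = self.peptides_per_protein
        if not 1 <= lo <= hi:
            raise ValueError("invalid peptides_per_protein range")
        if self.n_pooled_channels < 1:
            raise ValueError("need at least one pooled channel per plex")

    @property
    def n_subjects(self) -> int:
        return self.n_adp + self.n_adnp + self.n_cn

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, *stream])


@dataclass
class GroundTruth:
    """What the generator injected, for parameter-recovery tests."""

    true_effect_per_protein: pd.Series  # log2 FC AD+P vs AD-P
    altered_set: set[str]
    uncorrelated_peptides: set[str]
    reversing_genes: list[str] = field(default_factory=list)
    reversing_drugs: list[str] = field(default_factory=list)


def _n_plexes(n_subjects: int, size_min: int, size_max: int) -> int:
    """Smallest plex count that partitions n into plexes of size_min..size_max."""
    k = math.ceil(n_subjects / size_max)
    if k == 0 or n_subjects < size_min * k:
        raise ValueError(
            f"{n_subjects} subjects cannot be partitioned into plexes of "
            f"{size_min}-{size_max}"
        )
    return k


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the cohort metadata and the plex layout.

    Returns one row per subject (index = sample id) with group label,
    covariates (age, PMI, sex, APOE*e4, Lewy body, phospho-tau area and its
    log2), PSD yield, and plex/channel assignment. Subjects are dealt to
    plexes round-robin within (group, sex) strata, so every plex is balanced
    for diagnosis and sex as in the block design.
    """
    config.validate()
    rng = config.rng(0)
    n = config.n_subjects
    k = _n_plexes(n, config.plex_size_min, config.plex_size_max)

    groups = (
        [GROUP_ADP] * config.n_adp
        + [GROUP_ADNP] * config.n_adnp
        + [GROUP_CN] * config.n_cn
    )
    meta = pd.DataFrame(
        {
            "group": groups,
            "sex": rng.integers(0, 2, size=n),  # 1 = male
            "age": rng.normal(84.0, 7.0, size=n).round(1),
            "pmi": np.maximum(rng.normal(7.0, 4.0, size=n), 1.0).round(2),
        },
        index=pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id"),
    )
    apoe_rate = {GROUP_ADP: 0.59, GROUP_ADNP: 0.53, GROUP_CN: 0.16}
    lewy_rate = {GROUP_ADP: 0.30, GROUP_ADNP: 0.25, GROUP_CN: 0.05}
    meta["apoe4"] = (
        rng.random(n) < meta["group"].map(apoe_rate).to_numpy()
    ).astype(int)
    meta["lewy_body"] = (
        rng.random(n) < meta["group"].map(lewy_rate).to_numpy()
    ).astype(int)
    # phospho-tau area fraction: lognormal, entered into models as log2
    meta["ptau_area"] = np.exp(rng.normal(-3.0, 0.6, size=n))
    meta["log2_ptau"] = np.log2(meta["ptau_area"])
    mu = meta["group"].map(config.yield_means).to_numpy()
    meta["psd_yield"] = np.maximum(rng.normal(mu, config.yield_sd), 0.05)

    # deal to plexes round-robin within (group, sex) strata; the running
    # cursor carries across strata so plex sizes end up floor/ceil(n/k)
    order: list[str] = []
    for (_, _), sub in meta.groupby(["group", "sex"], sort=True):
        ids = list(sub.index)
        rng.shuffle(ids)
        order.extend(ids)
    plex_of: dict[str, int] = {}
    counts = [0] * k
    cursor = 0
    for sid in order:
        plex_of[sid] = cursor % k
        counts[cursor % k] += 1
        cursor += 1
    meta["plex"] = [f"P{plex_of[s] + 1:02d}" for s in meta.index]
    sizes = meta["plex"].value_counts()
    if not sizes.between(config.plex_size_min, config.plex_size_max).all():
        raise ValueError("plex assignment produced out-of-range plex sizes")
    # channel numbers within plex; pooled channels use the last slots
    # (channels 12 and 13 in the study's labeling scheme)
    chan = meta.groupby("plex").cumcount() + 1
    meta["channel"] = [f"C{c:02d}" for c in chan]
    return meta


def _pooled_channel_meta(cohort: pd.DataFrame, n_pooled: int) -> pd.DataFrame:
    """Channel metadata rows for subjects plus pooled controls."""
    subj = pd.DataFrame(
        {
            "plex": cohort["plex"].to_numpy(),
            "channel": cohort["channel"].to_numpy(),
            "sample_id": cohort.index.to_numpy(),
            "is_pooled": False,
        },
        index=pd.Index(
            cohort["plex"].str.cat(cohort["channel"], sep="."), name="channel_key"
        ),
    )
    rows = []
    for plex in pd.unique(cohort["plex"]):
        for j in range(n_pooled):
            ch = f"C{12 + j:02d}"
            rows.append((f"{plex}.{ch}", plex, ch, np.nan, True))
    pooled = pd.DataFrame(
        rows, columns=["channel_key", "plex", "channel", "sample_id", "is_pooled"]
    ).set_index("channel_key")
    return pd.concat([subj, pooled])


def generate_peptide_data(
    config: SimulationConfig, cohort: pd.DataFrame
) -> tuple[PeptideMatrix, GroundTruth]:
    """Simulate the multiplexed peptide abundance matrix.

    See the module docstring for the generative model. Returns the matrix
    (zeros encode missing values, as in exported reporter-ion tables) and the
    injected ground truth.
    """
    config.validate()
    rng = config.rng(1)
    lo, hi = config.peptides_per_protein
    n_pep_per = rng.integers(lo, hi + 1, size=config.n_proteins)
    proteins = np.repeat(
        [f"PROT{i + 1:04d}" for i in range(config.n_proteins)], n_pep_per
    )
    n_pep = len(proteins)
    peptides = pd.Index([f"PEP{i + 1:06d}" for i in range(n_pep)], name="peptide")
    mappings = [(p,) for p in proteins]
    # a small fraction of peptides map ambiguously to a second protein;
    # QC removes them before roll-up
    n_multi = round(config.frac_multimapped * n_pep)
    if n_multi and config.n_proteins > 1:
        for i in rng.choice(n_pep, size=n_multi, replace=False):
            other = f"PROT{int(rng.integers(config.n_proteins)) + 1:04d}"
            if other == mappings[i][0]:
                other = f"PROT{(int(other[4:]) % config.n_proteins) + 1:04d}"
            mappings[i] = (mappings[i][0], other)
    pep2prot = pd.Series(mappings, index=peptides)

    protein_ids = [f"PROT{i + 1:04d}" for i in range(config.n_proteins)]
    n_altered = round(config.pi_altered * config.n_proteins)
    altered = set(rng.choice(protein_ids, size=n_altered, replace=False))
    effect_per_protein = pd.Series(0.0, index=pd.Index(protein_ids, name="protein"))
    effect_per_protein[list(altered)] = -np.log2(config.mean_ratio_altered)

    # discordant ("uncorrelated") peptides: only peptides of multi-peptide
    # proteins are eligible; they get an independent opposite-direction effect
    multi = pd.Series(n_pep_per, index=protein_ids)[proteins].to_numpy() >= 2
    single_mapped = (pep2prot.map(len) == 1).to_numpy()
    eligible = peptides[multi & single_mapped]
    n_uncorr = min(round(config.frac_uncorrelated_peptides * n_pep), len(eligible))
    uncorr = set(rng.choice(eligible, size=n_uncorr, replace=False)) if n_uncorr else set()

    pep_effect = effect_per_protein[proteins].to_numpy().copy()
    is_uncorr = peptides.isin(list(uncorr))
    pep_effect[is_uncorr] = config.uncorrelated_effect

    baseline = rng.normal(10.0, 2.0, size=config.n_proteins)
    pep_base = baseline[np.repeat(np.arange(config.n_proteins), n_pep_per)]
    pep_base = pep_base + rng.normal(0.0, 1.0, size=n_pep)

    is_adp = (cohort["group"] == GROUP_ADP).to_numpy().astype(float)
    cov_term = np.zeros(len(cohort))
    for cov, beta in config.covariate_effect_sizes.items():
        if beta == 0.0 or cov not in cohort.columns:
            continue
        x = cohort[cov].to_numpy(dtype=float)
        cov_term += beta * (x - x.mean())

    plexes = list(pd.unique(cohort["plex"]))
    batch = rng.normal(0.0, config.batch_sd, size=(len(plexes), n_pep))
    plex_idx = {p: i for i, p in enumerate(plexes)}
    subj_batch = batch[[plex_idx[p] for p in cohort["plex"]], :].T  # pep x subj

    true_subj = (
        pep_base[:, None]
        + np.outer(pep_effect, is_adp)
        + cov_term[None, :]
    )
    log2_subj = true_subj + subj_batch + rng.normal(
        0.0, config.log2_sd, size=(n_pep, len(cohort))
    )

    # pooled controls: all-subject average of the true profile + batch + noise
    pooled_true = true_subj.mean(axis=1)
    meta = _pooled_channel_meta(cohort, config.n_pooled_channels)
    pooled_keys = meta.index[meta["is_pooled"]]
    pooled_cols = np.empty((n_pep, len(pooled_keys)))
    for j, key in enumerate(pooled_keys):
        b = batch[plex_idx[meta.loc[key, "plex"]], :]
        pooled_cols[:, j] = pooled_true + b + rng.normal(
            0.0, config.pooled_noise_sd, size=n_pep
        )

    subj_keys = meta.index[~meta["is_pooled"]]
    log2_all = np.concatenate([log2_subj, pooled_cols], axis=1)
    abundance = pd.DataFrame(
        np.exp2(log2_all),
        index=peptides,
        columns=subj_keys.append(pooled_keys),
    )

    if config.missing_rate > 0:
        frac = max(config.missing_peptide_frac, config.missing_rate)
        n_spotty = round(frac * n_pep)
        spotty = rng.choice(n_pep, size=n_spotty, replace=False)
        p_entry = min(config.missing_rate / frac, 1.0)
        mask = rng.random((n_spotty, abundance.shape[1])) < p_entry
        vals = abundance.to_numpy()
        for r, row_mask in zip(spotty, mask):
            vals[r, row_mask] = 0.0
        abundance = pd.DataFrame(vals, index=abundance.index, columns=abundance.columns)

    matrix = PeptideMatrix(
        abundance=abundance, channel_meta=meta.loc[abundance.columns], pep2prot=pep2prot
    )
    truth = GroundTruth(
        true_effect_per_protein=effect_per_protein,
        altered_set=altered,
        uncorrelated_peptides=uncorr,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# pharmacology fixtures


def generate_pharmacology_fixtures(
    config: SimulationConfig,
    truth: GroundTruth,
    disease_sig: SignedSignature,
    top_entities: Sequence[str] | None = None,
    n_null_genes: int = 5,
    atlas_noise_sd: float = 0.3,
) -> tuple[KnockdownAtlas, pd.DataFrame, pd.DataFrame]:
    """Build knockdown-atlas, drug-target and LINCS-style fixtures.

    The atlas contains: two reversing genes (sign-flipped disease signature
    plus noise), one recapitulating gene (same sign), one subset-inconsistent
    gene that tracks the disease signature off the top subset but opposes it
    on the top subset (the MTOR-style case), and ``n_null_genes`` null genes
    (permuted magnitudes). The drug table wires drugs to these genes with
    actions exercising the nomination rules; the LINCS table gives the
    designated reversing drug CNS profiles opposing the disease signature,
    plus rows that the dose/cell-line filters must exclude.
    """
    if len(disease_sig) == 0:
        raise ValueError("disease signature is empty")
    rng = config.rng(2)
    mags = disease_sig.values_for_correlation().astype(float)
    entities = disease_sig.entities
    if top_entities is None:
        k = max(5, round(0.15 * len(entities)))
        top_entities = mags.abs().sort_values(ascending=False).index[:k]
    top_mask = entities.isin(pd.Index(top_entities))

    scale = float(mags.abs().mean()) or 1.0
    noise = lambda: rng.normal(0.0, atlas_noise_sd * scale, size=len(entities))

    rows = []

    def add_gene(gene: str, values: np.ndarray) -> None:
        for e, v in zip(entities, values):
            if v != 0:
                rows.append((gene, e, float(v)))

    add_gene("GENE_REV1", -mags.to_numpy() + noise())
    add_gene("GENE_REV2", -mags.to_numpy() + noise())
    add_gene("GENE_RECAP", mags.to_numpy() + noise())
    # MTOR-style subset inconsistency: aligned with the disease signature off
    # the top subset, but ordered OPPOSITELY within the top subset around a
    # mid-level offset (so its overall rank correlation stays positive while
    # the top-subset correlation is negative)
    mvec = mags.to_numpy().copy()
    mt = mvec[top_mask]
    mvec[top_mask] = mags.mean() - 3.0 * (mt - mt.mean())
    add_gene("GENE_MTORLIKE", mvec + noise())
    for i in range(n_null_genes):
        add_gene(f"GENE_NULL{i + 1}", rng.permutation(mags.to_numpy()))
    atlas = KnockdownAtlas(pd.DataFrame(rows, columns=["gene", "entity", "value"]))

    drugs = pd.DataFrame(
        [
            ("reversodil", "GENE_REV1", "antagonist"),
            ("fostamet", "GENE_REV2", "inhibitor"),
            ("recaptor", "GENE_RECAP", "potentiator"),
            ("mtoractin", "GENE_MTORLIKE", "potentiator"),
            ("decoyzol", "GENE_NULL1", "inhibitor"),
            ("wrongwayol", "GENE_REV1", "potentiator"),
        ],
        columns=["drug", "gene", "action"],
    )

    lincs_rows = []
    covered = rng.random(len(entities)) < 0.7
    for cell, cns in (("NEU1", True), ("GLIA2", True), ("HEPG9", False)):
        for e, m, c in zip(entities, mags, covered):
            if not c:
                continue
            z = -np.sign(m) * (1.5 + abs(rng.normal(0.0, 0.3)))
            lincs_rows.append(("reversodil", e, float(z), cell, cns, 10.0))
            # low-dose rows must be excluded by the dose filter
            lincs_rows.append(("reversodil", e, float(-z), cell, cns, 0.1))
    # a drug tested only outside the CNS ("not tested in CNS cells" status)
    for e in entities[:10]:
        lincs_rows.append(("peripherol", e, 2.0, "HEPG9", False, 10.0))
    lincs = pd.DataFrame(
        lincs_rows, columns=["drug", "gene", "z", "cell_line", "is_cns", "dose_um"]
    )

    truth.reversing_genes = ["GENE_REV1", "GENE_REV2"]
    truth.reversing_drugs = ["reversodil", "fostamet"]
    return atlas, drugs, lincs


# ---------------------------------------------------------------------------
# drug-treatment (maraviroc-style) experiment


def generate_treatment_experiment(
    config: SimulationConfig,
    disease_sig: SignedSignature,
    n_treated: int = 6,
    n_vehicle: int = 6,
    reversal_fraction: float = 0.6,
    reversal_strength: float = 1.0,
    noise_sd: float = 0.3,
    extra_proteins: int = 30,
    include_outlier: bool = False,
    outlier_yield: float = 0.35,
    normal_yield: float = 1.31,
) -> tuple[PeptideMatrix, pd.DataFrame]:
    """Simulate a two-arm (treated vs vehicle) proteomics experiment.

    Treated samples receive a log2 shift opposing the disease sign on a
    ``reversal_fraction`` subset of signature proteins, scaled by the disease
    magnitude (stronger reversal where the disease effect was larger, as the
    in-vivo validation showed). Optionally one treated sample is a low-yield
    outlier whose abundances are scaled down accordingly.

    Returns the peptide matrix (single plex, two pooled channels) and a
    per-sample metadata frame with ``arm`` and ``psd_yield``.
    """
    if len(disease_sig) == 0:
        raise ValueError("disease signature is empty")
    rng = config.rng(3)
    sig_prot = list(disease_sig.entities)
    proteins = sig_prot + [f"XPROT{i + 1:04d}" for i in range(extra_proteins)]
    n_prot = len(proteins)
    peptides = pd.Index([f"MPEP{i + 1:06d}" for i in range(n_prot)], name="peptide")
    pep2prot = pd.Series([(p,) for p in proteins], index=peptides)

    n = n_treated + n_vehicle
    sample_ids = [f"M{i + 1:02d}" for i in range(n)]
    arm = ["treated"] * n_treated + ["vehicle"] * n_vehicle
    meta = pd.DataFrame(
        {"arm": arm, "psd_yield": np.maximum(rng.normal(normal_yield, 0.1, n), 0.05)},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    mags = disease_sig.values_for_correlation().abs().reindex(sig_prot).fillna(0.0)
    shift = np.zeros(n_prot)
    n_rev = round(reversal_fraction * len(sig_prot))
    rev_idx = rng.choice(len(sig_prot), size=n_rev, replace=False)
    signs = disease_sig.sign.reindex(sig_prot).to_numpy(dtype=float)
    shift[rev_idx] = (
        -signs[rev_idx] * reversal_strength * np.maximum(mags.to_numpy()[rev_idx], 1e-6)
    )

    base = rng.normal(10.0, 2.0, size=n_prot)
    is_treated = np.array([a == "treated" for a in arm], dtype=float)
    log2_subj = (
        base[:, None]
        + np.outer(shift, is_treated)
        + rng.normal(0.0, noise_sd, size=(n_prot, n))
    )
    pooled = base[:, None] + rng.normal(0.0, 0.05, size=(n_prot, 2))
    vals = np.exp2(np.concatenate([log2_subj, pooled], axis=1))

    if include_outlier:
        meta.loc[sample_ids[0], "psd_yield"] = outlier_yield
        vals[:, 0] *= outlier_yield / normal_yield

    channels = [f"C{i + 1:02d}" for i in range(n + 2)]  # last two are pooled
    channel_meta = pd.DataFrame(
        {
            "plex": "P01",
            "channel": channels,
            "sample_id": sample_ids + [np.nan, np.nan],
            "is_pooled": [False] * n + [True, True],
        },
        index=pd.Index([f"P01.{c}" for c in channels], name="channel_key"),
    )
    abundance = pd.DataFrame(vals, index=peptides, columns=channel_meta.index)
    return (
        PeptideMatrix(abundance=abundance, channel_meta=channel_meta, pep2prot=pep2prot),
        meta,
    )
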