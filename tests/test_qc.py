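"""QC/normalization operations: hand-computable cases and invariants."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_matrix
from psdpharm import SimulationConfig, generate_cohort, generate_peptide_data
from psdpharm import qc
from psdpharm.containers import NormalizationReport

SINGLE_PLEX = [
    ("P1.C01", "P1", "S1"),
    ("P1.C02", "P1", "S2"),
    ("P1.C12", "P1", None),
    ("P1.C13", "P1", None),
]


class TestZerosToMissing:
    def test_no_zeros_identity(self):
        m = build_matrix([[1.0, 2.0, 3.0, 4.0]], SINGLE_PLEX)
        out = qc.zeros_to_missing(m)
        pd.testing.assert_frame_equal(out.abundance, m.abundance)

    def test_threshold_is_exact_zero(self):
        m = build_matrix([[0.0, 0.0001, 1.0, 2.0]], SINGLE_PLEX)
        out = qc.zeros_to_missing(m)
        assert np.isnan(out.abundance.iloc[0, 0])
        assert out.abundance.iloc[0, 1] == 0.0001

    def test_all_zero_matrix_retains_nothing_downstream(self):
        m = build_matrix(np.zeros((3, 4)), SINGLE_PLEX)
        out = qc.zeros_to_missing(m)
        assert out.abundance.isna().all().all()
        kept = qc.present_call_filter(out, 1.0)
        assert len(kept.peptides) == 0

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            build_matrix([[-1.0, 1.0, 1.0, 1.0]], SINGLE_PLEX)


class TestLoadingNormalization:
    def test_hand_factors(self):
        channels = SINGLE_PLEX[:2]
        m = build_matrix([[40.0, 100.0], [60.0, 200.0]], channels)
        out = qc.sample_loading_normalize(m)
        totals = out.abundance.sum(axis=0)
        assert np.allclose(totals, 200.0)
        assert np.allclose(out.abundance["P1.C01"], [80.0, 120.0])

    def test_equal_totals_unchanged(self):
        m = build_matrix([[1.0, 2.0], [3.0, 2.0]], SINGLE_PLEX[:2])
        out = qc.sample_loading_normalize(m)
        pd.testing.assert_frame_equal(out.abundance, m.abundance)

    def test_missing_excluded_from_totals(self):
        m = build_matrix([[10.0, 5.0], [np.nan, 5.0]], SINGLE_PLEX[:2])
        out = qc.sample_loading_normalize(m)
        pd.testing.assert_frame_equal(out.abundance, m.abundance)

    def test_all_missing_channel_raises(self):
        m = build_matrix([[np.nan, 1.0]], SINGLE_PLEX[:2])
        with pytest.raises(ValueError, match="P1.C01"):
            qc.sample_loading_normalize(m)


def plexes(n, pooled_missing_in):
    """n plexes x 1 peptide; pooled channels NaN in the given plexes."""
    channels, row = [], []
    for i in range(1, n + 1):
        channels += [
            (f"P{i}.C01", f"P{i}", f"S{i}"),
            (f"P{i}.C12", f"P{i}", None),
            (f"P{i}.C13", f"P{i}", None),
        ]
        miss = i in pooled_missing_in
        row += [1.0, np.nan if miss else 1.0, np.nan if miss else 1.0]
    return build_matrix([row], channels)


class TestPooledMissingFilter:
    def test_removed_at_half(self):
        m = plexes(4, pooled_missing_in={1, 2})
        kept, removed = qc.filter_pooled_missing(m)
        assert removed == ["pep1"]
        assert len(kept.peptides) == 0

    def test_single_pooled_channel_present_retains(self):
        channels, row = [], []
        for i in range(1, 5):
            channels += [
                (f"P{i}.C12", f"P{i}", None),
                (f"P{i}.C13", f"P{i}", None),
                (f"P{i}.C01", f"P{i}", f"S{i}"),
            ]
            row += [np.nan, 1.0, 1.0]  # only one pooled channel missing
        m = build_matrix([row], channels)
        kept, removed = qc.filter_pooled_missing(m)
        assert removed == []
        assert list(kept.peptides) == ["pep1"]

    def test_below_half_retained(self):
        m = plexes(3, pooled_missing_in={1})
        kept, removed = qc.filter_pooled_missing(m)
        assert removed == []

    def test_plex_without_pooled_raises(self):
        m = build_matrix([[1.0, 2.0]], [("P1.C01", "P1", "S1"), ("P1.C02", "P1", "S2")])
        with pytest.raises(ValueError, match="pooled"):
            qc.filter_pooled_missing(m)


class TestMultimapped:
    def test_multi_removed_single_kept(self):
        m = build_matrix(
            np.ones((3, 4)),
            SINGLE_PLEX,
            peptides=["a", "b", "c"],
            pep2prot={"a": ("P1",), "b": ("P1", "P2"), "c": ("P3",)},
        )
        kept, removed = qc.drop_multimapped(m)
        assert removed == ["b"]
        assert list(kept.peptides) == ["a", "c"]
        assert kept.pep2prot.map(len).eq(1).all()

    def test_removal_report(self):
        peptides = [f"p{i}" for i in range(10)]
        p2p = {p: ("G1", "G2") if i < 3 else (f"G{i}",) for i, p in enumerate(peptides)}
        m = build_matrix(np.ones((10, 4)), SINGLE_PLEX, peptides=peptides, pep2prot=p2p)
        report = NormalizationReport()
        kept, removed = qc.drop_multimapped(m, report)
        assert len(kept.peptides) == 7
        assert len(removed) == 3
        assert all(r["reason"] == "multi-mapped" for r in report.removed_peptides)

    def test_zero_mapping_raises(self):
        m = build_matrix([[1.0] * 4], SINGLE_PLEX, peptides=["a"], pep2prot={"a": ()})
        with pytest.raises(ValueError, match="no protein mapping"):
            qc.drop_multimapped(m)


class TestOutlierDetection:
    def _matrix(self, totals):
        channels = [(f"P1.C{i + 1:02d}", "P1", f"S{i + 1}") for i in range(len(totals))]
        return build_matrix([list(totals)], channels)

    def test_equal_totals_no_flags(self):
        assert qc.detect_outlier_samples(self._matrix([5.0] * 11)) == []

    def test_low_yield_sample_flagged(self):
        # one sample with roughly a quarter of the typical total abundance
        rng = np.random.default_rng(0)
        totals = list(1.31 + rng.normal(0, 0.05, 10)) + [0.35]
        m = self._matrix(totals)
        assert qc.detect_outlier_samples(m, k=3.0) == ["P1.C11"]

    def test_infinite_k_never_flags(self):
        m = self._matrix([1.0, 5.0, 100.0, 2.0])
        assert qc.detect_outlier_samples(m, k=np.inf) == []

    def test_pooled_never_flagged(self):
        channels = SINGLE_PLEX + [("P1.C03", "P1", "S3")]
        m = build_matrix([[5.0, 5.0, 0.001, 0.001, 5.0]], channels)
        assert qc.detect_outlier_samples(m, k=3.0) == []


class TestIRS:
    def test_hand_example(self, two_plex_matrix):
        out = qc.irs_normalize(two_plex_matrix)
        # peptide 1: pooled plex1 (100,120), plex2 (200,220) -> overall 160
        p1 = out.abundance.loc["pep1", ["P1.C12", "P1.C13"]].mean()
        p2 = out.abundance.loc["pep1", ["P2.C12", "P2.C13"]].mean()
        assert p1 == pytest.approx(160.0, rel=1e-12)
        assert p2 == pytest.approx(160.0, rel=1e-12)
        # subject channels scaled by the same plex factor
        assert out.abundance.loc["pep1", "P1.C01"] == pytest.approx(90 * 160 / 110)

    def test_single_plex_unchanged(self):
        m = build_matrix([[90.0, 110.0, 100.0, 120.0]], SINGLE_PLEX)
        out = qc.irs_normalize(m)
        pd.testing.assert_frame_equal(out.abundance, m.abundance)

    def test_undefined_factor_sets_plex_missing(self, two_plex_matrix):
        ab = two_plex_matrix.abundance.copy()
        ab.loc["pep1", ["P2.C12", "P2.C13"]] = np.nan
        m = two_plex_matrix.with_abundance(ab)
        out = qc.irs_normalize(m)
        assert out.abundance.loc["pep1", ["P2.C01", "P2.C02"]].isna().all()
        assert out.abundance.loc["pep2"].notna().all()

    def test_removes_batch_effect_from_pooled_channels(self):
        cfg = SimulationConfig(n_proteins=40, batch_sd=1.0, missing_rate=0.0,
                               n_adp=22, n_adnp=22, n_cn=0)
        cohort = generate_cohort(cfg)
        m, _ = generate_peptide_data(cfg, cohort)
        out = qc.irs_normalize(qc.zeros_to_missing(m))
        plex_means = pd.concat(
            {
                plex: out.abundance[out.channels_in_plex(plex, pooled=True)].mean(axis=1)
                for plex in out.plexes
            },
            axis=1,
        )
        rel_spread = plex_means.max(axis=1) / plex_means.min(axis=1) - 1
        assert rel_spread.max() < 1e-9


class TestMedianNormalize:
    def test_hand_factors(self):
        channels = SINGLE_PLEX[:2]
        m = build_matrix([[5.0, 20.0], [10.0, 40.0], [15.0, 60.0]], channels)
        out = qc.median_normalize(m)
        # channel medians 10 and 40; overall median of all six values = 17.5
        target = np.median([5, 20, 10, 40, 15, 60])
        assert np.allclose(out.abundance.median(axis=0), target)
        assert np.allclose(out.abundance["P1.C01"], np.array([5, 10, 15]) * target / 10)

    def test_equal_medians_unchanged(self):
        m = build_matrix([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]], SINGLE_PLEX[:2])
        out = qc.median_normalize(m)
        pd.testing.assert_frame_equal(out.abundance, m.abundance)

    def test_preserves_rank_order(self):
        rng = np.random.default_rng(1)
        m = build_matrix(rng.uniform(1, 100, (20, 4)), SINGLE_PLEX)
        out = qc.median_normalize(m)
        for col in m.abundance.columns:
            a = m.abundance[col].rank()
            b = out.abundance[col].rank()
            pd.testing.assert_series_equal(a, b)


class TestPresentCall:
    def test_fraction_arithmetic(self):
        channels = [(f"P1.C{i + 1:02d}", "P1", f"S{i + 1}") for i in range(4)]
        ab = np.array([[1.0, 1, 1, 1], [1, 1, np.nan, np.nan], [1, np.nan, np.nan, np.nan]])
        m = build_matrix(ab, channels)
        assert len(qc.present_call_filter(m, 1.0).peptides) == 1
        assert len(qc.present_call_filter(m, 0.5).peptides) == 2
        assert len(qc.present_call_filter(m, 0.25).peptides) == 3

    def test_identity_without_missing(self):
        m = build_matrix(np.ones((5, 4)), SINGLE_PLEX)
        out = qc.present_call_filter(m, 1.0)
        pd.testing.assert_frame_equal(out.abundance, m.abundance)

    def test_pooled_excluded_from_denominator(self):
        # present in all subjects but missing in pooled: still 100% present
        m = build_matrix([[1.0, 1.0, np.nan, np.nan]], SINGLE_PLEX)
        assert len(qc.present_call_filter(m, 1.0).peptides) == 1

    def test_bad_threshold(self):
        m = build_matrix([[1.0] * 4], SINGLE_PLEX)
        with pytest.raises(ValueError):
            qc.present_call_filter(m, 0.0)


class TestChainInvariants:
    def test_stage_order_recorded(self):
        cfg = SimulationConfig(n_proteins=30, n_adp=22, n_adnp=22, n_cn=0)
        cohort = generate_cohort(cfg)
        m, _ = generate_peptide_data(cfg, cohort)
        _, report = qc.normalize_pipeline(m)
        assert report.stages[:7] == qc.PIPELINE_ORDER

    def test_scaling_preserves_within_channel_ratios(self):
        rng = np.random.default_rng(7)
        m = build_matrix(rng.uniform(1, 50, (10, 4)), SINGLE_PLEX)
        for op in (qc.sample_loading_normalize, qc.median_normalize):
            out = op(m)
            ratio_before = m.abundance.iloc[0] / m.abundance.iloc[1]
            ratio_after = out.abundance.iloc[0] / out.abundance.iloc[1]
            pd.testing.assert_series_equal(ratio_before, ratio_after)
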