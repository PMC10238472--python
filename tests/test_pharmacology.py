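"""Signature building, knockdown screening, nomination, LINCS, Signed Jaccard."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psdpharm import (
    SignedSignature,
    build_signature,
    correlate_knockdown,
    lincs_signature,
    nominate_drugs,
    signed_jaccard,
    subset_consistency_filter,
)
from psdpharm.containers import KnockdownAtlas


def sig(mapping, label="s"):
    signs = pd.Series({k: np.sign(v) for k, v in mapping.items()}).astype(int)
    mags = pd.Series({k: abs(v) for k, v in mapping.items()})
    return SignedSignature(sign=signs, magnitude=mags, label=label)


def atlas_from(genes: dict[str, dict[str, float]]) -> KnockdownAtlas:
    rows = [
        (g, e, v) for g, mapping in genes.items() for e, v in mapping.items()
    ]
    return KnockdownAtlas(pd.DataFrame(rows, columns=["gene", "entity", "value"]))


class TestBuildSignature:
    def _result(self):
        return pd.DataFrame(
            {
                "log2fc": [-0.2, 0.1, 0.0, -0.4],
                "p": [0.01, 0.2, 0.5, 0.03],
                "p_adj": [0.04, 0.4, 0.7, 0.06],
            },
            index=["G1", "G2", "G3", "G4"],
        )

    def test_full_mode_signs(self):
        with pytest.warns(UserWarning, match="zero-log2FC"):
            s = build_signature(self._result(), mode="full")
        assert s.sign.to_dict() == {"G1": -1, "G2": 1, "G4": -1}

    def test_top_mode_filters_by_raw_p(self):
        s = build_signature(self._result(), mode="top", alpha=0.05)
        assert set(s.entities) == {"G1", "G4"}

    def test_top_size_matches_nominal_de_count(self):
        rng = np.random.default_rng(0)
        n = 1613
        p = np.concatenate([rng.uniform(0, 0.05, 240), rng.uniform(0.05, 1, n - 240)])
        res = pd.DataFrame(
            {"log2fc": -np.abs(rng.normal(0.2, 0.05, n)), "p": p, "p_adj": p},
            index=[f"G{i}" for i in range(n)],
        )
        s = build_signature(res, mode="top", alpha=0.05)
        assert len(s) == 240


class TestCorrelateKnockdown:
    def _disease(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 0.3, n)
        vals[vals == 0] = 0.1
        return sig({f"G{i}": v for i, v in enumerate(vals)}, label="disease")

    def test_exact_flip_rho_minus_one(self):
        d = self._disease()
        vals = d.values_for_correlation()
        atlas = atlas_from({"kd": (-vals).to_dict()})
        out = correlate_knockdown(atlas, d)
        assert out.loc["kd", "rho"] == pytest.approx(-1.0)

    def test_identity_rho_plus_one(self):
        d = self._disease()
        atlas = atlas_from({"kd": d.values_for_correlation().to_dict()})
        out = correlate_knockdown(atlas, d)
        assert out.loc["kd", "rho"] == pytest.approx(1.0)

    def test_null_mean_rho_near_zero(self):
        d = self._disease(n=50, seed=987)
        rhos = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            vals = rng.normal(0, 1, 50)
            atlas = atlas_from({"kd": {f"G{i}": v for i, v in enumerate(vals)}})
            rhos.append(correlate_knockdown(atlas, d).loc["kd", "rho"])
        se = np.std(rhos, ddof=1) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * se

    def test_min_shared_skip(self):
        d = self._disease(n=30)
        atlas = atlas_from({"kd": {"G0": 1.0, "G1": -1.0}})
        out = correlate_knockdown(atlas, d, min_shared=10)
        assert out.loc["kd", "skipped"] == "too-few-shared"
        assert np.isnan(out.loc["kd", "rho"])


class TestNominate:
    def _corr(self, rho, p=1e-4):
        return pd.DataFrame(
            {"rho": [rho], "p": [p], "n_shared": [100], "sign": [np.sign(rho)],
             "skipped": [""]},
            index=pd.Index(["GENE"], name="gene"),
        )

    def _drugs(self, action):
        return pd.DataFrame(
            [("drugx", "GENE", action)], columns=["drug", "gene", "action"]
        )

    @pytest.mark.parametrize(
        "rho,action,expected",
        [
            (-0.4, "antagonist", True),   # the maraviroc/CCR5 pattern
            (-0.4, "inhibitor", True),
            (-0.4, "potentiator", False),
            (+0.4, "potentiator", True),  # the pimecrolimus/MTOR pattern
            (+0.4, "agonist", True),
            (+0.4, "antagonist", False),
        ],
    )
    def test_action_alignment_rules(self, rho, action, expected):
        out = nominate_drugs(self._corr(rho), self._drugs(action))
        assert (len(out) == 1) is expected

    def test_insignificant_correlation_not_nominated(self):
        out = nominate_drugs(self._corr(-0.4, p=0.5), self._drugs("antagonist"))
        assert out.empty

    def test_unknown_action_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="unknown action"):
            out = nominate_drugs(self._corr(-0.4), self._drugs("mystery"))
        assert out.empty

    def test_action_alias_normalization(self):
        out = nominate_drugs(self._corr(-0.4), self._drugs("Blocker"))
        assert len(out) == 1
        assert out["action"].iloc[0] == "antagonist"


class TestSubsetConsistency:
    def _setup(self, top_vals):
        full_entities = {f"G{i}": -0.2 - 0.01 * i for i in range(20)}
        full = sig(full_entities, "full")
        top = sig({k: full_entities[k] for k in list(full_entities)[:12]}, "top")
        atlas = atlas_from({"GENE": top_vals})
        cand = pd.DataFrame(
            [("drugx", "GENE", "antagonist", -0.3, 1e-4, "rule")],
            columns=["drug", "gene", "action", "rho", "rho_p", "rule"],
        )
        return atlas, full, top, cand

    def test_sign_flip_dropped(self):
        # knockdown aligned with disease on the top subset (positive rho_top)
        # while the full-signature rho was negative -> excluded
        vals = {f"G{i}": -0.2 - 0.01 * i for i in range(12)}
        atlas, full, top, cand = self._setup(vals)
        out = subset_consistency_filter(atlas, full, top, cand, min_shared=5)
        assert out.empty

    def test_consistent_sign_retained(self):
        vals = {f"G{i}": 0.2 + 0.01 * i for i in range(12)}
        atlas, full, top, cand = self._setup(vals)
        out = subset_consistency_filter(atlas, full, top, cand, min_shared=5)
        assert len(out) == 1
        assert out["subset_consistent"].iloc[0] == "consistent"
        assert out["rho_top"].iloc[0] < 0

    def test_untestable_retained_with_flag(self):
        atlas, full, top, cand = self._setup({"G0": -0.2, "G1": -0.21})
        out = subset_consistency_filter(atlas, full, top, cand, min_shared=5)
        assert len(out) == 1
        assert out["subset_consistent"].iloc[0] == "untestable"


class TestLincs:
    def _profiles(self, rows):
        return pd.DataFrame(
            rows, columns=["drug", "gene", "z", "cell_line", "is_cns", "dose_um"]
        )

    def test_mean_z_threshold(self):
        prof = self._profiles(
            [
                ("d", "g1", 1.5, "NEU", True, 10.0),
                ("d", "g1", 0.7, "NEU2", True, 10.0),
                ("d", "g2", 1.5, "NEU", True, 10.0),
                ("d", "g2", 0.2, "NEU2", True, 10.0),
            ]
        )
        s, status = lincs_signature(prof, "d")
        assert status == "ok"
        # g1 mean 1.1 > 1 kept with sign +; g2 mean 0.85 excluded
        assert s.sign.to_dict() == {"g1": 1}

    def test_dose_filter(self):
        prof = self._profiles(
            [
                ("d", "g1", 5.0, "NEU", True, 0.5),
                ("d", "g1", -5.0, "NEU", True, 2.0),
            ]
        )
        s, _ = lincs_signature(prof, "d", min_dose=1.0)
        assert s.sign.to_dict() == {"g1": -1}

    def test_non_cns_only_status(self):
        prof = self._profiles([("d", "g1", 5.0, "HEP", False, 10.0)])
        s, status = lincs_signature(prof, "d", cns_only=True)
        assert status == "not tested in CNS cells"
        assert len(s) == 0

    def test_absent_drug_status(self):
        prof = self._profiles([("other", "g1", 5.0, "NEU", True, 10.0)])
        s, status = lincs_signature(prof, "d")
        assert status == "not found"


entity_names = st.text(alphabet="abcdefgh", min_size=1, max_size=3)
signatures = st.dictionaries(entity_names, st.sampled_from([-1, 1]), min_size=1)


class TestSignedJaccard:
    def test_hand_example(self):
        a = SignedSignature(pd.Series({"g1": 1, "g2": 1, "g3": -1}))
        b = SignedSignature(pd.Series({"g1": 1, "g2": -1, "g4": 1}))
        assert signed_jaccard(a, b) == pytest.approx(0.0)

    def test_empty_union_is_zero(self):
        e = SignedSignature(pd.Series(dtype=int))
        assert signed_jaccard(e, e) == 0.0

    @given(signatures)
    @settings(max_examples=200, deadline=None)
    def test_identity_and_flip(self, mapping):
        a = SignedSignature(pd.Series(mapping))
        assert signed_jaccard(a, a) == pytest.approx(1.0)
        assert signed_jaccard(a, a.flipped()) == pytest.approx(-1.0)

    @given(signatures, signatures)
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, ma, mb):
        a = SignedSignature(pd.Series(ma))
        b = SignedSignature(pd.Series(mb))
        j = signed_jaccard(a, b)
        assert j == pytest.approx(signed_jaccard(b, a))
        assert -1.0 <= j <= 1.0

    @given(signatures, signatures)
    @settings(max_examples=200, deadline=None)
    def test_equals_plain_jaccard_when_signs_agree(self, ma, mb):
        # force agreement on the intersection
        mb = {k: ma.get(k, v) for k, v in mb.items()}
        a = SignedSignature(pd.Series(ma))
        b = SignedSignature(pd.Series(mb))
        inter = len(a.entities.intersection(b.entities))
        union = len(a.entities.union(b.entities))
        assert signed_jaccard(a, b) == pytest.approx(inter / union)
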