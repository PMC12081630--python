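import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from seedcap._errors import ConfigurationError, SeedcapError
from seedcap.estimation import CapSet
from seedcap.stats import (
    ParcellationOverlay,
    cap_spatial_overlap,
    correlate_clinical,
    fdr_adjust,
    fit_group_model,
    network_overlap,
    pair_caps,
)

from oracles import bh_bruteforce


def _caps_with_sets(pos_sets, neg_sets, n_vox=200, rng_seed=0):
    """CapSet with prescribed suprathreshold sets and consistent maps."""
    k = len(pos_sets)
    rng = np.random.default_rng(rng_seed)
    maps = rng.normal(scale=0.1, size=(k, n_vox))
    for c in range(k):
        maps[c, list(pos_sets[c])] = 3.0
        maps[c, list(neg_sets[c])] = -3.0
    return CapSet(
        k=k,
        maps=maps,
        assignments=np.arange(1, k + 1),
        pos_voxels=[np.asarray(sorted(s), dtype=int) for s in pos_sets],
        neg_voxels=[np.asarray(sorted(s), dtype=int) for s in neg_sets],
        occupancy_pct=np.full(k, 100.0 / k),
    )


class TestNetworkOverlap:
    def test_containment(self):
        labels = np.ones(100, dtype=int) * 7
        caps = _caps_with_sets([range(10, 30)], [range(40, 50)], n_vox=100)
        tab = network_overlap(caps, ParcellationOverlay(labels))
        pos = tab[(tab.sign == "positive")]
        assert len(pos) == 1
        assert pos.iloc[0]["pct"] == 100.0
        assert pos.iloc[0]["network_id"] == 7

    def test_even_split(self):
        labels = np.r_[np.ones(50, int), np.full(50, 2)]
        caps = _caps_with_sets([list(range(45, 55))], [[]], n_vox=100)
        tab = network_overlap(caps, ParcellationOverlay(labels))
        pcts = dict(zip(tab.network_id, tab.pct))
        assert pcts == {1: 50.0, 2: 50.0}

    def test_matches_bruteforce_tally_and_sums_to_100(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 18, size=500)  # includes background 0
        pos = rng.choice(500, size=80, replace=False)
        neg = np.setdiff1d(rng.choice(500, size=120, replace=False), pos)
        caps = _caps_with_sets([pos], [neg], n_vox=500)
        tab = network_overlap(caps, ParcellationOverlay(labels))
        for sign, vox in (("positive", pos), ("negative", neg)):
            sub = tab[tab.sign == sign]
            assert sub.pct.sum() == pytest.approx(100.0, abs=1e-6)
            for _, row in sub.iterrows():
                expected = 100.0 * np.sum(labels[vox] == row.network_id) / len(vox)
                assert row.pct == pytest.approx(expected, abs=1e-12)


class TestCapSpatialOverlap:
    def test_identical_capsets_full_overlap(self):
        caps = _caps_with_sets([range(10), range(30, 40)], [range(50, 60), range(70, 75)])
        assert np.allclose(cap_spatial_overlap(caps, caps), 100.0)

    def test_disjoint_sets_zero(self):
        a = _caps_with_sets([range(10)], [range(20, 30)])
        b = _caps_with_sets([range(100, 110)], [range(120, 130)])
        assert np.allclose(
            cap_spatial_overlap(a, b, pairing=np.array([0])), 0.0
        )

    def test_jaccard_arithmetic(self):
        """|A| = |B| = 100, 50 shared -> 100*50/150 = 33.33%."""
        a = _caps_with_sets([range(0, 100)], [[]], n_vox=400)
        b = _caps_with_sets([range(50, 150)], [[]], n_vox=400)
        ov = cap_spatial_overlap(a, b, pairing=np.array([0]))
        assert ov[0] == pytest.approx(100 * 50 / 150, abs=1e-9)
        cont = cap_spatial_overlap(a, b, method="containment", pairing=np.array([0]))
        assert cont[0] == pytest.approx(50.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = _caps_with_sets([rng.choice(200, 40, replace=False)], [[]], rng_seed=3)
        b = _caps_with_sets([rng.choice(200, 60, replace=False)], [[]], rng_seed=4)
        p = np.array([0])
        assert cap_spatial_overlap(a, b, pairing=p) == pytest.approx(
            cap_spatial_overlap(b, a, pairing=p)
        )

    def test_pairing_by_correlation(self):
        caps = _caps_with_sets([range(10), range(50, 60)], [range(80, 90), range(120, 130)])
        swapped = CapSet(
            k=2,
            maps=caps.maps[::-1].copy(),
            assignments=caps.assignments,
            pos_voxels=caps.pos_voxels[::-1],
            neg_voxels=caps.neg_voxels[::-1],
            occupancy_pct=caps.occupancy_pct,
        )
        assert pair_caps(caps, swapped).tolist() == [1, 0]
        assert np.allclose(cap_spatial_overlap(caps, swapped), 100.0)


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.037]))[0] == pytest.approx(0.037, abs=1e-15)

    def test_textbook_example(self):
        adj = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04, atol=1e-12)

    def test_all_equal_ps_unchanged(self):
        adj = fdr_adjust(np.full(6, 0.2))
        assert np.allclose(adj, 0.2, atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))

    def test_matches_bruteforce_on_fuzzed_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(fdr_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(SeedcapError):
            fdr_adjust(np.array([0.5, 1.2]))


def _toy_tables(rng_seed=0, n_per_group=8, k=4, effect=0.0, effect_cap=4):
    rng = np.random.default_rng(rng_seed)
    mrows, crows = [], []
    for g, gname in enumerate(["reference", "test"]):
        for i in range(n_per_group):
            sid = f"{gname}-{i}"
            crows.append(
                dict(
                    subject_id=sid,
                    group=gname,
                    age=rng.normal(40, 10),
                    sex=i % 2,
                    bdi=rng.normal(10, 5),
                )
            )
            for c in range(1, k + 1):
                y = rng.normal(10, 2) + (effect if (g == 1 and c == effect_cap) else 0)
                mrows.append(dict(subject_id=sid, cap=c, entries=y))
    return pd.DataFrame(mrows), pd.DataFrame(crows)


class TestGroupModel:
    COVS = ("age", "sex", "bdi")

    def test_f_statistics_match_projection_oracle(self):
        metrics, clinical = _toy_tables(rng_seed=5, effect=3.0)
        res = fit_group_model(metrics, clinical, "entries", covariates=self.COVS)
        df = metrics.merge(clinical, on="subject_id")

        def rss(formula):
            return smf.ols(formula, data=df).fit().ssr

        full_fit = smf.ols("entries ~ C(group)*C(cap) + age + sex + bdi", data=df).fit()
        rss_full, df_res = full_fit.ssr, full_fit.df_resid
        ss_cap = rss("entries ~ C(group) + age + sex + bdi") - rss(
            "entries ~ C(group) + C(cap) + age + sex + bdi"
        )
        ss_int = rss("entries ~ C(group) + C(cap) + age + sex + bdi") - rss_full
        f_cap = (ss_cap / 3) / (rss_full / df_res)
        f_int = (ss_int / 3) / (rss_full / df_res)
        omn = res.omnibus.set_index("term")
        assert omn.loc["state", "F"] == pytest.approx(f_cap, abs=1e-8)
        assert omn.loc["group:state", "F"] == pytest.approx(f_int, abs=1e-8)
        assert omn.loc["state", "df_den"] == df_res

    def test_detects_planted_contrast(self):
        metrics, clinical = _toy_tables(rng_seed=6, effect=6.0)
        res = fit_group_model(metrics, clinical, "entries", covariates=self.COVS)
        sig = res.posthoc[res.posthoc.significant]
        assert sig.cap.tolist() == [4]
        assert sig.iloc[0]["estimate"] > 0

    def test_posthoc_fdr_matches_adjusting_raw_ps(self):
        metrics, clinical = _toy_tables(rng_seed=7, effect=2.0)
        res = fit_group_model(metrics, clinical, "entries", covariates=self.COVS)
        assert np.allclose(
            res.posthoc.p_fdr, fdr_adjust(res.posthoc.p_raw.to_numpy()), atol=1e-12
        )

    def test_collinear_covariate_rejected(self):
        metrics, clinical = _toy_tables(rng_seed=8)
        clinical["dup"] = (clinical.group == "test").astype(float)
        with pytest.raises(ConfigurationError, match="rank deficient"):
            fit_group_model(metrics, clinical, "entries", covariates=("age", "dup"))

    def test_missing_covariates_drop_subjects_with_warning(self):
        metrics, clinical = _toy_tables(rng_seed=9)
        clinical.loc[0, "bdi"] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            res = fit_group_model(metrics, clinical, "entries", covariates=self.COVS)
        assert res.n_obs == (len(clinical) - 1) * 4


class TestClinicalCorrelations:
    def _tables(self, y_from_x):
        rng = np.random.default_rng(10)
        x = rng.normal(size=20)
        clinical = pd.DataFrame(
            dict(
                subject_id=[f"s{i}" for i in range(20)],
                subgroup=["FW"] * 10 + ["no-FW"] * 10,
                stai_s=x,
            )
        )
        metrics = pd.DataFrame(
            dict(
                subject_id=[f"s{i}" for i in range(20)],
                cap=1,
                entries=y_from_x(x),
            )
        )
        return metrics, clinical

    def test_identity_gives_r_one(self):
        metrics, clinical = self._tables(lambda x: x)
        out = correlate_clinical(metrics, clinical, [("entries", 1, "stai_s")])
        assert np.allclose(out.r, 1.0, atol=1e-12)

    def test_sign_flip_gives_r_minus_one(self):
        metrics, clinical = self._tables(lambda x: -x)
        out = correlate_clinical(metrics, clinical, [("entries", 1, "stai_s")])
        assert np.allclose(out.r, -1.0, atol=1e-12)

    def test_bivariate_normal_sampling_distribution(self):
        rng = np.random.default_rng(11)
        n = 1000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        clinical = pd.DataFrame(
            dict(subject_id=[f"s{i}" for i in range(n)], subgroup="FW", stai_s=x)
        )
        metrics = pd.DataFrame(
            dict(subject_id=[f"s{i}" for i in range(n)], cap=1, entries=y)
        )
        out = correlate_clinical(metrics, clinical, [("entries", 1, "stai_s")])
        assert out.r[0] == pytest.approx(0.5, abs=0.06)

    def test_degenerate_variable_reported_missing(self):
        metrics, clinical = self._tables(lambda x: np.zeros_like(x))
        out = correlate_clinical(metrics, clinical, [("entries", 1, "stai_s")])
        assert out.r.isna().all()
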