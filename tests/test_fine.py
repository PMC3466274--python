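import numpy as np
import pytest

from dcgnet import (
    MotifConfiguration,
    MotifDomain,
    SharingMatrix,
    fine_feature_vector,
    missing_counts,
    motif_configuration,
    motif_domain,
    odds_score,
    restrict_domain,
)


def config(sid, trial, *motifs):
    return MotifConfiguration(
        subject_id=sid, trial=trial, motifs=frozenset(frozenset(m) for m in motifs)
    )


def sharing_from_blocks(n, blocks, within=1.0):
    values = np.zeros((n, n))
    for b in blocks:
        idx = np.array(b) - 1
        values[np.ix_(idx, idx)] = within
    np.fill_diagonal(values, 1.0)
    return SharingMatrix(values=values, temperature=0.001, n_walks=1, roi_ids=tuple(range(1, n + 1)))


class TestMotifConfiguration:
    def test_exact_pair_blocks_become_motifs(self):
        p = sharing_from_blocks(4, [(1, 2), (3, 4)])
        cfg = motif_configuration(p)
        assert cfg.motifs == {frozenset({1, 2}), frozenset({3, 4})}

    def test_no_off_diagonal_sharing_gives_empty_configuration(self):
        p = sharing_from_blocks(4, [])
        assert motif_configuration(p).motifs == frozenset()

    def test_singletons_excluded(self):
        p = sharing_from_blocks(5, [(1, 2, 3)])  # node 4, 5 are singletons
        cfg = motif_configuration(p)
        assert cfg.motifs == {frozenset({1, 2, 3})}

    def test_invariant_to_roi_ordering(self):
        p1 = sharing_from_blocks(4, [(1, 2)])
        perm = np.array([2, 3, 0, 1])
        values = p1.values[np.ix_(perm, perm)]
        roi_ids = tuple(p1.roi_ids[i] for i in perm)
        p2 = SharingMatrix(values=values, temperature=0.001, n_walks=1, roi_ids=roi_ids)
        assert motif_configuration(p1).motifs == motif_configuration(p2).motifs

    def test_overlapping_motifs_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            config("s", "green", (1, 2), (2, 3))

    def test_singleton_motif_rejected(self):
        with pytest.raises(ValueError, match="2 ROIs"):
            config("s", "green", (1,))

    def test_bad_prune_height_rejected(self):
        with pytest.raises(ValueError, match="prune_height"):
            motif_configuration(sharing_from_blocks(4, []), prune_height=0.0)


class TestMotifDomain:
    def test_prevalence_counts_subjects(self):
        dom = motif_domain(
            [config("a", "green", (87, 88)), config("b", "green", (87, 88), (1, 2))],
            group="TD",
        )
        assert dom.prevalence[frozenset({87, 88})] == 2
        assert dom.prevalence[frozenset({1, 2})] == 1
        assert dom.n_subjects == 2

    def test_disjoint_configurations_all_prevalence_one(self):
        dom = motif_domain([config("a", "red", (1, 2)), config("b", "red", (3, 4))])
        assert set(dom.prevalence.values()) == {1}

    def test_mixed_trials_rejected(self):
        with pytest.raises(ValueError, match="mixed trials"):
            motif_domain([config("a", "green", (1, 2)), config("b", "red", (1, 2))])

    def test_prevalence_conservation(self):
        configs = [
            config("a", "green", (1, 2), (3, 4)),
            config("b", "green", (1, 2)),
            config("c", "green", (5, 6)),
        ]
        dom = motif_domain(configs)
        assert sum(len(c) for c in configs) == sum(dom.prevalence.values())


class TestRestrictDomain:
    def test_tau_one_is_identity(self):
        dom = motif_domain([config("a", "green", (1, 2)), config("b", "green", (1, 2))])
        assert restrict_domain(dom, 1).prevalence == dom.prevalence

    def test_threshold_is_inclusive(self):
        dom = MotifDomain(
            group="ASD", trial="green",
            prevalence={frozenset({1, 2}): 14, frozenset({3, 4}): 15}, n_subjects=29,
        )
        restricted = restrict_domain(dom, 15)
        assert restricted.motifs == {frozenset({3, 4})}

    def test_tau_above_all_prevalences_empties_domain(self):
        dom = MotifDomain(group="ASD", trial="green", prevalence={frozenset({1, 2}): 5})
        assert len(restrict_domain(dom, 6)) == 0

    def test_monotone_in_tau(self):
        prevalence = {frozenset({i, i + 1}): i for i in range(1, 20, 2)}
        dom = MotifDomain(group="TD", trial="green", prevalence=prevalence)
        for t1 in range(1, 10):
            assert restrict_domain(dom, t1 + 1).motifs <= restrict_domain(dom, t1).motifs


def domains_for(prev_asd, prev_td, n_asd=29, n_td=29):
    return (
        MotifDomain(group="ASD", trial="green", prevalence=prev_asd, n_subjects=n_asd),
        MotifDomain(group="TD", trial="green", prevalence=prev_td, n_subjects=n_td),
    )


class TestOddsScore:
    def test_td_favoring_motif(self):
        """Prevalence 10 vs 21 of 29 points toward TD: log odds about -0.742."""
        m = frozenset({87, 88})
        asd, td = domains_for({m: 10}, {m: 21})
        cfg = config("s", "green", (87, 88))
        assert odds_score(cfg, asd, td) == pytest.approx(np.log(10 / 21))

    def test_motif_absent_from_either_domain_ignored(self):
        m = frozenset({1, 2})
        asd, td = domains_for({m: 10}, {frozenset({3, 4}): 10})
        assert odds_score(config("s", "green", (1, 2)), asd, td) == 0.0

    def test_log_symmetric_cancellation(self):
        m1, m2 = frozenset({1, 2}), frozenset({3, 4})
        asd, td = domains_for({m1: 10, m2: 5}, {m1: 5, m2: 10})
        cfg = config("s", "green", (1, 2), (3, 4))
        assert odds_score(cfg, asd, td) == pytest.approx(0.0)

    def test_antisymmetric_under_domain_swap(self):
        m1, m2 = frozenset({1, 2}), frozenset({3, 4})
        asd, td = domains_for({m1: 17, m2: 4}, {m1: 6, m2: 12}, n_asd=28, n_td=29)
        cfg = config("s", "green", (1, 2), (3, 4))
        assert odds_score(cfg, asd, td) == pytest.approx(-odds_score(cfg, td, asd))

    def test_unequal_domain_sizes_compared_per_capita(self):
        m = frozenset({1, 2})
        asd, td = domains_for({m: 14}, {m: 15}, n_asd=28, n_td=30)
        expected = np.log((14 / 28) / (15 / 30))
        assert odds_score(config("s", "green", (1, 2)), asd, td) == pytest.approx(expected)


class TestMissingCounts:
    def test_basic_membership(self):
        m1, m2 = frozenset({1, 2}), frozenset({3, 4})
        asd, td = domains_for({m1: 5, m2: 5}, {m1: 5})
        assert missing_counts(config("s", "green", m1, m2), asd, td) == (0, 1)

    def test_empty_configuration(self):
        asd, td = domains_for({}, {})
        assert missing_counts(config("s", "green"), asd, td) == (0, 0)

    def test_tau_fifteen_worked_example(self):
        """ASD prevalence 14 vs TD 16 at tau=15: missing from ASD domain only."""
        m = frozenset({87, 88})
        asd, td = domains_for({m: 14}, {m: 16})
        asd15, td15 = restrict_domain(asd, 15), restrict_domain(td, 15)
        assert missing_counts(config("s", "green", m), asd15, td15) == (1, 0)


class TestFineFeatureVector:
    @pytest.fixture()
    def cohort_configs(self):
        configs, groups = {}, {}
        common, asd_only = (1, 2), (3, 4)
        for i in range(4):
            sid = f"A{i}"
            groups[sid] = "ASD"
            configs[(sid, "green")] = config(sid, "green", common, asd_only)
        for i in range(4):
            sid = f"T{i}"
            groups[sid] = "TD"
            configs[(sid, "green")] = config(sid, "green", common)
        return configs, groups

    def test_jackknife_lowers_own_prevalence_by_one(self, cohort_configs):
        configs, groups = cohort_configs
        ff = fine_feature_vector("A0", configs, groups, tau=1, trials=("green",))
        odds, miss_asd, miss_td = ff.components["green"]
        # common motif: own-group prevalence 3 (of 3), TD 4 (of 4) -> per-capita even
        assert odds == pytest.approx(np.log((3 / 3) / (4 / 4)))
        assert (miss_asd, miss_td) == (0, 1)  # asd_only motif absent from TD domain

    def test_discriminating_motif_produces_positive_odds(self):
        configs, groups = {}, {}
        for i in range(6):
            sid = f"A{i}"
            groups[sid] = "ASD"
            motifs = [(1, 2)] if i < 5 else []
            configs[(sid, "green")] = config(sid, "green", *motifs)
        for i in range(6):
            sid = f"T{i}"
            groups[sid] = "TD"
            motifs = [(1, 2)] if i < 2 else []
            configs[(sid, "green")] = config(sid, "green", *motifs)
        ff = fine_feature_vector("A0", configs, groups, tau=2, trials=("green",))
        assert ff.components["green"][0] > 0

    def test_missing_trial_flagged_absent(self, cohort_configs):
        configs, groups = cohort_configs
        ff = fine_feature_vector("A0", configs, groups, tau=1, trials=("green", "red"))
        assert "red" not in ff.components
        with pytest.raises(KeyError, match="red"):
            ff.predictors(("green", "red"))
        assert ff.predictors(("green",)).shape == (2,)

    def test_equal_prevalence_motifs_give_zero_odds(self):
        configs, groups = {}, {}
        for g, prefix in (("ASD", "A"), ("TD", "T")):
            for i in range(3):
                sid = f"{prefix}{i}"
                groups[sid] = g
                configs[(sid, "green")] = config(sid, "green", (1, 2))
        # per-capita prevalence 2/2 vs 3/3 for an ASD subject: ratio 1
        ff = fine_feature_vector("A0", configs, groups, tau=1, trials=("green",))
        assert ff.components["green"][0] == pytest.approx(0.0)

    def test_unknown_subject_rejected(self, cohort_configs):
        configs, groups = cohort_configs
        with pytest.raises(KeyError, match="nobody"):
            fine_feature_vector("nobody", configs, groups, tau=1)
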