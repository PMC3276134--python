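import math

import numpy as np
import pytest

from senescreen.archetype_classify import (
    ArchetypeConfig,
    Passage2Filter,
    assign_classes,
    class_recovery_summary,
    compute_passage2_filter,
    rank_by_archetype,
    recovered_fraction,
)
from senescreen.profile import MDP, compute_all_mdps
from conftest import make_dataset


def mdp_of(mean, genotype="g", n=4):
    mean = np.asarray(mean, dtype=float)
    return MDP(genotype=genotype, n_repeats=n, mean=mean, sd=np.zeros_like(mean))


class TestPassage2Filter:
    def test_cutoff_formula(self):
        f = Passage2Filter(c_ave=2000.0, c_sd=640.0)
        assert f.c_s == 1680.0

    def test_zero_sd_cutoff_equals_mean(self):
        assert Passage2Filter(c_ave=7.0, c_sd=0.0).c_s == 7.0
        assert Passage2Filter(c_ave=0.0, c_sd=0.0).c_s == 0.0

    def test_computed_over_individual_cultures(self):
        # two genotypes with unequal replicate counts: individual cultures,
        # not genotype means, define the population
        ds = make_dataset({"a": [[10, 1], [20, 1], [30, 1]], "b": [[100, 1]]})
        f = compute_passage2_filter(ds, passage=1)
        sizes = [10, 20, 30, 100]
        assert f.c_ave == pytest.approx(np.mean(sizes))
        assert f.c_sd == pytest.approx(np.std(sizes, ddof=1))
        assert f.c_s == pytest.approx(f.c_ave - 0.5 * f.c_sd)

    def test_passage_out_of_range(self):
        ds = make_dataset({"a": [[1, 2]]})
        with pytest.raises(ValueError):
            compute_passage2_filter(ds, passage=5)


class TestRanking:
    def test_archetype_heads_list_with_r_one(self):
        mdps = {"arch": mdp_of([1, 5, 2, 8], "arch"),
                "other": mdp_of([8, 2, 5, 1], "other")}
        ranked = rank_by_archetype(mdps, "arch")
        assert ranked.entries[0] == ("arch", 1.0)

    def test_affine_copy_ties_with_archetype(self):
        base = np.array([1.0, 5, 2, 8])
        mdps = {"arch": mdp_of(base, "arch"),
                "copy": mdp_of(3 * base + 10, "copy"),
                "anti": mdp_of(-base, "anti")}
        ranked = rank_by_archetype(mdps, "arch")
        assert [g for g, _ in ranked.entries[:2]] == ["arch", "copy"]
        assert ranked.entries[1][1] == pytest.approx(1.0)

    def test_ordering_matches_brute_force(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        mdps = {"arch": mdp_of(base, "arch")}
        for i in range(5):
            mdps[f"g{i}"] = mdp_of(rng.normal(size=10), f"g{i}")
        ranked = rank_by_archetype(mdps, "arch")

        def brute_r(m):
            x, y = m.mean, base
            return float(np.corrcoef(x, y)[0, 1])

        expected = ["arch"] + sorted(
            (g for g in mdps if g != "arch"),
            key=lambda g: (-brute_r(mdps[g]), g),
        )
        assert [g for g, _ in ranked.entries] == expected

    def test_undefined_r_sorts_last(self):
        mdps = {"arch": mdp_of([1, 2, 3], "arch"),
                "flat": mdp_of([4, 4, 4], "flat"),
                "good": mdp_of([2, 4, 6], "good")}
        ranked = rank_by_archetype(mdps, "arch")
        assert ranked.entries[-1] == ("flat", None)

    def test_missing_archetype(self):
        with pytest.raises(KeyError):
            rank_by_archetype({"g": mdp_of([1, 2, 3])}, "arch")


def toy_classification_setup():
    """Hand-built screen: archetype curves plus comparators with known
    relations to them.  Passage-1 sizes define the early-fitness filter."""
    P = 8
    normal = [100, 90, 40, 10, 15, 40, 60, 70]
    no_rec = [40, 20, 6, 3, 2, 2, 2, 2]
    fast = [100, 30, 8, 30, 80, 95, 98, 99]
    series = {
        "his3": [normal, normal],
        "rad52": [no_rec, no_rec],
        "rif1": [fast, fast],
        # affine copy of normal: r = 1 but healthy early fitness
        "like_normal": [[2 * v + 5 for v in normal]] * 2,
        # scaled copy of no-recovery archetype, sick at the filter passage
        "like_norec": [[0.9 * v for v in no_rec]] * 2,
        # like_norec shape but healthy early: must fail the filter
        "norec_but_big": [[2.5 * v for v in no_rec]] * 2,
    }
    ds = make_dataset(series)
    mdps = compute_all_mdps(ds)
    cfg = ArchetypeConfig(
        recovery_passage=8, recovery_size_threshold=50.0,
        fast_recovery_top_k=1, filter_passage=1,
    )
    return ds, mdps, cfg


class TestAssignClasses:
    def test_archetype_is_member_of_its_own_class(self):
        ds, mdps, cfg = toy_classification_setup()
        asg = assign_classes(mdps, ds, cfg)
        assert "normal" in asg["his3"].memberships
        assert "no_recovery" in asg["rad52"].memberships
        assert "fast_recovery" in asg["rif1"].memberships

    def test_affine_copy_joins_normal_class(self):
        ds, mdps, cfg = toy_classification_setup()
        asg = assign_classes(mdps, ds, cfg)
        assert asg["like_normal"].r_normal == pytest.approx(1.0)
        assert "normal" in asg["like_normal"].memberships

    def test_filter_conjunct_blocks_healthy_strain(self):
        ds, mdps, cfg = toy_classification_setup()
        asg = assign_classes(mdps, ds, cfg)
        a = asg["norec_but_big"]
        assert a.r_no_recovery > 0.5  # correlates with the archetype shape
        assert not a.passes_p2_filter
        assert "no_recovery" not in a.memberships
        b = asg["like_norec"]
        assert b.passes_p2_filter and "no_recovery" in b.memberships

    def test_no_recovery_membership_implies_filter_pass(self):
        ds, mdps, cfg = toy_classification_setup()
        for a in assign_classes(mdps, ds, cfg).values():
            if "no_recovery" in a.memberships:
                assert a.passes_p2_filter

    def test_every_genotype_gets_all_three_r_values(self):
        ds, mdps, cfg = toy_classification_setup()
        for a in assign_classes(mdps, ds, cfg).values():
            assert a.r_normal is not None
            assert a.r_no_recovery is not None
            assert a.r_fast_recovery is not None

    def test_tightening_thresholds_never_adds_members(self):
        ds, mdps, cfg = toy_classification_setup()
        loose = assign_classes(mdps, ds, cfg)
        import dataclasses

        tight_cfg = dataclasses.replace(cfg, r_normal=0.95, r_no_recovery=0.8)
        tight = assign_classes(mdps, ds, tight_cfg)
        for g in loose:
            for cls in ("normal", "no_recovery"):
                if cls in tight[g].memberships:
                    assert cls in loose[g].memberships

    def test_affine_rescaling_leaves_r_memberships_unchanged(self):
        ds, mdps, cfg = toy_classification_setup()
        base = assign_classes(mdps, ds, cfg)
        rescaled = {
            g: (m if g in ("his3", "rad52", "rif1")
                else MDP(g, m.n_repeats, 3.0 * m.mean + 20.0, m.sd))
            for g, m in mdps.items()
        }
        out = assign_classes(rescaled, ds, cfg)
        for g in mdps:
            assert out[g].r_normal == pytest.approx(base[g].r_normal, abs=1e-12)
            keep = {m for m in base[g].memberships}
            got = {m for m in out[g].memberships}
            # only the scale-dependent filter may change memberships
            assert got - {"no_recovery"} == keep - {"no_recovery"}

    def test_missing_archetype_rejected(self):
        ds, mdps, cfg = toy_classification_setup()
        del mdps["rif1"]
        with pytest.raises(KeyError, match="rif1"):
            assign_classes(mdps, ds, cfg)

    def test_top_k_boundary_ties_included(self):
        P = 6
        base = np.array([10.0, 8, 3, 1, 4, 9])
        # power-of-two scalings give bit-identical r values (exact ties)
        mdps = {"arch": mdp_of(base, "arch"),
                "tie1": mdp_of(2 * base, "tie1"),
                "tie2": mdp_of(4 * base, "tie2"),
                "far": mdp_of(base[::-1].copy(), "far")}
        ds = make_dataset({g: [list(m.mean)] for g, m in mdps.items()})
        cfg = ArchetypeConfig(
            normal_archetype="arch", no_recovery_archetype="arch",
            fast_recovery_archetype="arch", fast_recovery_top_k=2,
            recovery_passage=6, filter_passage=1,
        )
        asg = assign_classes(mdps, ds, cfg)
        members = {g for g, a in asg.items() if "fast_recovery" in a.memberships}
        # arch, tie1, tie2 all at r = 1: the k-th value ties are kept
        assert members == {"arch", "tie1", "tie2"}


class TestRecoveredFraction:
    def decline_then(*tail):
        pass

    @staticmethod
    def curve(recover_at=None, P=22, high=4000.0, low=100.0, nadir=6):
        """Healthy start, decline to a nadir, optional regrowth."""
        s = []
        for p in range(1, P + 1):
            if p < nadir:
                s.append(high - (high - low) * (p - 1) / (nadir - 1))
            elif recover_at is not None and p >= recover_at:
                s.append(high)
            else:
                s.append(low)
        return s

    def test_counting_half_recovered(self):
        reps = [self.curve(recover_at=10)] * 4 + [self.curve()] * 4
        ds = make_dataset({"g": reps})
        assert recovered_fraction(ds, "g") == 0.5

    def test_none_recovered_is_zero(self):
        ds = make_dataset({"g": [self.curve()] * 8})
        assert recovered_fraction(ds, "g") == 0.0

    def test_threshold_boundary_inclusive(self):
        series = self.curve()
        series[18] = 1000.0  # exactly the threshold at the deadline passage
        ds = make_dataset({"g": [series]})
        assert recovered_fraction(ds, "g") == 1.0

    def test_recovery_after_deadline_not_counted(self):
        late = self.curve(recover_at=21)
        ds = make_dataset({"g": [late]})
        cfg = ArchetypeConfig(recovery_passage=19)
        assert recovered_fraction(ds, "g", cfg) == 0.0
        cfg22 = ArchetypeConfig(recovery_passage=22)
        assert recovered_fraction(ds, "g", cfg22) == 1.0

    def test_healthy_early_fitness_alone_is_not_recovery(self):
        # declines from 4000 and stays low: was big early, never recovered
        ds = make_dataset({"g": [self.curve()]})
        assert recovered_fraction(ds, "g") == 0.0

    def test_at_passage_mode_checks_deadline_only(self):
        transient = self.curve(recover_at=10)
        transient[18] = 150.0  # sick again (below threshold) at the deadline
        ds = make_dataset({"g": [transient]})
        by = ArchetypeConfig(recovery_mode="by_passage")
        at = ArchetypeConfig(recovery_mode="at_passage")
        assert recovered_fraction(ds, "g", by) == 1.0
        assert recovered_fraction(ds, "g", at) == 0.0

    def test_monotone_in_deadline_and_threshold(self):
        rng = np.random.default_rng(5)
        reps = [
            self.curve(recover_at=int(rng.integers(7, 22)))
            if rng.random() < 0.6 else self.curve()
            for _ in range(20)
        ]
        ds = make_dataset({"g": reps})
        fracs = [
            recovered_fraction(ds, "g", ArchetypeConfig(recovery_passage=p))
            for p in range(6, 23)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        by_thr = [
            recovered_fraction(
                ds, "g", ArchetypeConfig(recovery_size_threshold=t))
            for t in (10.0, 100.0, 1000.0, 5000.0)
        ]
        assert all(a >= b for a, b in zip(by_thr, by_thr[1:]))

    def test_deadline_beyond_experiment_rejected(self):
        ds = make_dataset({"g": [[1.0, 2.0]]})
        with pytest.raises(ValueError):
            recovered_fraction(ds, "g", ArchetypeConfig(recovery_passage=19))


class TestClassRecoverySummary:
    def test_unweighted_mean_over_members(self):
        ds, mdps, cfg = toy_classification_setup()
        asg = assign_classes(mdps, ds, cfg)
        asg["his3"].recovered_fraction = 0.25
        asg["like_normal"].recovered_fraction = 0.75
        asg["his3"].memberships = {"normal"}
        asg["like_normal"].memberships = {"normal"}
        for g in asg:
            if g not in ("his3", "like_normal"):
                asg[g].memberships -= {"normal"}
        summary = class_recovery_summary(asg)
        assert summary["normal"] == pytest.approx(0.5)

    def test_empty_class_flagged_none(self):
        ds, mdps, cfg = toy_classification_setup()
        asg = assign_classes(mdps, ds, cfg)
        for a in asg.values():
            a.memberships.discard("fast_recovery")
        assert class_recovery_summary(asg)["fast_recovery"] is None

    def test_all_sterile_class_mean_zero(self):
        P = 8
        dead = [[0.0] * P] * 4
        ds = make_dataset({"a": dead, "b": dead})
        cfg = ArchetypeConfig(recovery_passage=8)
        fr = [recovered_fraction(ds, g, cfg) for g in ("a", "b")]
        assert fr == [0.0, 0.0]
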