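import itertools
import random

import numpy as np
import pytest

from r2ht import htmodel as hm
from r2ht import treebuild as tb
from r2ht.distances import build_matrix
from r2ht.elements import StructuralVariant
from r2ht.hosts import parse_dated_newick


@pytest.fixture(scope="module")
def fixture_model(distmats_mod, mapping_mod, host_mod):
    nt, aa = distmats_mod
    return hm.DivergenceAgeModel.from_distance_matrix(
        nt, mapping_mod, host_mod, aa_matrix=aa)


@pytest.fixture(scope="module")
def distmats_mod():
    from r2ht import io
    return io.load_published_distances()


@pytest.fixture(scope="module")
def mapping_mod():
    from r2ht import io
    return io.load_fixture_mapping()


@pytest.fixture(scope="module")
def host_mod():
    from r2ht.hosts import load_fixture_host_tree
    return load_fixture_host_tree()


class TestAssemblePoints:
    def test_default_point_count(self, fixture_model):
        """Cross-taxon pairs among the seven includable elements: the
        ancient paralog and the degenerate copy are dropped."""
        pts = fixture_model.points
        assert len(pts.points) == 19
        assert pts.excluded_elements == {
            "R2BggB": "paralog", "R2Brdeg": "degenerate"}

    def test_include_degenerate_variant(self, distmats_mod, mapping_mod,
                                        host_mod):
        nt, aa = distmats_mod
        pts = hm.assemble_points(nt, mapping_mod, host_mod,
                                 aa_matrix=aa, include_degenerate=True)
        assert len(pts.points) == 24  # eight elements, intra dropped

    def test_intra_taxon_pairs_have_age_zero(self, distmats_mod,
                                             mapping_mod, host_mod):
        nt, aa = distmats_mod
        pts = hm.assemble_points(nt, mapping_mod, host_mod,
                                 include_intra_taxon=True)
        intra = [p for p in pts.points if len(p.taxa) == 1]
        assert intra and all(p.age == 0.0 for p in intra)

    def test_single_taxon_yields_empty(self, host_mod):
        recs = {"x": "ACGTAC", "y": "ACGTAA"}
        nt = build_matrix(recs)
        import pandas as pd
        mp = pd.DataFrame({"element_id": ["x", "y"],
                           "taxon": ["rossius", "rossius"]})
        pts = hm.assemble_points(nt, mp, host_mod)
        assert pts.points == []

    def test_unmapped_element_raises(self, distmats_mod, host_mod):
        import pandas as pd
        nt, _ = distmats_mod
        mp = pd.DataFrame({"element_id": ["R2Ba"], "taxon": ["atticus"]})
        with pytest.raises(KeyError):
            hm.assemble_points(nt, mp, host_mod)

    def test_ages_used(self, fixture_model):
        ages = {p.age for p in fixture_model.points.points}
        assert ages == {2.0, 15.4, 17.0, 22.8}


class TestRegression:
    def test_first_principles_agreement(self):
        """OLS/Pearson agree with direct sums-of-squares formulas."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            x = rng.uniform(0, 25, n)
            y = 0.004 * x + rng.normal(0, 0.02, n)
            pts = [
                hm.AgeDivergencePoint(
                    pair=frozenset((f"a{i}", f"b{i}")),
                    taxa=frozenset(("s", "t")), age=float(x[i]),
                    d_nt=float(y[i]), d_aa=None)
                for i in range(n)
            ]
            fit = hm.fit_divergence_age(pts)
            sxy = np.sum((x - x.mean()) * (y - y.mean()))
            sxx = np.sum((x - x.mean()) ** 2)
            syy = np.sum((y - y.mean()) ** 2)
            assert fit.slope == pytest.approx(sxy / sxx, abs=1e-12)
            assert fit.intercept == pytest.approx(
                y.mean() - sxy / sxx * x.mean(), abs=1e-12)
            assert fit.r2 == pytest.approx(sxy ** 2 / (sxx * syy),
                                           abs=1e-12)
            assert fit.r2 == pytest.approx(fit.pearson_r ** 2,
                                           abs=1e-12)

    def test_collinear_points(self):
        pts = [
            hm.AgeDivergencePoint(frozenset((f"x{i}", f"y{i}")),
                                  frozenset(("s", "t")),
                                  float(i), 0.01 * i, None)
            for i in range(1, 8)
        ]
        fit = hm.fit_divergence_age(pts)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.p_value < 1e-9
        assert hm.flag_candidates(pts) == set()

    def test_too_few_points(self):
        pts = [
            hm.AgeDivergencePoint(frozenset(("a", "b")),
                                  frozenset(("s", "t")), 1.0, 0.01, None)
        ]
        with pytest.raises(ValueError):
            hm.fit_divergence_age(pts)

    def test_fixture_r2_values(self, fixture_model, six_ht_pairs):
        """The published all-pairs and excluded-refit R² emerge from
        the bundled table."""
        fit_all = hm.fit_divergence_age(fixture_model.points)
        assert fit_all.r2 == pytest.approx(0.034, abs=0.005)
        assert fit_all.p_value > 0.05
        fit_excl = hm.fit_divergence_age(fixture_model.points,
                                         exclude=six_ht_pairs)
        assert fit_excl.r2 == pytest.approx(0.796, abs=0.005)
        assert fit_excl.p_value < 0.001

    def test_fixture_aa_r2(self, fixture_model, six_ht_pairs):
        fit_all = hm.fit_divergence_age(fixture_model.points,
                                        response="aa")
        assert fit_all.r2 == pytest.approx(0.041, abs=0.005)
        fit_excl = hm.fit_divergence_age(
            fixture_model.points, exclude=six_ht_pairs, response="aa")
        assert fit_excl.r2 == pytest.approx(0.796, abs=0.005)


class TestFlagging:
    def test_fixture_flags_exactly_six(self, fixture_model,
                                       six_ht_pairs):
        assert hm.flag_candidates(fixture_model.points) == six_ht_pairs

    def test_flagging_robust_to_t_range(self, fixture_model,
                                        six_ht_pairs):
        for t in (2.0, 2.5, 3.0):
            got = hm.flag_candidates(fixture_model.points, t_flag=t)
            assert got == six_ht_pairs

    def test_age_class_method(self, fixture_model, six_ht_pairs):
        got = hm.flag_candidates(fixture_model.points,
                                 method="age-class", f=0.5)
        assert got == six_ht_pairs

    def test_unknown_method(self, fixture_model):
        with pytest.raises(ValueError):
            hm.flag_candidates(fixture_model.points, method="nope")

    def test_only_low_outliers_flagged(self):
        """A point far ABOVE the trend (paralogy) is never flagged."""
        rng = np.random.default_rng(3)
        pts = []
        for i, age in enumerate([2, 2, 15, 15, 17, 17, 22, 22] * 2):
            d = 0.008 * age + rng.normal(0, 0.002)
            pts.append(hm.AgeDivergencePoint(
                frozenset((f"u{i}", f"v{i}")), frozenset(("s", "t")),
                float(age), float(d), None))
        pts.append(hm.AgeDivergencePoint(
            frozenset(("hi", "ho")), frozenset(("s", "t")),
            2.0, 0.5, None))  # extreme paralog-like point
        flagged = hm.flag_candidates(pts)
        assert frozenset(("hi", "ho")) not in flagged

    def test_refit_never_decreases_r2(self, fixture_model):
        flagged = hm.flag_candidates(fixture_model.points)
        fit_all = hm.fit_divergence_age(fixture_model.points)
        fit_excl = hm.fit_divergence_age(fixture_model.points,
                                         exclude=flagged)
        assert fit_excl.r2 >= fit_all.r2


class TestModelResults:
    def test_fit_reports_both_responses(self, fixture_model):
        res = fixture_model.fit()
        assert set(res.fits) == {"nt", "aa"}
        assert res.regression_all.r2 == pytest.approx(0.034, abs=0.005)
        assert res.regression_refit.r2 == pytest.approx(0.797,
                                                        abs=0.005)

    def test_explicit_exclusion_list(self, fixture_model, six_ht_pairs):
        res = fixture_model.fit(exclude=six_ht_pairs)
        assert res.flagged_pairs == six_ht_pairs
        assert res.params["explicit_exclude"]

    def test_summary_mentions_key_numbers(self, fixture_model):
        s = fixture_model.fit().summary()
        assert "0.034" in s and "0.797" in s
        assert "R2Bgb / R2Brfun" in s

    def test_plot_returns_axes(self, fixture_model):
        import matplotlib
        matplotlib.use("Agg")
        ax = fixture_model.fit().plot()
        assert ax.get_xlabel().startswith("host split age")


class TestLineages:
    def test_shared_deletion_binds_lineage(self, fixture_model,
                                           distmats_mod):
        nt, _ = distmats_mod
        profiles = {
            "R2Bgmdel": {StructuralVariant("deletion", 1035, 1460, 426)},
            "R2Brdel": {StructuralVariant("deletion", 1035, 1460, 426)},
        }
        lp = fixture_model.fit().model and hm.assign_lineages(
            nt, profiles,
            elements=[l for l in nt.labels if l != "R2BggB"])
        assert lp.block_of("R2Bgmdel") == lp.block_of("R2Brdel")
        # low divergence alone does not merge across indel profiles
        assert lp.block_of("R2Bgm") != lp.block_of("R2Brdel")

    def test_all_distant_all_singletons(self):
        recs = {"a": "A" * 50, "b": "C" * 50, "c": "G" * 50}
        lp = hm.assign_lineages(build_matrix(recs))
        assert all(len(b) == 1 for b in lp.blocks)

    def test_transitive_closure(self):
        import numpy as np
        from r2ht.distances import DistanceMatrix
        d = np.array([[0, .005, .009], [.005, 0, .005],
                      [.009, .005, 0]])
        m = DistanceMatrix(["a", "b", "c"], d,
                           np.full((3, 3), 100), np.zeros((3, 3)))
        lp = hm.assign_lineages(m)
        assert lp.blocks == [frozenset({"a", "b", "c"})]


class TestPatchiness:
    def test_maretimi_rossius_block_is_patchy(self, mapping_mod,
                                              host_mod):
        assert hm.patchy_distribution(
            frozenset({"R2Bgmdel", "R2Brdel"}), mapping_mod, host_mod)

    def test_sister_pair_not_patchy(self, mapping_mod, host_mod):
        assert not hm.patchy_distribution(
            frozenset({"R2Bgb", "R2Bgm"}), mapping_mod, host_mod)

    def test_single_taxon_not_patchy(self, mapping_mod, host_mod):
        assert not hm.patchy_distribution(
            frozenset({"R2Ba"}), mapping_mod, host_mod)


class TestTopologyConflicts:
    def test_congruent_trees_no_conflict(self):
        import pandas as pd
        host = parse_dated_newick("((A:1,B:1):1,(C:1,D:1):1);")
        recs, _, _ = _sim_on(host, seed=0)
        tree = tb.outgroup_root(
            tb.neighbor_joining(build_matrix(recs)), {"C_1", "D_1"})
        mp = pd.DataFrame({
            "element_id": list(recs),
            "taxon": [e.rsplit("_", 1)[0] for e in recs]})
        conflicts, rf = hm.topology_conflicts(tree, host, mp)
        assert conflicts == [] and rf == 0

    def test_fixture_conflict_on_benazzii_maretimi(
            self, distmats_mod, mapping_mod, host_mod):
        nt, _ = distmats_mod
        sub = nt.submatrix([l for l in nt.labels if l != "R2BggB"])
        tree = tb.outgroup_root(tb.neighbor_joining(sub),
                                {"R2Ba", "R2BggA"})
        conflicts, rf = hm.topology_conflicts(tree, host_mod,
                                              mapping_mod)
        assert rf > 0
        assert any(c["host_clade"] == frozenset({"benazzii", "maretimi"})
                   for c in conflicts)

    def test_shuffled_mapping_conflicts(self):
        import pandas as pd
        host = parse_dated_newick("((A:1,B:1):1,(C:1,D:1):1);")
        recs, _, _ = _sim_on(host, seed=1)
        tree = tb.midpoint_root(tb.neighbor_joining(build_matrix(recs)))
        mp = pd.DataFrame({
            "element_id": list(recs),
            "taxon": ["A", "C", "B", "D"],  # scrambled
        })
        _, rf = hm.topology_conflicts(tree, host, mp)
        assert rf > 0


def _sim_on(host, seed):
    from r2ht.simulate import SimulationConfig, simulate
    return simulate(SimulationConfig(host=host, rate=0.05,
                                     seq_length=1000, seed=seed))


class TestEvents:
    def test_empty_candidates(self, host_mod, mapping_mod, distmats_mod):
        nt, _ = distmats_mod
        lp = hm.assign_lineages(nt)
        tree = tb.neighbor_joining(
            nt.submatrix([l for l in nt.labels if l != "R2BggB"]))
        assert hm.reconstruct_events(set(), lp, tree, host_mod,
                                     mapping_mod) == []

    def test_fixture_reconstructs_two_events(
            self, fixture_model, distmats_mod, host_mod, six_ht_pairs):
        from r2ht.io import load_fixture_indel_profiles
        nt, _ = distmats_mod
        sub = nt.submatrix([l for l in nt.labels if l != "R2BggB"])
        tree = tb.outgroup_root(tb.neighbor_joining(sub),
                                {"R2Ba", "R2BggA"})
        tree = tb.calibrate_ages(tree, [("R2Brfun", "R2Brdeg", 5.4),
                                        ("R2BggA", "R2Ba", 15.4)])
        res = fixture_model.fit()
        events = res.reconstruct_events(
            tree, indel_profiles=load_fixture_indel_profiles())
        assert len(events) == 2
        by_hub = {e.hub: e for e in events}
        # old event: rossius element seeded the benazzii/maretimi clade
        e1 = by_hub["R2Brfun"]
        assert e1.donor_taxa == frozenset({"rossius"})
        assert e1.recipient_taxa == frozenset({"benazzii", "maretimi"})
        assert all(e1.criteria.values())
        # recent event: the deletion-carrying copy came back to rossius
        e2 = by_hub["R2Brdel"]
        assert e2.recipient_taxa == frozenset({"rossius"})
        assert "maretimi" in e2.donor_taxa
        assert e2.age_upper_bound_myr < e1.age_upper_bound_myr
        assert {p for e in events for p in e.supporting_pairs} \
            == six_ht_pairs
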