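"""Binding ratios, mean + k*SD thresholds, intersections, BH testing, S-values."""

import numpy as np
import pandas as pd
import pytest

import immunosig as ims
from immunosig.fixtures import load_reference_signature
from immunosig.synthetic_cohort import GroupSpec
from tests.conftest import make_matrix


def _two_group_matrix(case_vals, control_vals):
    """Linear-scale matrix with one column per mouse, two strains."""
    case_vals = np.atleast_2d(np.asarray(case_vals, dtype=float))
    control_vals = np.atleast_2d(np.asarray(control_vals, dtype=float))
    records, cols = [], {}
    for i in range(case_vals.shape[1]):
        sid = f"case{i + 1}"
        records.append(ims.SampleRecord(sample_id=sid, mouse_id=sid,
                                        strain="MRL/lpr", age_months=4.0))
        cols[sid] = case_vals[:, i]
    for i in range(control_vals.shape[1]):
        sid = f"ctrl{i + 1}"
        records.append(ims.SampleRecord(sample_id=sid, mouse_id=sid,
                                        strain="C3H/HeJ", age_months=4.0))
        cols[sid] = control_vals[:, i]
    samples = ims.array_io.samples_frame(records)
    values = pd.DataFrame(cols, index=[f"pep_{i + 1}" for i in range(case_vals.shape[0])])
    return ims.IntensityMatrix(values, samples, scale="median_normalized")


CASE = ims.SampleFilter(strain="MRL/lpr")
CONTROL = ims.SampleFilter(strain="C3H/HeJ")
CONTRAST = ims.ContrastSpec("test", CASE, CONTROL)


class TestBindingRatio:
    def test_simple_means(self):
        m = _two_group_matrix([[4.0]], [[2.0]])
        assert ims.binding_ratio(m, CONTRAST).tolist() == [2.0]

    def test_identical_groups_give_unit_ratios(self, rng):
        vals = np.abs(rng.normal(2, 0.5, size=(20, 2))) + 0.1
        m = _two_group_matrix(vals, vals)
        np.testing.assert_allclose(ims.binding_ratio(m, CONTRAST).to_numpy(), 1.0)

    def test_matches_brute_force_loop(self, rng):
        case = np.abs(rng.normal(3, 1, size=(50, 4))) + 0.1
        ctrl = np.abs(rng.normal(2, 1, size=(50, 3))) + 0.1
        m = _two_group_matrix(case, ctrl)
        ratios = ims.binding_ratio(m, CONTRAST)
        for p in range(50):
            expected = case[p].mean() / ctrl[p].mean()
            assert ratios.iloc[p] == pytest.approx(expected)

    def test_log_scale_rejected(self, rng):
        m = make_matrix(rng.normal(size=(5, 2)), n_mice=2, scale="log10")
        with pytest.raises(ValueError, match="linear"):
            ims.binding_ratio(m, ims.ContrastSpec("x", ims.SampleFilter(mouse_ids=("m1",)),
                                                  ims.SampleFilter(mouse_ids=("m2",))))


class TestComputeThreshold:
    def test_constant_control_intensities_collapse_to_their_value(self, rng):
        m = _two_group_matrix(np.full((5, 2), 4.0), np.full((5, 2), 2.0))
        ratios = ims.binding_ratio(m, CONTRAST)
        rule = ims.compute_threshold(m, CONTRAST, ratios, ims.ThresholdRule(k=7.0))
        assert rule.tau == pytest.approx(2.0)  # SD across peptides is 0

    def test_hand_computed_control_distribution(self):
        m = _two_group_matrix(np.full((3, 1), 9.0), np.array([[1.0], [2.0], [3.0]]))
        ratios = ims.binding_ratio(m, CONTRAST)
        rule = ims.compute_threshold(m, CONTRAST, ratios, ims.ThresholdRule(k=1.5))
        assert rule.tau == pytest.approx(2.0 + 1.5 * np.std([1, 2, 3], ddof=1))

    def test_ratio_distribution_reference(self, rng):
        case = np.abs(rng.normal(3, 1, size=(30, 3))) + 0.1
        ctrl = np.abs(rng.normal(2, 1, size=(30, 3))) + 0.1
        m = _two_group_matrix(case, ctrl)
        ratios = ims.binding_ratio(m, CONTRAST)
        rule = ims.compute_threshold(
            m, CONTRAST, ratios, ims.ThresholdRule(k=2.0, reference="ratio_distribution")
        )
        assert rule.tau == pytest.approx(ratios.mean() + 2.0 * ratios.std(ddof=1))

    def test_per_peptide_control_reference(self, rng):
        ctrl = np.abs(rng.normal(2, 0.3, size=(10, 4))) + 0.1
        m = _two_group_matrix(np.full((10, 2), 5.0), ctrl)
        ratios = ims.binding_ratio(m, CONTRAST)
        rule = ims.compute_threshold(
            m, CONTRAST, ratios, ims.ThresholdRule(k=1.0, reference="per_peptide_control")
        )
        mu, sd = ctrl.mean(axis=1), ctrl.std(axis=1, ddof=1)
        np.testing.assert_allclose(rule.tau.to_numpy(), (mu + sd) / mu)

    def test_single_peptide_sd_undefined(self):
        m = _two_group_matrix([[4.0]], [[2.0]])
        with pytest.raises(ValueError, match="single peptide"):
            ims.compute_threshold(m, CONTRAST, ims.binding_ratio(m, CONTRAST),
                                  ims.ThresholdRule(k=1.5))


class TestSelectSignature:
    def test_zero_sd_reference_with_equal_ratios_selects_nothing(self):
        ratios = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        rule = ims.ThresholdRule(k=1.5, tau=2.0)
        assert len(ims.select_signature(ratios, rule)) == 0  # strict inequality

    def test_strict_inequality_at_the_boundary(self):
        ratios = pd.Series([1.0, 2.0, 5.0], index=list("abc"))
        pset = ims.select_signature(ratios, ims.ThresholdRule(k=0, tau=2.0))
        assert set(pset.members.index) == {"c"}
        assert pset.members.loc["c", "ratio"] == 5.0

    def test_prefilter_mask_gates_selection(self):
        ratios = pd.Series([5.0, 5.0], index=list("ab"))
        mask = pd.Series([True, False], index=list("ab"))
        pset = ims.select_signature(ratios, ims.ThresholdRule(k=0, tau=1.0),
                                    prefilter_mask=mask)
        assert set(pset.members.index) == {"a"}

    def test_noise_free_recovery_of_forty_spikes_in_five_hundred(self):
        lib = ims.generate_library(n=500, seed=13)
        eff = ims.EffectModel.random(lib, seed=13, n_diagnostic=40, n_behavior=0,
                                     n_predictive=0, fold_log10_sd=0.0)
        noise = ims.NoiseModel(seed=13).silent()
        design = ims.CohortDesign(groups=(GroupSpec("MRL/lpr", 4.0, 3),
                                          GroupSpec("C3H/HeJ", 4.0, 3)))
        m = ims.generate_cohort(lib, design, eff, noise)
        avg = ims.delog10(ims.average_technical_replicates(
            ims.log10_transform(ims.median_normalize(m))))
        ratios = ims.binding_ratio(avg, CONTRAST)
        rule = ims.compute_threshold(avg, CONTRAST, ratios, ims.ThresholdRule(k=1.5))
        selected = set(ims.select_signature(ratios, rule).members.index)
        assert selected == set(eff.diagnostic)

    def test_raising_k_never_grows_the_signature(self, rng):
        case = np.abs(rng.normal(3, 1.5, size=(200, 3))) + 0.1
        ctrl = np.abs(rng.normal(2, 1.0, size=(200, 3))) + 0.1
        m = _two_group_matrix(case, ctrl)
        ratios = ims.binding_ratio(m, CONTRAST)
        previous = None
        for k in (0.0, 0.25, 1.0, 1.5, 2.5, 4.0):
            rule = ims.compute_threshold(m, CONTRAST, ratios, ims.ThresholdRule(k=k))
            members = set(ims.select_signature(ratios, rule).members.index)
            if previous is not None:
                assert members <= previous
            previous = members

    def test_global_intensity_rescaling_leaves_signatures_unchanged(self):
        lib = ims.generate_library(n=300, seed=21)
        eff = ims.EffectModel.random(lib, seed=21, n_diagnostic=10, n_behavior=0,
                                     n_predictive=0)
        design = ims.CohortDesign(groups=(GroupSpec("MRL/lpr", 4.0, 3),
                                          GroupSpec("C3H/HeJ", 4.0, 3)))
        raw = ims.generate_cohort(lib, design, eff, ims.NoiseModel(seed=21))

        def run(matrix):
            avg = ims.delog10(ims.average_technical_replicates(
                ims.log10_transform(ims.median_normalize(matrix))))
            ratios = ims.binding_ratio(avg, CONTRAST)
            rule = ims.compute_threshold(avg, CONTRAST, ratios, ims.ThresholdRule(k=1.5))
            return set(ims.select_signature(ratios, rule).members.index)

        scaled = ims.IntensityMatrix(raw.values * 37.5, raw.samples, raw.scale)
        assert run(raw) == run(scaled)


class TestPrefilterGreater:
    A = ims.SampleFilter(phenotype="high_floater")
    B = ims.SampleFilter(phenotype="low_floater")

    def _matrix(self, high, low):
        high, low = np.atleast_2d(high), np.atleast_2d(low)
        records, cols = [], {}
        for i in range(high.shape[1]):
            sid = f"h{i + 1}"
            records.append(ims.SampleRecord(sample_id=sid, mouse_id=sid,
                                            strain="MRL/lpr", age_months=4.0,
                                            phenotype="high_floater"))
            cols[sid] = high[:, i]
        for i in range(low.shape[1]):
            sid = f"l{i + 1}"
            records.append(ims.SampleRecord(sample_id=sid, mouse_id=sid,
                                            strain="MRL/lpr", age_months=4.0,
                                            phenotype="low_floater"))
            cols[sid] = low[:, i]
        samples = ims.array_io.samples_frame(records)
        values = pd.DataFrame(cols, index=[f"pep_{i + 1}" for i in range(high.shape[0])])
        return ims.IntensityMatrix(values, samples, scale="median_normalized")

    def test_equal_groups_all_false(self, rng):
        vals = np.abs(rng.normal(2, 0.5, size=(10, 2))) + 0.1
        m = self._matrix(vals, vals)
        assert not ims.prefilter_greater(m, self.A, self.B).any()

    def test_single_peptide_strictly_greater(self):
        m = self._matrix([[3.0]], [[2.0]])
        assert ims.prefilter_greater(m, self.A, self.B).tolist() == [True]

    def test_matches_brute_force_comparison(self, rng):
        high = np.abs(rng.normal(2, 1, size=(40, 3))) + 0.1
        low = np.abs(rng.normal(2, 1, size=(40, 2))) + 0.1
        m = self._matrix(high, low)
        mask = ims.prefilter_greater(m, self.A, self.B)
        expected = high.mean(axis=1) > low.mean(axis=1)
        np.testing.assert_array_equal(mask.to_numpy(), expected)

    def test_empty_group_rejected(self, rng):
        vals = np.abs(rng.normal(2, 1, size=(5, 2))) + 0.1
        m = self._matrix(vals, vals)
        with pytest.raises(ValueError, match="non-empty"):
            ims.prefilter_greater(m, self.A, ims.SampleFilter(strain="C3H/HeJ"))


def _pset(name, ids, study=1, ratios=None, seqs=None):
    members = pd.DataFrame(
        {"ratio": ratios if ratios is not None else np.linspace(2.5, 3.5, len(ids))},
        index=pd.Index(ids, name="peptide_id"),
    )
    if seqs is not None:
        members.insert(0, "sequence", seqs)
    return ims.PeptideSet(name=name, members=members, provenance={"study": study})


class TestIntersectSignatures:
    def test_basic_intersection(self):
        inter = ims.intersect_signatures(
            _pset("a", ["p1", "p2", "p3"], study=1),
            _pset("b", ["p2", "p3", "p4"], study=2),
        )
        assert set(inter.members.index) == {"p2", "p3"}
        assert {"ratio_study1", "ratio_study2"} <= set(inter.members.columns)

    def test_disjoint_sets_yield_empty(self):
        inter = ims.intersect_signatures(_pset("a", ["p1"]), _pset("b", ["p2"], study=2))
        assert len(inter) == 0

    def test_commutative_and_associative_on_member_ids(self, rng):
        universe = [f"p{i}" for i in range(30)]
        sets = [
            _pset(name, sorted(rng.choice(universe, size=12, replace=False)), study=s)
            for name, s in (("a", 1), ("b", 2), ("c", 1))
        ]
        a, b, c = sets
        assert (ims.intersect_signatures(a, b).ids
                == ims.intersect_signatures(b, a).ids)
        left = ims.intersect_signatures(ims.intersect_signatures(a, b), c)
        right = ims.intersect_signatures(a, ims.intersect_signatures(b, c))
        assert left.ids == right.ids

    def test_mismatched_libraries_rejected(self):
        a = _pset("a", ["p1"], seqs=["AAAGSC"])
        b = _pset("b", ["p1"], study=2, seqs=["WWWGSC"])
        with pytest.raises(ValueError, match="different libraries"):
            ims.intersect_signatures(a, b)

    def test_shared_reference_sequence_flagged_across_published_sets(self):
        # this sequence appears in both the lupus-diagnostic and the
        # behavior-diagnostic published tables
        diag = load_reference_signature("diagnostic_lupus")
        behav = load_reference_signature("behavior_diagnostic")
        seq = "AQLGMYGVYRPVEIWPDGSC"
        assert seq in diag.members.index and seq in behav.members.index
        flagged = ims.flag_memberships(diag, {"behavior_diagnostic": behav})
        assert bool(flagged.members.loc[seq, "in_behavior_diagnostic"])


class TestDifferentialBinding:
    def _log_matrix(self, case, ctrl):
        m = _two_group_matrix(np.exp(case), np.exp(ctrl))
        return ims.IntensityMatrix(np.log10(m.values), m.samples, "log10")

    def test_identical_distributions_yield_no_discoveries(self, rng):
        vals = rng.normal(0, 0.3, size=(50, 3))
        table = ims.differential_binding(self._log_matrix(vals, vals), CONTRAST)
        assert table["significant"].sum() == 0

    def test_bh_qvalues_match_hand_rolled_step_up(self, rng):
        from tests.bh_oracle import bh_step_up

        for _ in range(10):
            case = rng.normal(0, 1, size=(30, 4))
            ctrl = rng.normal(0.3, 1, size=(30, 4))
            table = ims.differential_binding(self._log_matrix(case, ctrl), CONTRAST)
            np.testing.assert_allclose(
                table["q"].to_numpy(), bh_step_up(table["p"].to_numpy()), rtol=1e-10
            )

    def test_small_group_rejected(self, rng):
        m = self._log_matrix(rng.normal(size=(5, 1)), rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match=">= 2 mice"):
            ims.differential_binding(m, CONTRAST)


class TestSValue:
    @pytest.mark.parametrize("odd, even, expected", [(0.5, 0.2, 0.3), (0.1, 0.2, -0.1)])
    def test_difference_including_negative_results(self, odd, even, expected):
        assert ims.s_value(odd, even) == pytest.approx(expected)

    def test_clone_positivity_rule(self):
        assert ims.clone_positive(0.11)
        assert not ims.clone_positive(0.1)  # strictly above the 0.1 OD cutoff
        assert not ims.clone_positive(-0.05)

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            ims.s_value(-0.1, 0.0)
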