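"""Tests for superposition, Fnat/LRMS/IRMS, classification and cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pepiface.capri import (
    QUALITY_ORDER,
    classify_quality,
    evaluate,
    fnat,
    irms,
    kabsch_superpose,
    lrms,
    native_contacts,
    summarize_cohort,
)
from pepiface.fixtures import load_fixture
from pepiface.synthetic import DecoySpec, ToyComplexParams, make_decoy, make_toy_complex

from .conftest import brute_force_residue_contacts, random_rigid_transform


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(-5, 5, (10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_90deg_rotation(self):
        pts = np.random.default_rng(1).uniform(-5, 5, (12, 3))
        true_rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        target = pts @ true_rot.T
        rot, _, rmsd = kabsch_superpose(pts, target)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot, true_rot, atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_degenerate(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)

    def test_matches_independent_minimizer(self):
        # noisy correspondence: sigma = 0.1 A, n = 50, seeded
        rng = np.random.default_rng(2024)
        mobile = rng.uniform(-8, 8, (50, 3))
        true_rot = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        target = mobile @ true_rot.T + np.array([1.0, -2.0, 3.0])
        target += rng.normal(0, 0.1, target.shape)
        _, _, rmsd = kabsch_superpose(mobile, target)

        def rmsd_of_rotvec(rv):
            rot = Rotation.from_rotvec(rv).as_matrix()
            moved = mobile @ rot.T
            shift = (target - moved).mean(axis=0)
            return float(np.sqrt(((moved + shift - target) ** 2).sum(axis=1).mean()))

        # quaternion grid seed + derivative-free refinement, independent of SVD
        grid = Rotation.random(500, random_state=np.random.RandomState(99)).as_rotvec()
        best = min(grid, key=rmsd_of_rotvec)
        res = minimize(rmsd_of_rotvec, best, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
        assert rmsd == pytest.approx(res.fun, abs=1e-3)
        assert rmsd <= res.fun + 1e-9  # Kabsch is the true optimum


class TestFnat:
    def test_model_equals_reference(self, toy_complex, toy_spec):
        model, _ = toy_complex
        assert fnat(model, model, toy_spec) == 1.0

    def test_far_translation_zero(self, toy_complex, toy_spec):
        model, _ = toy_complex
        decoy = make_decoy(model, DecoySpec(translation=(100.0, 0, 0)), toy_spec)
        assert fnat(decoy, model, toy_spec) == 0.0

    def test_no_native_contacts_undefined(self, toy_spec):
        model, contacts = make_toy_complex(ToyComplexParams("IREKL", gap=100.0))
        assert contacts == []
        assert fnat(model, model, toy_spec) is None

    def test_matches_brute_force_enumeration(self, toy_complex, toy_spec):
        model, _ = toy_complex
        for seed in range(5):
            decoy = make_decoy(model, DecoySpec.random(seed, max_translation=4.0), toy_spec)
            ref_contacts = brute_force_residue_contacts(model, toy_spec, 5.0)
            mod_contacts = brute_force_residue_contacts(decoy, toy_spec, 5.0)
            expected = len(ref_contacts & mod_contacts) / len(ref_contacts)
            assert fnat(decoy, model, toy_spec) == pytest.approx(expected, abs=1e-12)

    def test_native_contacts_match_generator_truth(self, toy_complex, toy_spec):
        model, contacts = toy_complex
        assert native_contacts(model, toy_spec, 5.0) == set(contacts)


class TestLrms:
    def test_zero_for_identity(self, toy_complex, toy_spec):
        model, _ = toy_complex
        assert lrms(model, model, toy_spec) == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_exact(self, toy_complex, toy_spec):
        model, _ = toy_complex
        decoy = make_decoy(model, DecoySpec(translation=(0.0, 4.0, 0.0)), toy_spec)
        assert lrms(decoy, model, toy_spec) == pytest.approx(4.0, abs=1e-9)

    def test_global_rigid_motion_invariance(self, toy_complex, toy_spec):
        model, _ = toy_complex
        decoy = make_decoy(model, DecoySpec.random(11), toy_spec)
        base = lrms(decoy, model, toy_spec)
        rng = np.random.default_rng(12)
        rot, trans = random_rigid_transform(rng)
        moved = decoy.transformed(rotation=rot, translation=trans)
        assert lrms(moved, model, toy_spec) == pytest.approx(base, abs=1e-8)


class TestIrms:
    def test_zero_for_identity(self, toy_complex, toy_spec):
        model, _ = toy_complex
        assert irms(model, model, toy_spec) == pytest.approx(0.0, abs=1e-9)

    def test_global_rotation_of_model_zero(self, toy_complex, toy_spec):
        model, _ = toy_complex
        rng = np.random.default_rng(3)
        rot, trans = random_rigid_transform(rng)
        moved = model.transformed(rotation=rot, translation=trans)
        assert irms(moved, model, toy_spec) == pytest.approx(0.0, abs=1e-8)

    def test_matches_definition_oracle(self, toy_complex, toy_spec):
        model, _ = toy_complex
        decoy = make_decoy(model, DecoySpec.random(21, max_translation=3.0), toy_spec)
        # independent recomputation from the definition, using
        # scipy's align_vectors instead of the package Kabsch
        pairs = brute_force_residue_contacts(model, toy_spec, 10.0)
        keys = {k for pair in pairs for k in pair}
        mod_pts, ref_pts = [], []
        for chain in ("A", "C"):
            for res_ref in model.chains[chain]:
                if res_ref.key not in keys:
                    continue
                res_mod = decoy.residue(*res_ref.key)
                for name in ("N", "CA", "C", "O"):
                    a_ref, a_mod = res_ref.atom(name), res_mod.atom(name)
                    if a_ref is not None and a_mod is not None:
                        ref_pts.append(a_ref.coords)
                        mod_pts.append(a_mod.coords)
        mod_pts, ref_pts = np.array(mod_pts), np.array(ref_pts)
        rot, expected = Rotation.align_vectors(
            ref_pts - ref_pts.mean(axis=0), mod_pts - mod_pts.mean(axis=0)
        )
        # align_vectors rssd -> rmsd
        expected_rmsd = expected / np.sqrt(len(mod_pts))
        assert irms(decoy, model, toy_spec) == pytest.approx(expected_rmsd, abs=1e-6)

    def test_pure_translation_positive(self, toy_complex, toy_spec):
        model, _ = toy_complex
        decoy = make_decoy(model, DecoySpec(translation=(0.0, 2.0, 0.0)), toy_spec)
        assert irms(decoy, model, toy_spec) > 0

    def test_empty_interface_rejected(self, toy_spec):
        model, _ = make_toy_complex(ToyComplexParams("IREKL", gap=100.0))
        with pytest.raises(ValueError, match="interface"):
            irms(model, model, toy_spec)


class TestClassification:
    @pytest.mark.parametrize(
        "fnat_v,lrms_v,irms_v,expected",
        [
            (0.9, 0.8, 0.4, "High"),
            (0.55, 1.5, 0.9, "Medium"),
            (0.0, 50.0, 30.0, "Incorrect"),
            (0.3, 4.0, 1.5, "Acceptable"),
            (0.9, 0.8, 0.6, "Medium"),  # irms blocks High
            (0.15, 0.1, 0.1, "Incorrect"),  # fnat blocks everything
        ],
    )
    def test_examples(self, fnat_v, lrms_v, irms_v, expected):
        quality, _ = classify_quality(fnat_v, lrms_v, irms_v)
        assert quality == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_quality(0.5, -1.0, 0.5)

    def test_undefined_fnat_flagged(self):
        quality, flags = classify_quality(None, 0.5, 0.3)
        assert flags["fnat_ignored"]
        assert quality == "High"

    @settings(max_examples=200, deadline=None)
    @given(
        fnat_v=st.floats(0, 1),
        lrms_v=st.floats(0, 10),
        irms_v=st.floats(0, 5),
        which=st.sampled_from(["fnat", "lrms", "irms"]),
        delta=st.floats(0.01, 2.0),
    )
    def test_monotone_improvement_never_lowers_class(
        self, fnat_v, lrms_v, irms_v, which, delta
    ):
        base, _ = classify_quality(fnat_v, lrms_v, irms_v)
        if which == "fnat":
            improved, _ = classify_quality(min(fnat_v + delta, 1.0), lrms_v, irms_v)
        elif which == "lrms":
            improved, _ = classify_quality(fnat_v, max(lrms_v - delta, 0.0), irms_v)
        else:
            improved, _ = classify_quality(fnat_v, lrms_v, max(irms_v - delta, 0.0))
        assert QUALITY_ORDER.index(improved) >= QUALITY_ORDER.index(base)

    def test_evaluate_rigid_invariance(self, toy_complex, toy_spec):
        model, _ = toy_complex
        decoy = make_decoy(model, DecoySpec.random(31, max_translation=2.0), toy_spec)
        base = evaluate(decoy, model, toy_spec)
        rng = np.random.default_rng(8)
        rot, trans = random_rigid_transform(rng)
        moved = decoy.transformed(rotation=rot, translation=trans)
        again = evaluate(moved, model, toy_spec)
        assert again.quality == base.quality
        assert again.fnat == pytest.approx(base.fnat, abs=1e-12)
        assert again.lrms == pytest.approx(base.lrms, abs=1e-8)
        assert again.irms == pytest.approx(base.irms, abs=1e-8)


class TestCaOnlyModels:
    def _strip_to_ca(self, model):
        stripped = model.copy()
        for chain in stripped.chains.values():
            for res in chain:
                res.atoms = [a for a in res.atoms if a.name == "CA"]
        return stripped

    def test_ca_only_metrics_and_descriptor(self, toy_complex, toy_spec):
        model, _ = toy_complex
        decoy = make_decoy(model, DecoySpec(translation=(2.0, 0, 0)), toy_spec)
        ca_decoy = self._strip_to_ca(decoy)
        result = evaluate(ca_decoy, model, toy_spec)
        assert result.atoms_used == "CA-only"
        assert result.lrms == pytest.approx(2.0, abs=1e-9)
        if result.fnat is not None:
            assert result.fnat_low_confidence


class TestCohorts:
    def test_table4_ca_medoid_13pct(self):
        frame = load_fixture("table4")
        summary = summarize_cohort(frame["CA_Medoid"].tolist(), 1.0)
        assert len(summary.values) == 15
        assert summary.fraction_below == 13

    def test_table4_ca_filtered_33pct(self):
        frame = load_fixture("table4")
        assert summarize_cohort(frame["CA_Filtered"].tolist(), 1.0).fraction_below == 33

    def test_table4_ca_lowest_67pct(self):
        frame = load_fixture("table4")
        assert summarize_cohort(frame["CA_Lowest"].tolist(), 1.0).fraction_below == 67

    def test_all_below_100pct(self):
        assert summarize_cohort([0.1, 0.2, 0.3], 1.0).fraction_below == 100

    def test_strictly_below(self):
        assert summarize_cohort([1.0, 0.5], 1.0).fraction_below == 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort([], 1.0)

    def test_half_up_rounding(self):
        # 1/8 = 12.5% rounds up to 13
        assert summarize_cohort([0.5] + [2.0] * 7, 1.0).fraction_below == 13
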