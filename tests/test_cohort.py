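import numpy as np
import pytest

from alspheno import schema
from alspheno.cohort import (CohortSpec, PhenotypeLabel,
                             generate_clinical_features,
                             generate_connectivity_matrix, generate_cohort,
                             generate_cst_features, generate_tissue_volumes,
                             load_cohort, sample_fd_features,
                             sample_graph_features, save_cohort)
from alspheno.fractal import (binarize_probability_map,
                              estimate_box_counting_fd, skeletonize_3d)
from alspheno.graphs import compute_assortativity, compute_degree_density


class TestSpecAndLabels:
    def test_phenotype_coding_bijection(self):
        for code, name in enumerate(schema.PHENOTYPE_NAMES):
            assert PhenotypeLabel(code).name == name
            assert PhenotypeLabel.from_name(name).code == code
        with pytest.raises(ValueError):
            PhenotypeLabel(5)

    def test_default_group_sizes(self):
        spec = CohortSpec()
        assert spec.group_sizes == {"Control": 15, "ALS-CST+": 21,
                                    "ALS-CST-": 26, "ALS-Cl": 23,
                                    "ALS-FTD": 21}
        assert spec.n_subjects == 106

    @pytest.mark.parametrize("bad", [
        dict(group_sizes={"Control": 0}),
        dict(missing_rate=1.5),
        dict(effect_config={"graph": {"ALS-FTD": -0.5}}),
        dict(effect_config={"graph": {"ALS-FTD": float("inf")}}),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            CohortSpec(**bad)

    def test_signed_assortativity_effect_allowed(self):
        CohortSpec(effect_config={"assortativity_ad": {"ALS-FTD": -0.8}})


class TestTissueVolumes:
    def test_deterministic_and_bounded(self):
        spec = CohortSpec()
        wm1, gm1 = generate_tissue_volumes("Control", spec, seed=3)
        wm2, gm2 = generate_tissue_volumes("Control", spec, seed=3)
        assert np.array_equal(wm1, wm2) and np.array_equal(gm1, gm2)
        for arr in (wm1, gm1):
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_tissues_disjoint_with_contact(self):
        wm, gm = generate_tissue_volumes("Control", CohortSpec(), seed=1)
        wm_b = binarize_probability_map(wm).grid
        gm_b = binarize_probability_map(gm).grid
        assert not (wm_b & gm_b).any()
        # contact: some WM voxel has a GM voxel within its 26-neighbourhood
        from scipy import ndimage
        grown = ndimage.binary_dilation(
            wm_b, structure=ndimage.generate_binary_structure(3, 3))
        assert (grown & gm_b).any()

    def test_wm_skeleton_fd_reduced_in_ftd(self):
        """Branching-density effect: WM skeleton FD lower in ALS-FTD."""
        spec = CohortSpec()
        means = {}
        for group in ("Control", "ALS-FTD"):
            vals = []
            for seed in range(10):
                wm, _ = generate_tissue_volumes(group, spec, seed)
                skel = skeletonize_3d(binarize_probability_map(wm))
                vals.append(estimate_box_counting_fd(skel).fd)
            means[group] = np.mean(vals)
        assert means["ALS-FTD"] < means["Control"]


class TestConnectivityMatrices:
    def test_construction_invariants(self):
        m = generate_connectivity_matrix("Control", "FA", CohortSpec(), seed=0)
        assert m.weights.shape == (90, 90)
        assert np.allclose(m.weights, m.weights.T)
        assert (np.diag(m.weights) == 0).all()
        assert (m.weights >= 0).all()

    def test_deterministic(self):
        spec = CohortSpec()
        a = generate_connectivity_matrix("ALS-Cl", "MD", spec, seed=7)
        b = generate_connectivity_matrix("ALS-Cl", "MD", spec, seed=7)
        assert np.array_equal(a.weights, b.weights)

    def test_unknown_weighting_rejected(self):
        with pytest.raises(ValueError):
            generate_connectivity_matrix("Control", "T1", CohortSpec(), 0)

    def test_ad_assortativity_sign_separates_ftd_from_controls(self):
        spec = CohortSpec()
        means = {}
        for group in ("Control", "ALS-FTD"):
            vals = [compute_assortativity(
                generate_connectivity_matrix(group, "AD", spec, s))
                for s in range(20)]
            means[group] = np.mean(vals)
        assert means["ALS-FTD"] < 0.0 < means["Control"]

    def test_ftd_networks_sparser_than_controls(self):
        spec = CohortSpec()
        dens = {g: np.mean([compute_degree_density(
            generate_connectivity_matrix(g, "FA", spec, s))[1]
            for s in range(10)]) for g in ("Control", "ALS-FTD", "ALS-Cl")}
        assert dens["ALS-FTD"] < dens["Control"]
        assert dens["ALS-FTD"] < dens["ALS-Cl"]


class TestCSTFeatures:
    def test_exact_name_set(self):
        block = generate_cst_features("Control", CohortSpec(), seed=0)
        assert list(block) == schema.cst_feature_names()
        assert len(block) == 32
        assert "FA_Right_CP" in block and "MD_Left_subPMC" in block

    def test_zero_missing_rate_yields_no_nans(self):
        spec = CohortSpec(missing_rate=0.0)
        for seed in range(5):
            block = generate_cst_features("ALS-CST+", spec, seed)
            assert not any(np.isnan(v) for v in block.values())

    def test_full_missing_rate_masks_everything(self):
        block = generate_cst_features("Control", CohortSpec(missing_rate=1.0), 0)
        assert all(np.isnan(v) for v in block.values())

    def test_rostral_right_rd_elevated_in_cst_plus(self):
        spec = CohortSpec()
        means = {g: np.nanmean([generate_cst_features(g, spec, s)["RD_Right_CSoLV"]
                                for s in range(20)])
                 for g in ("Control", "ALS-CST+")}
        assert means["ALS-CST+"] > means["Control"]


class TestClinicalFeatures:
    def test_alsfrs_is_sum_of_subscores(self):
        spec = CohortSpec()
        for group in schema.PHENOTYPE_NAMES:
            for seed in range(5):
                block = generate_clinical_features(group, spec, seed)
                subs = [block[s] for s in schema.ALSFRS_SUBSCORES]
                assert block["ALSFRS-R"] == sum(subs)
                assert all(0 <= s <= 12 for s in subs)

    def test_controls_carry_neutral_convention(self):
        block = generate_clinical_features("Control", CohortSpec(), seed=2)
        assert block["ALSFRS-R"] == 48.0
        assert block["Dur_Symp"] == 0.0
        assert block["El_Escorial"] == 0.0
        assert block["Prog_Rate"] == 0.0

    def test_patients_have_positive_duration_and_progression_definition(self):
        spec = CohortSpec()
        for seed in range(5):
            block = generate_clinical_features("ALS-Cl", spec, seed)
            assert block["Dur_Symp"] > 0
            expected = (48.0 - block["ALSFRS-R"]) / block["Dur_Symp"]
            assert np.isclose(block["Prog_Rate"], expected)

    def test_ftd_functionally_worse_than_controls(self):
        spec = CohortSpec()
        ftd = np.mean([generate_clinical_features("ALS-FTD", spec, s)["ALSFRS-R"]
                       for s in range(20)])
        assert ftd < 48.0


class TestCohortAssembly:
    def test_default_cohort_composition(self):
        bundle = generate_cohort(CohortSpec(seed=5))
        assert len(bundle) == 106
        codes = [r.label.code for r in bundle.records]
        assert set(codes) <= {0, 1, 2, 3, 4}
        assert codes.count(2) == 26  # ALS-CST-
        assert bundle.metadata["mode"] == "fast"

    def test_byte_identical_reproduction(self):
        b1 = generate_cohort(CohortSpec(seed=9))
        b2 = generate_cohort(CohortSpec(seed=9))
        for r1, r2 in zip(b1.records, b2.records):
            assert r1.subject_id == r2.subject_id
            assert r1.label == r2.label
            for attr in ("graph_block", "cst_block", "fd_block",
                         "clinical_block"):
                a, b = getattr(r1, attr), getattr(r2, attr)
                assert list(a) == list(b)
                assert all(x == y or (np.isnan(x) and np.isnan(y))
                           for x, y in zip(a.values(), b.values()))

    def test_full_mode_small_cohort(self):
        spec = CohortSpec(group_sizes={"Control": 1, "ALS-FTD": 1}, seed=3)
        bundle = generate_cohort(spec, mode="full", volume_shape=(36, 36, 36),
                                 n_nulls=2)
        assert len(bundle) == 2
        assert bundle.metadata["mode"] == "full"
        rec = bundle.records[0]
        assert len(rec.graph_block) == 59
        assert len(rec.fd_block) == 20
        assert all(0 < rec.fd_block[k] <= 3 for k in rec.fd_block
                   if k.startswith("FD_"))

    def test_sampled_small_world_identity(self):
        block = sample_graph_features("Control", CohortSpec(), seed=4)
        for w in schema.GRAPH_WEIGHTINGS:
            sigma = block[f"Small world index_{w}"]
            lam = block[f"Normalized path length_{w}"]
            gam = block[f"Normalized clustering_{w}"]
            assert np.isclose(sigma, gam / lam)

    def test_sampled_fd_within_bounds(self):
        for g in schema.PHENOTYPE_NAMES:
            block = sample_fd_features(g, CohortSpec(), seed=1)
            for name, v in block.items():
                if name.startswith("FD_"):
                    assert 0 < v <= 3
            assert block["BPF_WM"] + block["BPF_GM"] <= 100

    def test_roundtrip_serialization(self, tmp_path):
        bundle = generate_cohort(
            CohortSpec(group_sizes={"Control": 2, "ALS-Cl": 2}, seed=8))
        save_cohort(bundle, tmp_path / "cohort")
        loaded = load_cohort(tmp_path / "cohort")
        assert len(loaded) == len(bundle)
        for r1, r2 in zip(bundle.records, loaded.records):
            assert r1.subject_id == r2.subject_id
            assert r1.label.code == r2.label.code
            assert np.allclose(list(r1.graph_block.values()),
                               list(r2.graph_block.values()))
            assert np.allclose(list(r1.cst_block.values()),
                               list(r2.cst_block.values()), equal_nan=True)
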