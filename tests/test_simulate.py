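import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LinearRing

from morphoqtl import pipeline, simulate as sim, stats
from morphoqtl.geometry import outline_area
from morphoqtl.qtl import lod_scan


class TestMakeOutline:
    def test_noise_free_outline_is_mirror_symmetric(self):
        p = sim.ShapeParams(notch_depth=0.2, depression_amp=0.1, rostral_ratio=0.8)
        o = sim.make_outline(p, 100, seed=0)
        mirrored = np.roll((o.points * [1, -1])[::-1], 1, axis=0)
        np.testing.assert_allclose(o.points, mirrored, atol=1e-12)

    def test_sharp_rectangle_area(self):
        p = sim.ShapeParams(rostral_ratio=1.0, corner_round=0.02, notch_depth=0.0,
                            depression_amp=0.0)
        o = sim.make_outline(p, 400, seed=0)
        assert outline_area(o) == pytest.approx(2.0 * 1.0, rel=0.01)

    def test_same_seed_identical(self):
        p = sim.ShapeParams(asymmetry_noise=0.02, landmark_jitter=0.01)
        a = sim.make_outline(p, 100, seed=9, rotation_range=0.3, translation_range=1.0)
        b = sim.make_outline(p, 100, seed=9, rotation_range=0.3, translation_range=1.0)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.control_points, b.control_points)

    def test_points_equally_spaced_along_source_curve(self):
        """Output vertices sit at equal arc-length steps of the dense
        parametric curve (chord lengths only vary where the curve bends)."""
        p = sim.ShapeParams(notch_depth=0.2)
        o = sim.make_outline(p, 100, seed=0)
        dense = sim._parametric_curve(p)
        from morphoqtl.geometry import resample_equal_arclength

        np.testing.assert_allclose(
            o.points, resample_equal_arclength(dense, 100), atol=1e-12
        )

    @pytest.mark.parametrize(
        "bad",
        [
            dict(notch_depth=0.45),
            dict(rostral_ratio=1.7),
            dict(depression_amp=0.6),
            dict(asymmetry_noise=-0.1),
            dict(length=-1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            sim.make_outline(sim.ShapeParams(**bad), 100, seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        dn=st.floats(0.0, 0.39),
        dl=st.floats(0.0, 0.49),
        r=st.floats(0.3, 1.5),
        rho=st.floats(0.05, 1.0),
    )
    def test_simple_outline_or_diagnostic(self, dn, dl, r, rho):
        """Every in-range parameter combination either yields a simple
        (non-self-intersecting) outline or is rejected with the
        self-intersection diagnostic — never a silent bad outline."""
        p = sim.ShapeParams(
            notch_depth=dn, depression_amp=dl, rostral_ratio=r, corner_round=rho
        )
        try:
            o = sim.make_outline(p, 100, seed=0)
        except ValueError as exc:
            assert "self-intersecting" in str(exc)
        else:
            assert LinearRing(o.points).is_simple

    def test_deep_notch_sharp_corners_rejected_with_diagnostic(self):
        p = sim.ShapeParams(notch_depth=0.375, rostral_ratio=0.5, corner_round=0.0625)
        with pytest.raises(ValueError, match="self-intersecting"):
            sim.make_outline(p, 100, seed=0)


class TestGenotypeToParams:
    def arch(self, **kw):
        return sim.study_architecture(**kw)

    def test_all_recipient_homozygous_is_baseline(self):
        arch = self.arch()
        g = {l.name: "B/B" for l in arch.loci}
        out = sim.genotype_to_params(g, arch, sim.B6_PARAMS)
        np.testing.assert_allclose(
            out.geometry_vector(), sim.B6_PARAMS.geometry_vector()
        )

    def test_codominant_heterozygote_is_midpoint(self):
        arch = self.arch()
        hom = {l.name: "B/B" for l in arch.loci}
        hom["Chr1"] = "S/S"
        het = dict(hom, Chr1="B/S")
        v_hom = sim.genotype_to_params(hom, arch, sim.B6_PARAMS).geometry_vector()
        v_het = sim.genotype_to_params(het, arch, sim.B6_PARAMS).geometry_vector()
        v0 = sim.B6_PARAMS.geometry_vector()
        np.testing.assert_allclose(v_het, (v_hom + v0) / 2, atol=1e-12)

    def test_suppression_scales_target_effect(self):
        arch = self.arch(suppression=0.8)
        base = sim.B6_PARAMS
        g_plain = {"Chr1": "S/S", "Chr13": "B/B", "Chr18": "B/B"}
        g_supp = {"Chr1": "S/S", "Chr13": "S/S", "Chr18": "B/B"}
        v0 = base.geometry_vector()
        d_plain = sim.genotype_to_params(g_plain, arch, base).geometry_vector() - v0
        d_supp = sim.genotype_to_params(g_supp, arch, base).geometry_vector() - v0
        # Chr13 has no own effect, so the difference is pure suppression
        np.testing.assert_allclose(d_supp, 0.2 * d_plain, atol=1e-12)

    def test_dominance_codes(self):
        assert sim.dose("B/S", 0.0) == 0.5
        assert sim.dose("B/S", 1.0) == 1.0  # donor dominant
        assert sim.dose("B/S", -1.0) == 0.0  # donor recessive

    def test_missing_locus_rejected(self):
        arch = self.arch()
        with pytest.raises(KeyError):
            sim.genotype_to_params({"Chr1": "B/B"}, arch, sim.B6_PARAMS)


class TestSimulateGenotypes:
    def test_f2_frequencies_one_quarter(self):
        arch = sim.study_architecture()
        gt = sim.simulate_genotypes(arch, "F2", 10000, seed=11)
        frac_bb = np.mean(gt.genotypes["D1Mit306"] == "B/B")
        assert frac_bb == pytest.approx(0.25, abs=0.02)
        frac_bs = np.mean(gt.genotypes["D1Mit306"] == "B/S")
        assert frac_bs == pytest.approx(0.5, abs=0.02)

    def test_congenic_fixed_genotypes(self):
        arch = sim.study_architecture()
        gt = sim.simulate_genotypes(arch, "congenic:Chr18", 10, seed=0)
        assert (gt.genotypes[["D18Mit23", "D18Mit123"]] == "S/S").all().all()
        other = [m for m in gt.marker_names if not m.startswith("D18")]
        assert (gt.genotypes[other] == "B/B").all().all()

    def test_heterozygous_congenic(self):
        arch = sim.study_architecture()
        gt = sim.simulate_genotypes(arch, "congenic:Chr1:het", 5, seed=0)
        assert (gt.genotypes["D1Mit306"] == "B/S").all()

    def test_zero_distance_markers_identical(self):
        rng = np.random.default_rng(3)
        g = sim._f2_gametes(np.array([50.0, 50.0]), 500, rng)
        np.testing.assert_array_equal(g[:, 0], g[:, 1])

    def test_linked_markers_correlated_unlinked_not(self):
        arch = sim.study_architecture()
        gt = sim.simulate_genotypes(arch, "F2", 4000, seed=5)
        d1a = gt.dose("D1Mit84")
        d1b = gt.dose("D1Mit306")  # 5 Mb apart: tight linkage
        d18 = gt.dose("D18Mit123")  # other chromosome
        assert np.corrcoef(d1a, d1b)[0, 1] > 0.8
        assert abs(np.corrcoef(d1a, d18)[0, 1]) < 0.06

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_genotypes(sim.study_architecture(), "F3", 5, seed=0)


class TestGenerateDataset:
    def test_rerun_reproduces_files_byte_identically(self, tmp_path):
        cfg = sim.f2_cross_config(seed=7)
        cfg.groups = cfg.groups[:2]  # small, parental groups only
        sim.generate_dataset(cfg, outdir=tmp_path / "a")
        sim.generate_dataset(cfg, outdir=tmp_path / "b")
        for name in ("outlines.tps", "genotypes.csv", "markers.csv", "design.csv",
                     "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_manifest_records_seed_and_hash(self, tmp_path):
        import json

        cfg = sim.f2_cross_config(seed=13)
        cfg.groups = cfg.groups[:2]
        sim.generate_dataset(cfg, outdir=tmp_path)
        man = json.loads((tmp_path / "manifest.json").read_text())
        assert man["seed"] == 13
        assert man["config_hash"] == cfg.config_hash()

    def test_yaml_config_round_trip(self):
        cfg = sim.f2_cross_config(seed=3)
        back = sim.SimulationConfig.from_yaml(cfg.to_yaml())
        assert back.config_hash() == cfg.config_hash()

    def test_null_architecture_nominal_type_one_error(self):
        """With all genetic effects zero, the two-group Hotelling test on
        retained PCs rejects at about the nominal rate."""
        arch = sim.study_architecture(
            effect_share={"Chr1": 0.0, "Chr13": 0.0, "Chr18": 0.0}
        )
        rejections = 0
        n_rep = 200
        for s in range(n_rep):
            cfg = sim.SimulationConfig(
                b6_params=sim.B6_PARAMS,
                donor_params=sim.DONOR_PARAMS,
                architecture=arch,
                groups=[
                    sim.GroupSpec("g1", "inbred_B6", 15),
                    sim.GroupSpec("g2", "inbred_B6", 15),
                ],
                seed=40000 + s,
            )
            ds = sim.generate_dataset(cfg)
            mat, _, _ = pipeline.coefficient_matrix(ds.outlines)
            space = stats.pca_fit(mat.to_numpy(), 5)
            groups = ds.design.set_index("id")["group"].reindex(mat.index)
            res = stats.hotelling_t2(
                space.scores[(groups == "g1").to_numpy()],
                space.scores[(groups == "g2").to_numpy()],
            )
            rejections += res.p_raw < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.10  # binomial band around the nominal 5%

    def test_lod_increases_with_additive_effect(self):
        """Downstream LOD at the causal marker grows, in expectation, with
        the locus's additive effect (50 replicates per effect level)."""
        lods = {}
        for share, tag in ((0.2, "weak"), (0.8, "strong")):
            arch = sim.study_architecture(
                effect_share={"Chr1": 0.0, "Chr13": 0.0, "Chr18": share}
            )
            delta = sim.DONOR_PARAMS.geometry_vector() - sim.B6_PARAMS.geometry_vector()
            u = delta / np.linalg.norm(delta)
            vals = []
            for s in range(50):
                rng = np.random.default_rng(50000 + s)
                gt = sim.simulate_genotypes(arch, "F2", 91, rng)
                pheno = []
                for ind in gt.genotypes.index:
                    g = {
                        l.name: gt.genotypes.loc[ind, l.causal_marker]
                        for l in arch.loci
                    }
                    vec = sim.genotype_to_params(g, arch, sim.B6_PARAMS).geometry_vector()
                    vec = vec + arch.residual_sd_shared * rng.standard_normal() * u
                    pheno.append(float(vec @ u))
                scan = lod_scan(np.array(pheno), gt)
                vals.append(scan.set_index("marker").loc["D18Mit123", "lod"])
            lods[tag] = np.mean(vals)
        assert lods["strong"] > lods["weak"] + 1.0

    def test_f2_scores_span_parental_means(self, f2_dataset):
        """The F2 discriminant-score distribution covers both parental
        group means (the segregation analogue of the score histogram)."""
        ds = f2_dataset
        res = pipeline.f2_scan(ds, n_perm=100, perm_seed=0)
        scores = res["scores"]
        g = ds.design.set_index("id")["group"]
        b6_mean = scores[g[g == "B6"].index].mean()
        donor_mean = scores[g[g == "66H"].index].mean()
        f2 = scores[g[g == "F2"].index]
        assert f2.min() < donor_mean and f2.max() > b6_mean
        assert b6_mean > 0 > donor_mean  # orientation convention
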