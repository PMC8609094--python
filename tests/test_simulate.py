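import numpy as np
import pytest

from rishharm import simulate as sim
from rishharm.dti import fa_map, fit_tensor, md_map
from rishharm.rish import compute_rish, group_mean_rish, learn_scale_maps
from rishharm.sh import fit_sh, reconstruct_signal


def small_study(snr=30.0, gamma=(1.0, 1.0, 1.0), n_training=3, n_patients=0):
    sites = [
        sim.SiteSpec("ref", 1200.0, 45, snr=snr, n_training=n_training,
                     n_patients=n_patients),
        sim.SiteSpec("tar", 1000.0, 32, snr=snr, gamma=gamma,
                     n_training=n_training, n_patients=n_patients),
    ]
    return sim.SyntheticStudy(sites)


class TestSiteSpec:
    def test_scheme_layout(self):
        s = sim.SiteSpec("x", 1150.0, 61, n_b0=7)
        scheme = s.scheme()
        assert scheme.n_directions == 61
        assert len(scheme.b0_indices) == 7
        assert scheme.shell_bvalue == 1150.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError, match="directions"):
            sim.SiteSpec("x", 1000.0, 4)
        with pytest.raises(ValueError, match="SNR"):
            sim.SiteSpec("x", 1000.0, 30, snr=0.0)
        with pytest.raises(ValueError, match="gamma"):
            sim.SiteSpec("x", 1000.0, 30, gamma=(1.0, -0.5, 1.0))


class TestPhantomGeometry:
    def test_masks_are_consistent(self):
        masks = sim.phantom_masks(sim.PhantomConfig())
        assert masks.skeleton.sum() >= 100
        assert (masks.skeleton & ~masks.wm).sum() == 0
        assert (masks.wm & masks.csf).sum() == 0
        assert (masks.wm & masks.gm).sum() == 0
        assert masks.brain.sum() > masks.wm.sum() + masks.csf.sum()
        assert (masks.severity_weight >= 0.5).all() and (masks.severity_weight <= 1.5).all()


class TestGeneratePhantom:
    def _subject(self, wmh=1.0, group="patient", seed=7):
        return sim.SubjectSpec("s1", "ref", group, 70.0, "F", wmh, seed)

    def test_deterministic_for_fixed_seed(self):
        cfg = sim.PhantomConfig()
        a = sim.generate_phantom(cfg, self._subject())
        b = sim.generate_phantom(cfg, self._subject())
        np.testing.assert_array_equal(a.tensors6, b.tensors6)
        np.testing.assert_array_equal(a.lesion, b.lesion)

    def test_zero_wmh_control_has_no_lesions(self):
        cfg = sim.PhantomConfig()
        truth = sim.generate_phantom(cfg, self._subject(wmh=0.1, group="control"))
        assert truth.lesion.sum() == 0

    def test_lesion_volume_matches_wmh_burden_exactly(self):
        cfg = sim.PhantomConfig()
        truth = sim.generate_phantom(cfg, self._subject(wmh=2.0))
        n_brain = truth.masks.brain.sum()
        assert truth.lesion.sum() == round(2.0 / 100 * n_brain)

    def test_excessive_lesion_volume_raises(self):
        cfg = sim.PhantomConfig()
        with pytest.raises(ValueError, match="exceeds"):
            sim.generate_phantom(cfg, self._subject(wmh=60.0))

    def test_lesions_have_higher_md_and_lower_fa_than_nawm(self):
        # construction check across several patients via the tensor fit
        study = small_study(snr=np.inf, n_training=0, n_patients=4)
        cohort = sim.generate_cohort(study, 3)
        checked = 0
        for sid in cohort.subject_ids(group="patient"):
            truth = cohort.truth(sid)
            if truth.lesion.sum() < 5:
                continue
            dwi = truth.signal(cohort.site(cohort.subject(sid).site).scheme())
            tensors = fit_tensor(dwi)
            md = md_map(tensors)
            fa = fa_map(tensors)
            nawm = truth.masks.wm & ~truth.lesion
            assert np.nanmean(md[truth.lesion]) > np.nanmean(md[nawm])
            assert np.nanmean(fa[truth.lesion]) < np.nanmean(fa[nawm])
            checked += 1
        assert checked >= 2


class TestApplySiteEffect:
    def test_identity_site_noise_free_equals_sh_projection(self):
        study = small_study(snr=np.inf)
        cohort = sim.generate_cohort(study, 1)
        sid = cohort.subject_ids(site="ref")[0]
        truth = cohort.truth(sid)
        scheme = cohort.site("ref").scheme()
        clean = truth.signal(scheme)
        gamma1 = np.ones(study.phantom.shape + (3,))
        out = sim.apply_site_effect(clean, cohort.site("ref"), gamma1, seed=0)
        coeffs = fit_sh(clean, l_max=4, reg_lambda=0.0)
        expected = reconstruct_signal(coeffs, scheme.directions)
        got = out.data[..., ~scheme.b0_mask]
        np.testing.assert_allclose(got[clean.mask], expected[clean.mask], atol=1e-8)

    def test_order2_suppression_lowers_fa_not_md(self):
        study = small_study(snr=np.inf, gamma=(1.0, 0.8, 1.0))
        cohort = sim.generate_cohort(study, 2)
        skel = cohort.masks.skeleton

        def group_mean(site, metric):
            vals = []
            for sid in cohort.subject_ids(site=site, role="training"):
                tensors = fit_tensor(cohort.dwi(sid))
                m = (fa_map if metric == "fa" else md_map)(tensors)
                vals.append(np.nanmean(m[skel]))
            return np.mean(vals)

        fa_ref, fa_tar = group_mean("ref", "fa"), group_mean("tar", "fa")
        md_ref, md_tar = group_mean("ref", "md"), group_mean("tar", "md")
        assert fa_tar < fa_ref - 0.02
        assert abs(md_tar - md_ref) / md_ref < 0.05

    def test_scale_maps_recover_inverse_gamma_in_wm(self):
        # the core parameter-recovery experiment: learned Delta_l ~ 1/gamma_l
        study = small_study(snr=200.0, gamma=(1.0, 0.8, 0.9), n_training=20)
        cohort = sim.generate_cohort(study, 4)
        from rishharm.bmap import map_volume

        def site_mean(site):
            maps = []
            for sid in cohort.subject_ids(site=site, role="training"):
                dwi = map_volume(cohort.dwi(sid), 1000.0)
                maps.append(compute_rish(fit_sh(dwi, l_max=4, reg_lambda=0.0)))
            return group_mean_rish(maps, smoothing_fwhm=0.0)

        delta = learn_scale_maps(site_mean("ref"), site_mean("tar"))
        wm = cohort.masks.wm & cohort.masks.skeleton
        gamma = cohort.gamma_fields["tar"]
        for i in range(3):
            ratio = delta.data[..., i][wm] * gamma[..., i][wm]
            assert np.median(np.abs(ratio - 1.0)) < 0.05

    def test_estimated_b0_snr_matches_configuration(self):
        study = small_study(snr=30.0)
        sites = [sim.SiteSpec(**{**s.__dict__, "n_b0": 8}) for s in study.sites]
        cohort = sim.generate_cohort(sim.SyntheticStudy(sites), 5)
        sid = cohort.subject_ids(site="ref")[0]
        dwi = cohort.dwi(sid)
        snr_hat = sim.estimate_b0_snr(dwi, cohort.masks.wm)
        assert snr_hat == pytest.approx(30.0, rel=0.10)


class TestGenerateCohort:
    def test_schema_and_matching(self):
        study = small_study(n_training=16, n_patients=5)
        cohort = sim.generate_cohort(study, 6)
        t = cohort.table
        assert set(t.columns) >= {"subject_id", "site", "group", "role", "age",
                                  "sex", "wmh_volume", "lesion_seed"}
        assert t.subject_id.is_unique
        assert (t.wmh_volume >= 0).all()
        # training-control ages matched across sites by construction
        ages = t[t.role == "training"].groupby("site").age.mean()
        assert abs(ages["ref"] - ages["tar"]) < 2.0
        # controls stay below the patient WMH floor region
        assert t[t.group == "control"].wmh_volume.max() < 0.5

    def test_full_determinism_under_master_seed(self):
        study = small_study(n_training=2)
        c1 = sim.generate_cohort(study, 11)
        c2 = sim.generate_cohort(study, 11)
        assert c1.table.equals(c2.table)
        sid = c1.table.subject_id.iloc[0]
        np.testing.assert_array_equal(c1.dwi(sid).data, c2.dwi(sid).data)
        np.testing.assert_array_equal(c1.gamma_fields["tar"], c2.gamma_fields["tar"])

    def test_different_seeds_differ(self):
        study = small_study(n_training=2)
        c1 = sim.generate_cohort(study, 11)
        c2 = sim.generate_cohort(study, 12)
        sid = c1.table.subject_id.iloc[0]
        assert not np.array_equal(c1.dwi(sid).data, c2.dwi(sid).data)

    def test_write_round_trip(self, tmp_path):
        from rishharm.pipeline import FileCohort

        study = small_study(n_training=2, snr=np.inf)
        cohort = sim.generate_cohort(study, 13)
        cohort.write(tmp_path / "out")
        fc = FileCohort(tmp_path / "out")
        assert len(fc.table) == len(cohort.table)
        np.testing.assert_array_equal(fc.masks.skeleton, cohort.masks.skeleton)
        sid = cohort.table.subject_id.iloc[0]
        a = cohort.dwi(sid)
        b = fc.dwi(sid)
        np.testing.assert_allclose(b.data, a.data, rtol=1e-6, atol=1e-4)
        np.testing.assert_allclose(b.scheme.bvals, a.scheme.bvals)
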