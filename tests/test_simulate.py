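import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import afdecon as af
from afdecon import reference
from afdecon.simulate import BilirubinResponse, CohortSpec, GroupSpec


class TestGenerateSpectrum:
    def test_deterministic_given_seed(self, liver_lib, liver_sham_means):
        a = af.generate_spectrum(liver_lib, liver_sham_means, seed=5)
        b = af.generate_spectrum(liver_lib, liver_sham_means, seed=5)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_different_seed_differs(self, liver_lib, liver_sham_means):
        a = af.generate_spectrum(liver_lib, liver_sham_means, seed=5)
        b = af.generate_spectrum(liver_lib, liver_sham_means, seed=6)
        assert not np.array_equal(a.intensities, b.intensities)

    def test_total_area_honored(self, liver_lib, liver_sham_means):
        s = af.generate_spectrum(
            liver_lib, liver_sham_means, total_area=4321.0, noise_sigma=0.3, seed=0
        )
        assert s.integrated_area() == pytest.approx(4321.0, rel=1e-9)
        assert s.total_area_au == pytest.approx(4321.0, rel=1e-9)

    def test_noise_free_fit_round_trip(self, serum_lib):
        contribs = {
            k: v for k, (v, _) in reference.SERUM_CONTRIBUTIONS["bdl48"].items()
        }
        total = sum(contribs.values())
        s = af.generate_spectrum(serum_lib, contribs, noise_sigma=0.0, seed=0)
        c = af.fit_spectrum(s, serum_lib).contributions()
        for k, v in contribs.items():
            assert c[k] == pytest.approx(v / total * 100.0, rel=1e-3, abs=1e-3)

    def test_missing_fluorophore_rejected(self, liver_lib):
        with pytest.raises(ValueError, match="missing"):
            af.generate_spectrum(liver_lib, {"proteins": 100.0})


class TestGenerateCohort:
    def test_default_liver_cohort_structure(self):
        spec = af.default_cohort_spec("liver", seed=0)
        spectra, manifest = af.generate_cohort(spec)
        assert len(spectra) == 20  # 4 groups x 5
        assert set(manifest["group"]) == set(reference.GROUP_ORDER)
        assert manifest["sample_id"].is_unique
        # ground truth columns allow recovery scoring
        truth_cols = [c for c in manifest.columns if c.startswith("true_")]
        assert len(truth_cols) == 7
        sums = manifest[truth_cols].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_group_means_near_generating_targets(self):
        spec = af.default_cohort_spec("liver", n=5, seed=1)
        _, manifest = af.generate_cohort(spec)
        for gs in spec.groups:
            sub = manifest[manifest["group"] == gs.name]
            for name, (mean, se) in gs.contributions.items():
                sd = se * np.sqrt(gs.n)
                # sample mean of n draws: SE again ~ se; allow 3x for
                # renormalization distortion
                assert abs(sub[f"true_{name}"].mean() - mean) < 3 * se + 0.5, (
                    gs.name,
                    name,
                )

    def test_artifact_rate_one_fails_qc(self, serum_lib):
        spec = af.default_cohort_spec("serum", n=2, seed=3, artifact_rate=1.0)
        spectra, manifest = af.generate_cohort(spec, lib=serum_lib)
        assert manifest["has_artifact"].all()
        for s in spectra:
            assert not af.detect_hb_reabsorption(s).passed

    def test_zero_n_group_rejected(self):
        with pytest.raises(ValidationError):
            GroupSpec(name="bad", n=0, contributions={"a": (100.0, 1.0)})

    def test_unknown_cohort_key_rejected(self):
        with pytest.raises(ValidationError):
            CohortSpec.model_validate(
                {
                    "tissue": "liver",
                    "groups": [
                        {"name": "g", "n": 2, "contributions": {"proteins": (100, 1)}}
                    ],
                    "instrument": "OMA",
                }
            )

    def test_contributions_far_from_100_rejected(self):
        with pytest.raises(ValidationError, match="100"):
            GroupSpec(name="bad", contributions={"a": (50.0, 1.0)})


class TestInjectHbArtifact:
    def test_depth_zero_identity(self, smooth_serum_spectrum):
        out = af.inject_hb_artifact(smooth_serum_spectrum, 0.0)
        np.testing.assert_array_equal(out.intensities, smooth_serum_spectrum.intensities)

    def test_depth_bounds(self, smooth_serum_spectrum):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                af.inject_hb_artifact(smooth_serum_spectrum, bad)

    def test_notch_reduces_only_near_center(self, smooth_serum_spectrum):
        out = af.inject_hb_artifact(smooth_serum_spectrum, 0.3)
        wl = smooth_serum_spectrum.wavelengths_nm
        ratio = out.intensities / np.maximum(smooth_serum_spectrum.intensities, 1e-12)
        at_center = ratio[np.argmin(np.abs(wl - 555.0))]
        far = ratio[np.argmin(np.abs(wl - 450.0))]
        assert at_center == pytest.approx(0.7, abs=1e-6)
        assert far == pytest.approx(1.0, abs=1e-3)


class TestBilirubinResponse:
    def test_sham_concentration_below_floor(self):
        assert af.bilirubin_response(6e-7) == 0.0

    def test_saturation_plateau(self):
        assert af.bilirubin_response(1e-4) == af.bilirubin_response(5e-5) == 1.0

    def test_floor_boundary_inclusive_zero(self):
        assert af.bilirubin_response(1e-6) == 0.0

    def test_monotone_nondecreasing(self):
        concs = np.logspace(-7, -3.5, 60)
        vals = [af.bilirubin_response(c) for c in concs]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_smooth_knee_still_monotone_and_saturating(self):
        resp = BilirubinResponse(smooth_knee=0.2)
        concs = np.logspace(-7, -3.5, 80)
        vals = [af.bilirubin_response(c, resp) for c in concs]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            af.bilirubin_response(-1e-6)


def test_full_loop_reproduces_qualitative_ordering(liver_lib, serum_lib):
    """Default cohorts, preprocessed and refitted, keep the published
    direction of change: bilirubin and porphyrins rise with ligation time,
    NAD(P)H bound and vitamin A fall, proteins and lipopigments rise."""
    results = {}
    for tissue, lib in (("liver", liver_lib), ("serum", serum_lib)):
        spec = af.default_cohort_spec(tissue, seed=0)
        spectra, manifest = af.generate_cohort(spec)
        rows = {}
        for s in spectra:
            rows[s.sample_id] = af.fit_spectrum(s, lib).contributions()
        df = pd.DataFrame(rows).T.join(
            manifest.set_index("sample_id")["group"]
        )
        results[tissue] = df.groupby("group").mean().loc[list(reference.GROUP_ORDER)]
    serum = results["serum"]
    bdl = ["bdl24", "bdl48", "bdl72"]
    # bilirubin and porphyrins rise with ligation; sham is the floor and
    # 72 h the porphyrin ceiling (adjacent groups overlap within SE)
    assert all(
        serum.loc["sham", "bilirubin_517_530"] < serum.loc[g, "bilirubin_517_530"]
        for g in bdl
    )
    assert all(serum.loc["sham", "red_bands"] < serum.loc[g, "red_bands"] for g in bdl)
    assert serum["red_bands"].idxmax() == "bdl72"
    liver = results["liver"]
    assert liver["nadph_bound"].loc["sham"] > liver["nadph_bound"].loc["bdl72"]
    assert liver["vitamin_a"].loc["sham"] > liver["vitamin_a"].loc["bdl72"]
    assert all(liver.loc["sham", "proteins"] < liver.loc[g, "proteins"] for g in bdl)
    assert liver["proteins"].idxmax() == "bdl72"
    assert liver["lipopigments"].loc["sham"] < liver["lipopigments"].loc["bdl72"]
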