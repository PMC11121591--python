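"""Synthetic cohort generator: determinism, planted structure, fixtures."""

import json

import numpy as np
import pytest

from radgenmap.genomics import default_panel, score_genes
from radgenmap.synthetic import (
    MAX_PLANTED_R,
    CohortConfig,
    ConfigurationError,
    PlantedLink,
    TextureParams,
    generate_cnv_segments,
    generate_cohort,
    generate_roi_image,
    read_fixtures,
    write_fixtures,
)
from radgenmap.texture import roi_features


def small_config(**kw):
    defaults = dict(n_per_group=5, image_size=32, seed=1)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestCohort:
    def test_counts_and_balance(self):
        cohort = generate_cohort(small_config())
        assert len(cohort) == 15
        groups = [p.grade_group for p in cohort]
        assert all(groups.count(g) == 5 for g in (1, 2, 3))
        for p in cohort:
            assert set(p.images) == {"T2WI", "ADC"}

    def test_fixed_seed_is_reproducible(self):
        a = generate_cohort(small_config())
        b = generate_cohort(small_config())
        for pa, pb in zip(a, b):
            assert pa.patient_id == pb.patient_id
            assert pa.qc_score == pb.qc_score
            assert pa.truth == pb.truth
            for m in ("T2WI", "ADC"):
                assert np.array_equal(pa.images[m].pixels, pb.images[m].pixels)
            assert pa.segments == pb.segments

    def test_truth_round_trips_through_scoring(self):
        cohort = generate_cohort(small_config())
        panel = default_panel()
        for p in cohort:
            scores = score_genes(p.segments, panel, sample_ids=[p.patient_id])
            for gene, state in p.truth["gene_states"].items():
                assert scores.loc[p.patient_id, gene] == state

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="n_per_group"):
            generate_cohort(small_config(n_per_group=1))
        with pytest.raises(ConfigurationError, match="image_size"):
            generate_cohort(small_config(image_size=8))
        with pytest.raises(ConfigurationError, match="planted_links"):
            generate_cohort(
                small_config(planted_links=[PlantedLink("P4HA1", "Contrast_T2WI", 0.99)])
            )
        with pytest.raises(ConfigurationError, match="planted_links"):
            generate_cohort(
                small_config(planted_links=[PlantedLink("NOGENE", "Contrast_T2WI", 0.5)])
            )

    @pytest.mark.parametrize("target_r", [0.0, 0.3, 0.7])
    def test_planted_driver_state_correlation_calibration(self, target_r):
        """Sample corr(driver, gene state) within 3 SE of target at n=450."""
        cfg = CohortConfig(
            n_per_group=150,
            image_size=16,  # images irrelevant here; keep them cheap
            texture_params={g: TextureParams(2.0, 1.0, 0.3) for g in (1, 2, 3)},
            planted_links=[PlantedLink("P4HA1", "SumSquaresVariance_T2WI", target_r)],
            seed=3,
        )
        cohort = generate_cohort(cfg)
        t = np.array([p.truth["drivers"]["P4HA1"] for p in cohort])
        g = np.array([p.truth["gene_states"]["P4HA1"] for p in cohort])
        r = np.corrcoef(t, g)[0, 1]
        se = (1 - target_r**2) / np.sqrt(len(cohort))
        assert abs(r - target_r) <= 3 * se

    def test_qc_scores_within_bounds(self):
        cohort = generate_cohort(small_config(n_per_group=30))
        qc = np.array([p.qc_score for p in cohort])
        assert (qc >= 0).all() and (qc <= 100).all()
        assert 85 < qc.mean() < 97


class TestRoiGeneration:
    def test_mask_is_interior_and_large_enough(self, rng):
        img = generate_roi_image(TextureParams(4.0, 1.0, 0.3), 32, rng)
        frac = img.mask.mean()
        assert frac >= 0.25
        assert not img.mask[0].any() and not img.mask[-1].any()

    def test_different_seeds_same_summary_statistics(self):
        """Replicates differ pixelwise but share feature-level statistics."""
        par = TextureParams(4.0, 1.2, 0.3)
        contrasts = []
        pixels = []
        for seed in range(100):
            img = generate_roi_image(par, 32, np.random.default_rng(seed))
            pixels.append(img.pixels)
            contrasts.append(roi_features(img)["Contrast"])
        assert not np.array_equal(pixels[0], pixels[1])
        contrasts = np.asarray(contrasts)
        # every replicate within 6 sd of the replicate mean
        assert np.all(np.abs(contrasts - contrasts.mean()) < 6 * contrasts.std())

    def test_contrast_scale_monotonicity(self):
        """Doubling contrast_scale raises mean GLCM Contrast (paired seeds)."""
        lo, hi = [], []
        for seed in range(50):
            rng1 = np.random.default_rng(seed)
            rng2 = np.random.default_rng(seed)
            lo.append(
                roi_features(generate_roi_image(TextureParams(4.0, 0.8, 0.3), 32, rng1))["Contrast"]
            )
            hi.append(
                roi_features(generate_roi_image(TextureParams(4.0, 1.6, 0.3), 32, rng2))["Contrast"]
            )
        assert np.mean(hi) > np.mean(lo)
        # strict paired increase in the overwhelming majority of replicates
        assert np.mean(np.array(hi) > np.array(lo)) > 0.9

    def test_maximal_smoothing_limit_contrast_vanishes(self, rng):
        img = generate_roi_image(TextureParams(28.0, 0.2, 0.0), 32, rng)
        assert roi_features(img)["Contrast"] < 1.0

    def test_degenerate_parameters_raise(self, rng):
        with pytest.raises(ValueError):
            generate_roi_image(TextureParams(40.0, 1.0, 0.0), 32, rng)
        with pytest.raises(ValueError):
            generate_roi_image(TextureParams(4.0, 0.0, 0.0), 32, rng)


class TestCnvSegments:
    def test_states_recovered_exactly(self, rng):
        panel = default_panel()
        states = {"P4HA1": 1, "VEGFA": -1, "BAG3": 0}
        segs = generate_cnv_segments(states, panel, rng, sample_id="S1")
        scores = score_genes(segs, panel, sample_ids=["S1"])
        assert scores.loc["S1", "P4HA1"] == 1
        assert scores.loc["S1", "VEGFA"] == -1
        assert scores.loc["S1", "BAG3"] == 0

    def test_empty_states_only_decoys(self, rng):
        panel = default_panel()
        segs = generate_cnv_segments({}, panel, rng, sample_id="S1", n_decoys=5)
        scores = score_genes(segs, panel, sample_ids=["S1"])
        assert (scores.loc["S1"] == 0).all()
        assert len(segs) == 5

    def test_unknown_gene_rejected(self, rng):
        with pytest.raises(ValueError, match="NOGENE"):
            generate_cnv_segments({"NOGENE": 1}, default_panel(), rng)

    def test_random_state_maps_round_trip(self, rng):
        """Planted gain/loss maps are recovered cell-for-cell by scoring."""
        panel = default_panel()
        genes = panel.genes
        mismatches = 0
        for k in range(100):
            states = {g: int(rng.integers(-1, 2)) for g in genes}
            segs = generate_cnv_segments(states, panel, rng, sample_id=f"S{k}")
            scores = score_genes(segs, panel, sample_ids=[f"S{k}"])
            for g in genes:
                mismatches += scores.loc[f"S{k}", g] != states[g]
        assert mismatches == 0


class TestFixtures:
    @pytest.mark.parametrize("image_format", ["png", "txt"])
    def test_write_read_round_trip(self, tmp_path, image_format):
        cohort = generate_cohort(small_config(n_per_group=2))
        out = tmp_path / "fx"
        manifest = write_fixtures(cohort, out, image_format=image_format)
        back = read_fixtures(out)
        assert len(back) == len(cohort)
        for a, b in zip(cohort, back):
            assert a.patient_id == b.patient_id
            assert a.grade_group == b.grade_group
            assert a.qc_score == pytest.approx(b.qc_score)
            for m in ("T2WI", "ADC"):
                assert np.array_equal(a.images[m].pixels, b.images[m].pixels)
                assert np.array_equal(a.images[m].mask, b.images[m].mask)
            assert a.segments == b.segments
        assert manifest["n_patients"] == 6

    def test_manifest_checksums_match_files(self, tmp_path):
        from radgenmap._util import sha256_file

        cohort = generate_cohort(small_config(n_per_group=2))
        out = tmp_path / "fx"
        manifest = write_fixtures(cohort, out)
        for rel, digest in manifest["files"].items():
            assert sha256_file(out / rel) == digest

    def test_fixed_seed_fixed_checksums(self, tmp_path):
        m1 = write_fixtures(generate_cohort(small_config(n_per_group=2)), tmp_path / "a")
        m2 = write_fixtures(generate_cohort(small_config(n_per_group=2)), tmp_path / "b")
        assert m1["files"] == m2["files"]
        with open(tmp_path / "a" / "manifest.json") as f1, open(
            tmp_path / "b" / "manifest.json"
        ) as f2:
            assert f1.read() == f2.read()
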