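"""Synthetic scene generator: determinism, labels, and metric separability."""

import numpy as np
import pytest

from dermfocus.features import extract_features_image
from dermfocus.metrics import aggregate, teng_map
from dermfocus.synthetic import (
    ARTIFACT_KINDS,
    DegradationSpec,
    FOCUS_SIGMA_THRESHOLD,
    SceneSpec,
    build_plan,
    degrade,
    generate_dataset,
    is_focused,
    realize_record,
    render_artifact_scene,
    render_mole_scene,
    sample_scene_spec,
)

SMALL = (240, 320)  # keeps unit tests fast; still above the crop minimum


class TestMoleScenes:
    def test_same_spec_and_seed_bit_identical(self):
        spec = sample_scene_spec("s01", 11, SMALL)
        a = render_mole_scene(spec, 11)
        b = render_mole_scene(spec, 11)
        assert np.array_equal(a.pixels, b.pixels)

    def test_mole_exceeds_vignette_rejected(self):
        spec = SceneSpec(subject_id="x", size="big", vignette_radius=0.10, resolution=SMALL)
        with pytest.raises(ValueError):
            render_mole_scene(spec, 0)

    def test_hairless_scene_has_no_hair_darkening(self):
        bare = SceneSpec(subject_id="x", hair="none", resolution=SMALL)
        hairy = SceneSpec(subject_id="x", hair="beard", resolution=SMALL)
        a = render_mole_scene(bare, 5).pixels.astype(float)
        b = render_mole_scene(hairy, 5).pixels.astype(float)
        assert b.mean() < a.mean()  # beard strokes darken the scene

    def test_sharp_scene_beats_its_blurred_copy_on_tenengrad(self):
        spec = sample_scene_spec("s02", 3, SMALL)
        img = render_mole_scene(spec, 3)
        blurred = degrade(img, DegradationSpec(blur_kind="gaussian", sigma=4.0))
        from dermfocus.image import make_pair

        sharp_t = aggregate(teng_map(make_pair(img).gray.pixels), "SUM")
        blur_t = aggregate(teng_map(make_pair(blurred).gray.pixels), "SUM")
        assert sharp_t > blur_t


class TestArtifactScenes:
    @pytest.mark.parametrize("kind", ARTIFACT_KINDS)
    def test_deterministic(self, kind):
        a = render_artifact_scene(kind, 9, SMALL)
        b = render_artifact_scene(kind, 9, SMALL)
        assert np.array_equal(a.pixels, b.pixels)

    def test_dust_records_speck_count(self):
        img = render_artifact_scene("dust", 1, SMALL)
        assert img.meta["n_specks"] >= 1

    def test_plain_scene_has_small_intensity_range(self):
        plain = render_artifact_scene("plain", 2, SMALL).pixels
        spec = sample_scene_spec("s01", 2, SMALL)
        mole = render_mole_scene(spec, 2).pixels
        assert np.ptp(plain) < 0.5 * np.ptp(mole)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            render_artifact_scene("lens_flare", 0, SMALL)


class TestDegrade:
    def test_identity_spec_is_identity(self):
        img = render_artifact_scene("fabric", 4, SMALL)
        out = degrade(img, DegradationSpec())
        assert np.array_equal(out.pixels, img.pixels)

    def test_same_seed_same_noise(self):
        img = render_artifact_scene("plain", 4, SMALL)
        spec = DegradationSpec(blur_kind="gaussian", sigma=2.0, sensor_noise_sd=3.0)
        assert np.array_equal(degrade(img, spec, 7).pixels, degrade(img, spec, 7).pixels)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            DegradationSpec(blur_kind="gaussian", sigma=-1.0)

    def test_label_rule(self):
        assert is_focused(DegradationSpec())
        assert is_focused(DegradationSpec(blur_kind="gaussian", sigma=FOCUS_SIGMA_THRESHOLD / 2))
        assert not is_focused(DegradationSpec(blur_kind="gaussian", sigma=FOCUS_SIGMA_THRESHOLD))
        assert not is_focused(DegradationSpec(blur_kind="motion", length=9))


class TestDatasetPlan:
    def test_every_focused_image_has_blurred_counterpart(self):
        plan = build_plan(n_subjects=4, scenes_per_subject=2, seed=1, roles=("preview",))
        moles = [r for r in plan if r["label"] != "artifact"]
        focused = {(r["subject_id"], r["scene_index"]) for r in moles if r["label"] == "focused"}
        blurred = {(r["subject_id"], r["scene_index"]) for r in moles if r["label"] == "non_focused"}
        assert focused == blurred
        for r in moles:
            if r["label"] == "non_focused":
                assert r["sigma"] >= FOCUS_SIGMA_THRESHOLD

    def test_plan_deterministic(self):
        assert build_plan(seed=5, n_subjects=3, scenes_per_subject=1) == build_plan(
            seed=5, n_subjects=3, scenes_per_subject=1
        )

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            build_plan(n_subjects=1)

    def test_bad_class_mix_rejected(self):
        with pytest.raises(ValueError):
            build_plan(n_subjects=3, class_mix={"focused": 0.5, "non_focused": 0.5, "artifact": 0.5})


def test_generate_dataset_writes_consistent_manifest(tmp_path):
    manifest = generate_dataset(
        tmp_path / "data", n_subjects=2, scenes_per_subject=1, seed=7, roles=("preview",)
    )
    for rel in manifest["image_path"]:
        assert (tmp_path / "data" / rel).exists()
    assert (tmp_path / "data" / "manifest.csv").exists()
    assert (tmp_path / "data" / "generation_config.json").exists()
    # regeneration is byte-identical
    m2 = generate_dataset(
        tmp_path / "data2", n_subjects=2, scenes_per_subject=1, seed=7, roles=("preview",)
    )
    a = (tmp_path / "data" / manifest["image_path"].iloc[0]).read_bytes()
    b = (tmp_path / "data2" / m2["image_path"].iloc[0]).read_bytes()
    assert a == b


def test_relative_feature_separates_focus_classes():
    # the separability the downstream classifiers rely on
    ratios = []
    for seed in range(5):
        spec = sample_scene_spec(f"s{seed}", seed, SMALL)
        img = render_mole_scene(spec, seed)
        blurred = degrade(img, DegradationSpec(blur_kind="gaussian", sigma=6.0))
        f_sharp = extract_features_image(img)
        f_blur = extract_features_image(blurred)
        ratios.append(f_blur["GLVA_SUM_DIFF"] / f_sharp["GLVA_SUM_DIFF"])
    assert max(ratios) < 0.25
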