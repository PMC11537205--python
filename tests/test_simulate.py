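"""Synthetic tissue generator: determinism, mixture fidelity, round-trip
recoverability, rendering and parent-labeled sets."""

import numpy as np
import pytest
from scipy import stats

from phenogate import (
    CLASS_NAMES,
    ClassMapping,
    ConfigurationError,
    MappingError,
    PackingError,
    default_class_mapping,
    default_config,
    generate_parent_labeled_set,
    generate_tissue,
    render_pseudo_he,
)
from phenogate.workflows import gating_round_trip


class TestGenerateTissue:
    def test_zero_cells(self):
        cfg = default_config(n_cells=0, image_height_px=64, image_width_px=64)
        t = generate_tissue(cfg)
        assert t.instances.n_instances == 0
        assert (t.instances.labels == 0).all()
        assert len(t.truth) == 0

    def test_determinism_bit_identical(self):
        cfg = default_config(n_cells=60, seed=5, image_height_px=384, image_width_px=384)
        a = generate_tissue(cfg)
        b = generate_tissue(default_config(n_cells=60, seed=5, image_height_px=384, image_width_px=384))
        for ch in a.image.channel_names:
            assert np.array_equal(a.image.channel(ch), b.image.channel(ch))
        assert np.array_equal(a.instances.labels, b.instances.labels)
        assert a.truth.equals(b.truth)

    def test_bad_mixture_rejected(self):
        cfg = default_config(n_cells=10)
        cfg.class_mixture["goblet"] += 0.2
        with pytest.raises(ConfigurationError, match="sums"):
            generate_tissue(cfg)

    def test_packing_error_names_count(self):
        cfg = default_config(n_cells=500, image_height_px=96, image_width_px=96)
        with pytest.raises(PackingError, match="of 500"):
            generate_tissue(cfg)

    def test_truth_and_map_ids_agree(self, small_tissue):
        map_ids = set(small_tissue.instances.ids.tolist())
        truth_ids = set(small_tissue.truth["instance_id"].tolist())
        assert map_ids == truth_ids
        assert small_tissue.truth["instance_id"].is_unique

    def test_multinomial_mixture_chi_square(self):
        """Class counts at n>=500 are consistent with the mixture (alpha=0.01)."""
        cfg = default_config(n_cells=600, seed=21)
        t = generate_tissue(cfg)
        counts = t.truth["class"].value_counts()
        observed = np.array([counts.get(c, 0) for c in CLASS_NAMES])
        expected = np.full(len(CLASS_NAMES), 600 / len(CLASS_NAMES))
        stat, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_goblets_are_muc2_regions_not_nuclei(self, small_tissue):
        from phenogate.gating import mean_intensity_per_instance

        table = mean_intensity_per_instance(small_tissue.image, small_tissue.instances)
        merged = table.merge(small_tissue.truth[["instance_id", "class"]], on="instance_id")
        gob = merged[merged["class"] == "goblet"]
        nuc = merged[merged["class"] != "goblet"]
        assert len(gob) > 0
        assert (gob["mean_Muc2"] > 0.5).all()
        assert (gob["mean_DAPI"] < 0.5).all()
        assert (nuc["mean_DAPI"] > 0.5).all()


class TestRoundTrip:
    def test_zero_noise_recovers_every_class(self):
        assert gating_round_trip(n_cells=150, noise_sd=0.0, seed=3) == 1.0

    def test_accuracy_degrades_monotonically_with_noise(self):
        """3-point noise ladder, averaged over 5 seeds."""
        levels = (0.0, 0.6, 1.2)
        mean_acc = []
        for sd in levels:
            accs = [gating_round_trip(n_cells=120, noise_sd=sd, seed=s) for s in range(5)]
            mean_acc.append(np.mean(accs))
        assert mean_acc[0] + 0.02 >= mean_acc[1] >= mean_acc[2] - 0.02
        assert mean_acc[0] > mean_acc[2]  # the ladder actually bites


class TestPseudoHE:
    def test_zero_cells_uniform_background(self):
        t = generate_tissue(default_config(n_cells=0, image_height_px=32, image_width_px=32))
        rgb = render_pseudo_he(t)
        assert rgb.shape == (32, 32, 3)
        assert np.unique(rgb.reshape(-1, 3), axis=0).shape[0] == 1

    def test_deterministic(self, small_tissue):
        a = render_pseudo_he(small_tissue)
        b = render_pseudo_he(small_tissue)
        assert np.array_equal(a, b)

    def test_nuclei_darker_than_background(self, small_tissue):
        rgb = render_pseudo_he(small_tissue)
        lum = rgb.mean(axis=2)
        labels = small_tissue.instances.labels
        gob_ids = small_tissue.truth.loc[
            small_tissue.truth["class"] == "goblet", "instance_id"
        ].to_numpy()
        nucleus = (labels > 0) & ~np.isin(labels, gob_ids)
        assert lum[nucleus].mean() < lum[labels == 0].mean()

    def test_missing_dapi_raises(self, small_tissue):
        from phenogate import ChannelError
        import dataclasses

        img = small_tissue.image
        stripped = dataclasses.replace(
            small_tissue,
            image=type(img)({k: v for k, v in img.channels.items() if k != "DAPI"},
                            img.resolution_um_per_px),
        )
        with pytest.raises(ChannelError):
            render_pseudo_he(stripped)


@pytest.fixture(scope="module")
def tissues():
    cfgs = [
        default_config(n_cells=90, seed=31 + i, image_height_px=512, image_width_px=512,
                       slide_id=f"s{i}", patient_id=f"p{i}", site_id=f"site_{i % 2}")
        for i in range(2)
    ]
    return [generate_tissue(c) for c in cfgs]


class TestParentLabeledSet:

    def test_identity_mapping_no_drops_keeps_fine_labels(self, tissues):
        ident = ClassMapping.identity(CLASS_NAMES)
        tiles = generate_parent_labeled_set(tissues, ident, site_effects=False)
        for t in tiles:
            assert (t.table["class"] == t.table["fine_class"]).all()

    def test_paper_anchor_pairs(self):
        m = default_class_mapping()
        assert m.parent("helper T") == "lymphocyte"
        assert m.parent("enterocyte") == "epithelial"
        assert m.parent("progenitor") == "epithelial"
        assert m.parent("fibroblast") == "connective"
        assert m.parent("stromal (undetermined)") == "connective"
        assert "goblet" in m.droppable

    def test_tiles_are_256px_at_half_micron(self, tissues):
        tiles = generate_parent_labeled_set(tissues, default_class_mapping())
        assert len(tiles) > 0
        for t in tiles:
            assert t.tile.shape == (256, 256, 3)
            assert t.instances.shape == (256, 256)
            assert t.instances.resolution_um_per_px == 0.5

    def test_goblets_dropped_from_labels(self, tissues):
        # ids are scoped per tissue, so check one tissue's tiles at a time
        for tissue in tissues:
            gob_ids = {
                int(i) for i in tissue.truth.loc[tissue.truth["class"] == "goblet", "instance_id"]
            }
            assert gob_ids
            for t in generate_parent_labeled_set([tissue], default_class_mapping()):
                assert "goblet" not in set(t.table["fine_class"])
                assert not gob_ids & set(t.instances.ids.tolist())

    def test_unmapped_class_raises(self, tissues):
        partial = ClassMapping({"helper T": "lymphocyte"})
        with pytest.raises(MappingError):
            generate_parent_labeled_set(tissues, partial)

    def test_site_effect_shifts_colors(self, tissues):
        with_fx = generate_parent_labeled_set(tissues, default_class_mapping(), site_effects=True)
        without = generate_parent_labeled_set(tissues, default_class_mapping(), site_effects=False)
        assert any(
            not np.array_equal(a.tile, b.tile) for a, b in zip(with_fx, without)
        )
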