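"""Container conversion, dataset loading, train/validation splitting."""

import h5py
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoseg.core import save_sample
from cytoseg.cx22 import (Cx22FormatError, convert_cx22_container, load_dataset,
                          split_train_val, write_cx22_container)
from cytoseg.synthetic import SyntheticConfig, generate_dataset, generate_sample


@pytest.fixture()
def fixture_samples():
    cfg = SyntheticConfig.tiny(seed=17)
    return [generate_sample(cfg, i) for i in range(3)]


class TestConvert:
    def test_round_trip_through_hdf5_container(self, tmp_path, fixture_samples):
        container = tmp_path / "fixture.mat"
        write_cx22_container(fixture_samples, container)
        out = tmp_path / "converted"
        n = convert_cx22_container(container, out)
        assert n == 3
        assert len(list(out.glob("*.png"))) == 9
        loaded = {s.id: s for s in load_dataset(out)}
        for orig in fixture_samples:
            back = loaded[orig.id]
            assert (back.image == orig.image).all()
            assert (back.cytoplasm_mask == orig.cytoplasm_mask).all()
            assert (back.nucleus_mask == orig.nucleus_mask).all()

    def test_matlab_transposed_layout(self, tmp_path, fixture_samples):
        """MATLAB v7.3 stores arrays transposed; conversion must undo it."""
        container = tmp_path / "trans.mat"
        imgs = np.stack([s.image for s in fixture_samples])
        cyto = np.stack([s.cytoplasm_mask for s in fixture_samples]) * 255
        nuc = np.stack([s.nucleus_mask for s in fixture_samples]) * 255
        with h5py.File(container, "w") as f:
            f.create_dataset("img", data=imgs.transpose(3, 2, 1, 0))
            f.create_dataset("cyto", data=cyto.transpose(2, 1, 0))
            f.create_dataset("nuc", data=nuc.transpose(2, 1, 0))
        out = tmp_path / "converted"
        assert convert_cx22_container(container, out) == 3
        loaded = load_dataset(out)
        assert (loaded[0].cytoplasm_mask == fixture_samples[0].cytoplasm_mask).all()

    def test_empty_container_converts_zero(self, tmp_path):
        container = tmp_path / "empty.mat"
        write_cx22_container([], container)
        assert convert_cx22_container(container, tmp_path / "out") == 0

    def test_missing_nucleus_mask_names_the_sample(self, tmp_path, fixture_samples):
        container = tmp_path / "broken.mat"
        s = fixture_samples[0]
        with h5py.File(container, "w") as f:
            g = f.create_group("sample_007")
            g.create_dataset("image", data=s.image)
            g.create_dataset("cyto", data=s.cytoplasm_mask)
        with pytest.raises(Cx22FormatError, match="sample_007"):
            convert_cx22_container(container, tmp_path / "out")

    def test_manual_key_override(self, tmp_path, fixture_samples):
        container = tmp_path / "named.mat"
        write_cx22_container(fixture_samples, container)
        out = tmp_path / "out"
        n = convert_cx22_container(container, out, keys={
            "image": "images", "cyto": "cyto_masks", "nuc": "nuc_masks"})
        assert n == 3

    def test_override_with_absent_key_fails(self, tmp_path, fixture_samples):
        container = tmp_path / "named.mat"
        write_cx22_container(fixture_samples, container)
        with pytest.raises(Cx22FormatError, match="nope"):
            convert_cx22_container(container, tmp_path / "out", keys={
                "image": "images", "cyto": "cyto_masks", "nuc": "nope"})


class TestLoadDataset:
    def test_loads_generated_dataset_sorted(self, tmp_path):
        generate_dataset(SyntheticConfig.tiny(seed=2), 5, tmp_path)
        samples = load_dataset(tmp_path)
        assert len(samples) == 5
        assert [s.id for s in samples] == sorted(s.id for s in samples)

    def test_empty_directory(self, tmp_path):
        assert load_dataset(tmp_path) == []

    def test_orphan_image_reported_by_id(self, tmp_path, fixture_samples):
        save_sample(fixture_samples[0], tmp_path)
        (tmp_path / f"{fixture_samples[0].id}_nuc.png").unlink()
        with pytest.raises(Cx22FormatError, match=fixture_samples[0].id):
            load_dataset(tmp_path)


class TestSplit:
    def test_full_scale_split_sizes(self):
        ids = [f"s{i:04d}" for i in range(400)]
        split = split_train_val(ids, 0.9, seed=0)
        assert len(split.train) == 360 and len(split.val) == 40

    def test_half_split(self):
        split = split_train_val([str(i) for i in range(10)], 0.5, seed=1)
        assert len(split.train) == 5 and len(split.val) == 5

    def test_deterministic_given_seed(self):
        ids = [str(i) for i in range(10)]
        a = split_train_val(ids, 0.9, seed=3)
        b = split_train_val(ids, 0.9, seed=3)
        assert a == b

    @pytest.mark.parametrize("ratio", [0.0, 1.0, -0.2, 1.5])
    def test_ratio_out_of_range(self, ratio):
        with pytest.raises(ValueError):
            split_train_val(["a", "b"], ratio, seed=0)

    @given(st.integers(2, 200), st.floats(0.05, 0.95), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_split_is_a_partition(self, n, ratio, seed):
        ids = [f"id{i}" for i in range(n)]
        split = split_train_val(ids, ratio, seed)
        assert set(split.train) | set(split.val) == set(ids)
        assert not set(split.train) & set(split.val)
        assert abs(len(split.train) - ratio * n) <= 1
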