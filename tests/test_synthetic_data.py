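import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dropmorph.config import SyntheticConfig, large_droplet_config, small_droplet_config
from dropmorph.mask_geometry import extract_features, read_mask
from dropmorph.organoid_morphometry import branch_census, classify_structure
from dropmorph.synthetic_data import (
    SizingError,
    generate_droplet_mask,
    generate_organoid_mask,
    simulate_seeding,
    write_dataset,
)


class TestDropletMask:
    def test_uncontracted_equivalent_diameter(self):
        cfg = SyntheticConfig(
            droplet_diameter_um=750.0,
            pixel_size_um=2.0,
            image_shape_px=(512, 512),
            contraction_schedule={2: 0.0},
            growth_curve={2: 60.0},
            seed=3,
        )
        frame = generate_droplet_mask(cfg, "d0", 2)
        (f,) = extract_features(frame)
        assert f.equivalent_diameter_um / 2.0 == pytest.approx(375.0, abs=1.0)

    def test_contraction_followed_within_one_pixel(self, tiny_large_cfg):
        for i in range(3):
            did = f"drop{i:04d}"
            f2 = extract_features(generate_droplet_mask(tiny_large_cfg, did, 2))[0]
            f6 = extract_features(generate_droplet_mask(tiny_large_cfg, did, 6))[0]
            ratio = f6.equivalent_diameter_um / f2.equivalent_diameter_um
            px_tol = tiny_large_cfg.pixel_size_um / f2.equivalent_diameter_um
            assert ratio == pytest.approx(0.88, abs=px_tol)

    def test_deterministic(self, tiny_large_cfg):
        a = generate_droplet_mask(tiny_large_cfg, "drop0001", 6)
        b = generate_droplet_mask(tiny_large_cfg, "drop0001", 6)
        assert np.array_equal(a.label_image, b.label_image)

    def test_simply_connected(self, tiny_large_cfg):
        from scipy import ndimage

        frame = generate_droplet_mask(tiny_large_cfg, "drop0002", 6)
        mask = frame.label_image == 1
        _, n = ndimage.label(mask)
        assert n == 1
        assert np.array_equal(ndimage.binary_fill_holes(mask), mask)

    def test_oversized_droplet_rejected_by_config(self):
        with pytest.raises(ValueError, match="fit"):
            SyntheticConfig(
                droplet_diameter_um=1200.0,
                pixel_size_um=2.0,
                image_shape_px=(256, 256),
                contraction_schedule={2: 0.0},
                growth_curve={2: 60.0},
            )

    def test_unknown_day_rejected(self, tiny_large_cfg):
        with pytest.raises(KeyError):
            generate_droplet_mask(tiny_large_cfg, "drop0000", 99)


class TestOrganoidMask:
    def test_spheroid_major_axis_recovered(self):
        cfg = large_droplet_config(
            n_droplets=4, seed=21, contraction_schedule={4: 0.0}, growth_curve={4: 50.0}
        )
        for i in range(4):
            frame, gt = generate_organoid_mask(cfg, f"d{i}", 4, true_class="spheroid")
            feats = {f.label: f for f in extract_features(frame)}
            assert feats[2].major_axis_um == pytest.approx(
                gt.true_major_axis_um, abs=2 * cfg.pixel_size_um
            )

    def test_branched_phantom_census(self):
        cfg = large_droplet_config(
            n_droplets=24, seed=22, contraction_schedule={4: 0.02}, growth_curve={4: 150.0}
        )
        rel_errs = []
        for i in range(24):
            frame, gt = generate_organoid_mask(cfg, f"d{i}", 4, true_class="branched")
            census = branch_census(frame.label_image == 2, cfg.pixel_size_um)
            truth = sorted(gt.true_branch_lengths_um, reverse=True)
            meas = sorted(census.branch_lengths_um, reverse=True)
            assert len(meas) == len(truth)  # count recovered exactly
            assert census.n_branches >= 2
            rel_errs += [abs(m - t) / t for m, t in zip(meas, truth)]
        # frozen census-length tolerance at 2 um/px: median ~3%, >=80% of
        # branches within 10%, hard cap 35% (discrete-skeleton tip erosion
        # on curved tube ends produces rare outliers)
        rel_errs = np.asarray(rel_errs)
        assert float(np.median(rel_errs)) <= 0.06
        assert (rel_errs <= 0.10).mean() >= 0.80
        assert rel_errs.max() <= 0.35

    def test_ground_truth_branched_invariant(self):
        cfg = large_droplet_config(
            n_droplets=2, seed=23, contraction_schedule={4: 0.0}, growth_curve={4: 150.0}
        )
        _, gt = generate_organoid_mask(cfg, "d0", 4, true_class="branched")
        assert sum(1 for v in gt.true_branch_lengths_um if v >= 30.0) >= 2

    def test_growth_curve_monotone(self):
        cfg = large_droplet_config(
            n_droplets=2,
            seed=24,
            contraction_schedule={2: 0.0, 4: 0.02, 6: 0.05},
            growth_curve={2: 60.0, 4: 120.0, 6: 200.0},
        )
        majors = []
        for day in (2, 4, 6):
            frame, _ = generate_organoid_mask(cfg, "d0", day, true_class="spheroid")
            feats = {f.label: f for f in extract_features(frame)}
            majors.append(feats[2].major_axis_um)
        assert majors == sorted(majors)

    def test_organoid_inside_droplet(self, tiny_large_cfg):
        frame, _ = generate_organoid_mask(tiny_large_cfg, "drop0000", 6)
        organoid = frame.label_image == 2
        assert organoid.any()
        assert not (organoid & ~frame.droplet_mask).any()

    def test_min_boundary_distance_positive(self, tiny_large_cfg):
        _, gt = generate_organoid_mask(tiny_large_cfg, "drop0001", 2)
        assert gt.true_min_boundary_distance_um > 0

    def test_branch_in_tiny_droplet_raises_sizing_error(self):
        cfg = SyntheticConfig(
            droplet_diameter_um=80.0,
            pixel_size_um=2.0,
            image_shape_px=(64, 64),
            contraction_schedule={2: 0.0},
            growth_curve={2: 60.0},
        )
        with pytest.raises(SizingError):
            generate_organoid_mask(cfg, "d0", 2, true_class="branched")

    def test_class_validity_at_default_margins(self):
        # every phantom must land decisively on its class's side of the
        # classifier thresholds
        for preset, seed in ((large_droplet_config, 31), (small_droplet_config, 32)):
            cfg = preset(
                n_droplets=99,
                seed=seed,
                contraction_schedule={4: 0.02},
                growth_curve={4: 120.0},
            )
            for i in range(8):
                for cls in ("spheroid", "branched"):
                    frame, gt = generate_organoid_mask(cfg, f"v{i}", 4, true_class=cls)
                    feats = {f.label: f for f in extract_features(frame)}
                    census = branch_census(frame.label_image == 2, cfg.pixel_size_um)
                    assert classify_structure(feats[2], census) == cls


class TestSeeding:
    def test_large_droplet_mean_occupancy(self):
        cfg = large_droplet_config(seed=5)
        counts = simulate_seeding(cfg, n_droplets=100_000)
        lam = 5000.0 * (np.pi / 6 * 756e-4**3)  # conc/ml x volume in ml
        assert abs(counts.mean() - lam) < 3 * np.sqrt(lam / counts.size)
        assert counts.mean() == pytest.approx(1.1, abs=0.05)

    def test_small_droplet_mean_occupancy(self):
        cfg = small_droplet_config(seed=6)
        counts = simulate_seeding(cfg, n_droplets=100_000)
        assert counts.mean() == pytest.approx(0.8, abs=0.05)

    def test_zero_concentration(self):
        cfg = large_droplet_config(cell_concentration_per_ml=0.0, seed=7)
        assert not simulate_seeding(cfg, n_droplets=1000).any()

    def test_chi_square_goodness_of_fit(self):
        cfg = large_droplet_config(seed=8)
        counts = simulate_seeding(cfg, n_droplets=100_000)
        lam = counts.mean()
        kmax = int(counts.max())
        observed = np.bincount(counts, minlength=kmax + 1).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 1), lam) * counts.size
        expected[-1] = counts.size - expected[:-1].sum()  # tail mass
        keep = expected > 5
        # lump sparse tail bins
        obs = np.append(observed[keep][:-1], observed[~keep].sum() + observed[keep][-1])
        exp = np.append(expected[keep][:-1], expected[~keep].sum() + expected[keep][-1])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        pval = stats.chi2.sf(chi2, df=len(obs) - 2)  # lambda estimated
        assert pval > 0.01


class TestWriteDataset:
    def test_layout_and_round_trip(self, tmp_path, tiny_small_cfg):
        cfg = tiny_small_cfg.model_copy(update={"n_droplets": 5})
        cfg = type(cfg)(**cfg.model_dump())
        manifest_path = write_dataset(cfg, tmp_path / "ds")
        manifest = pd.read_csv(manifest_path)
        assert len(manifest) == 5 * 2  # droplets x days
        assert list(manifest.columns) == ["droplet_id", "day", "file", "pixel_size_um"]
        with open(tmp_path / "ds" / "ground_truth.json") as fh:
            gt = json.load(fh)
        assert len(gt) == len(manifest)
        # referential integrity
        gt_keys = {(r["droplet_id"], r["day"]) for r in gt}
        mf_keys = set(zip(manifest["droplet_id"], manifest["day"]))
        assert gt_keys == mf_keys
        # lossless read-back
        row = manifest.iloc[0]
        frame = read_mask(
            tmp_path / "ds" / row["file"],
            row["pixel_size_um"],
            row["droplet_id"],
            int(row["day"]),
        )
        regen, _ = generate_organoid_mask(cfg, row["droplet_id"], int(row["day"]))
        assert np.array_equal(frame.label_image, regen.label_image)

    def test_byte_identical_regeneration(self, tmp_path, tiny_small_cfg):
        p1 = write_dataset(tiny_small_cfg, tmp_path / "a")
        p2 = write_dataset(tiny_small_cfg, tmp_path / "b")
        assert open(p1, "rb").read() == open(p2, "rb").read()
        m = pd.read_csv(p1)
        for f in m["file"][:3]:
            b1 = open(tmp_path / "a" / f, "rb").read()
            b2 = open(tmp_path / "b" / f, "rb").read()
            assert b1 == b2
        g1 = open(tmp_path / "a" / "ground_truth.json", "rb").read()
        g2 = open(tmp_path / "b" / "ground_truth.json", "rb").read()
        assert g1 == g2
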