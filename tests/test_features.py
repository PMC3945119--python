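import hashlib

import numpy as np
import pytest
from scipy import ndimage

from plast.errors import DegenerateCellError, ParameterError, ZeroSignalError
from plast.features import (
    LS_STATS,
    REGIONS,
    CellRecord,
    LocalStructureParams,
    build_cell_record,
    derive_regions,
    extract_features,
    extract_field_features,
    feature_registry,
    local_structure_features,
    normalize_cell,
)


def disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


@pytest.fixture()
def concentric_cell():
    cell = disk_mask((40, 40), 20, 20, 10)
    nuc = disk_mask((40, 40), 20, 20, 4)
    return cell, nuc


class TestRegions:
    def test_concentric_disks_partition_exactly(self, concentric_cell):
        cell, nuc = concentric_cell
        regions = derive_regions(cell, nuc)
        # pixel-enumeration oracle for the disk/annulus counts
        assert regions["cellular"].sum() == cell.sum()
        assert regions["nuclear"].sum() == nuc.sum()
        assert regions["cytoplasmic"].sum() == cell.sum() - nuc.sum()
        assert np.array_equal(regions["cytoplasmic"], cell & ~nuc)
        # boundary is the rim removed by a radius-3 disk erosion of cytoplasm
        offs = [(dy, dx) for dy in range(-3, 4) for dx in range(-3, 4) if dy * dy + dx * dx <= 9]
        cyto = regions["cytoplasmic"]
        eroded = np.zeros_like(cyto)
        for y in range(40):
            for x in range(40):
                eroded[y, x] = all(
                    0 <= y + dy < 40 and 0 <= x + dx < 40 and cyto[y + dy, x + dx] for dy, dx in offs
                )
        assert np.array_equal(regions["cytoplasmic_boundary"], cyto & ~eroded)
        assert np.array_equal(regions["inner_cytoplasmic"], cyto & eroded)
        # disjoint union
        assert not (regions["cytoplasmic_boundary"] & regions["inner_cytoplasmic"]).any()

    def test_nucleus_covering_cell_is_degenerate(self, concentric_cell):
        cell, _ = concentric_cell
        with pytest.raises(DegenerateCellError):
            derive_regions(cell, cell)

    def test_missing_nucleus_gives_cytoplasm_equal_cell(self, concentric_cell):
        cell, _ = concentric_cell
        regions = derive_regions(cell, np.zeros_like(cell))
        assert np.array_equal(regions["cytoplasmic"], cell)
        assert not regions["nuclear"].any()


class TestNormalization:
    def test_uniform_cell_gives_equal_weights(self, concentric_cell):
        cell, _ = concentric_cell
        out = normalize_cell(np.where(cell, 7.0, 0.0), cell)
        assert np.allclose(out[cell], 1.0 / cell.sum())
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, concentric_cell):
        cell, _ = concentric_cell
        rng = np.random.default_rng(0)
        gfp = rng.uniform(1, 10, cell.shape)
        assert np.allclose(normalize_cell(gfp, cell), normalize_cell(2.0 * gfp, cell))

    def test_region_mass_fraction_preserved(self, concentric_cell):
        cell, nuc = concentric_cell
        rng = np.random.default_rng(1)
        gfp = np.where(cell, rng.uniform(1, 10, cell.shape), 0.0)
        out = normalize_cell(gfp, cell)
        assert out[nuc].sum() / out[cell].sum() == pytest.approx(gfp[nuc].sum() / gfp[cell].sum())

    def test_zero_signal_raises(self, concentric_cell):
        cell, _ = concentric_cell
        with pytest.raises(ZeroSignalError):
            normalize_cell(np.zeros(cell.shape), cell)


class TestRegistry:
    def test_group_sizes_sum_to_623(self):
        reg = feature_registry()
        counts = reg.groupby("group").size().to_dict()
        assert counts == {
            "morphology": 81,
            "intensity": 45,
            "intensity_ratio": 20,
            "haralick": 273,
            "moment": 18,
            "local_structure": 186,
        }
        assert len(reg) == 623
        assert reg["name"].is_unique

    def test_golden_names_frozen(self):
        digest = hashlib.sha256("\n".join(feature_registry()["name"]).encode()).hexdigest()
        assert digest == "4dc07518bc5f25ce53d8a81cb09bceff57c6eea4d681386a2435c81755c7bc78"


def _record(cell, nuc, gfp):
    regions = derive_regions(cell, nuc)
    return CellRecord("c1", "s1", regions, normalize_cell(gfp, cell))


class TestExtraction:
    def test_vector_length_and_order(self, concentric_cell):
        cell, nuc = concentric_cell
        rng = np.random.default_rng(2)
        vec = extract_features(_record(cell, nuc, rng.uniform(1, 5, cell.shape)))
        assert len(vec) == 623
        assert list(vec.index) == list(feature_registry()["name"])
        assert np.isfinite(vec.to_numpy()).all()

    def test_uniform_gfp_ratio_features_equal_area_ratios(self, concentric_cell):
        cell, nuc = concentric_cell
        vec = extract_features(_record(cell, nuc, np.where(cell, 3.0, 0.0)))
        regions = derive_regions(cell, nuc)
        for a in ("cellular", "nuclear"):
            for b in ("cytoplasmic",):
                expect = regions[a].sum() / regions[b].sum()
                assert vec[f"rat_{a}_{b}_total"] == pytest.approx(expect, rel=1e-9)
                assert vec[f"rat_{a}_{b}_mean"] == pytest.approx(1.0, rel=1e-9)

    def test_zero_signal_cell_gives_zero_vector_with_flag(self, concentric_cell):
        cell, nuc = concentric_cell
        rec = build_cell_record(np.zeros(cell.shape), cell, nuc, "c", "s")
        assert "zero_signal" in rec.flags
        vec = extract_features(rec)
        assert not vec.to_numpy().any()

    def test_scale_invariance_of_full_vector(self, concentric_cell):
        cell, nuc = concentric_cell
        rng = np.random.default_rng(3)
        gfp = np.where(cell, rng.uniform(1, 10, cell.shape), 0.0)
        v1 = extract_features(_record(cell, nuc, gfp))
        v2 = extract_features(_record(cell, nuc, 5.0 * gfp))
        assert np.allclose(v1.to_numpy(), v2.to_numpy(), atol=1e-12)

    def test_morphology_ignores_gfp(self, concentric_cell):
        cell, nuc = concentric_cell
        rng = np.random.default_rng(4)
        v1 = extract_features(_record(cell, nuc, np.where(cell, rng.uniform(1, 9, cell.shape), 0)))
        v2 = extract_features(_record(cell, nuc, np.where(cell, rng.uniform(1, 9, cell.shape), 0)))
        mor = feature_registry().query("group == 'morphology'")["name"]
        assert np.array_equal(v1[mor].to_numpy(), v2[mor].to_numpy())

    def test_missing_region_raises(self, concentric_cell):
        cell, nuc = concentric_cell
        rec = _record(cell, nuc, np.where(cell, 1.0, 0.0))
        del rec.regions["nuclear"]
        with pytest.raises(DegenerateCellError):
            extract_features(rec)


class TestLocalStructureFeatures:
    def test_sixteen_windows_give_96_plus_90(self, concentric_cell):
        cell, nuc = concentric_cell
        gfp = normalize_cell(np.where(cell, np.random.default_rng(5).uniform(1, 5, cell.shape), 0), cell)
        out = local_structure_features(gfp, cell)
        assert len(out) == 186
        assert sum(1 for k in out if "_global_" in k) == 96
        assert sum(1 for k in out if "_step_" in k) == 90

    def test_structure_equal_to_cell_gives_unit_ratios(self, concentric_cell):
        # a very negative bias makes every in-cell pixel a "structure"
        cell, nuc = concentric_cell
        rng = np.random.default_rng(6)
        gfp = normalize_cell(np.where(cell, rng.uniform(1, 3, cell.shape), 0.0), cell)
        out = local_structure_features(gfp, cell, LocalStructureParams(bias=-1.0))
        for k, v in out.items():
            assert v == pytest.approx(1.0, rel=1e-9), k

    def test_single_punctum_matches_direct_computation(self):
        # six-statistic oracle computed by hand at w=3
        cell = disk_mask((41, 41), 20, 20, 12)
        gfp = np.where(cell, 1e-4, 0.0)
        gfp[20, 20] = 1.0
        gfp = normalize_cell(gfp, cell)
        params = LocalStructureParams(window_sizes=(3, 5))
        out = local_structure_features(gfp, cell, params)

        img = np.where(cell, gfp, 0.0)
        mu = ndimage.uniform_filter(img, size=3, mode="reflect")
        B = (img > mu) & cell
        vals = img[B]
        lab, n_obj = ndimage.label(B)
        cell_vals = img[cell]
        lab_c, n_obj_c = ndimage.label(cell)
        oracle = {
            "total": vals.sum() / cell_vals.sum(),
            "mean": vals.mean() / cell_vals.mean(),
            "sd": vals.std() / cell_vals.std(),
            "obj_count": n_obj / n_obj_c,
            "obj_area": B.sum() / cell.sum(),
            "obj_mean_area": (B.sum() / n_obj) / (cell.sum() / n_obj_c),
        }
        for s in LS_STATS:
            assert out[f"ls_w03_global_{s}"] == pytest.approx(oracle[s], rel=1e-9)

    def test_fewer_than_two_windows_rejected(self):
        with pytest.raises(ParameterError):
            LocalStructureParams(window_sizes=(3,))
        with pytest.raises(ParameterError):
            LocalStructureParams(window_sizes=(3, 4))


def test_pattern_separability_on_synthetic_strains():
    """Nuclear vs cytoplasmic strains: at least one feature with Cohen's d > 2."""
    from plast import imaging, segmentation
    from plast.synthdata import SyntheticFieldSpec, generate_field

    tables = []
    for pattern in ("nuclear", "cytoplasmic"):
        fieldi, truth = generate_field(SyntheticFieldSpec(seed=21, pattern_class=pattern))
        gfp = imaging.subtract_background_fluorescence(fieldi.gfp, 50)
        dna = imaging.subtract_background_fluorescence(fieldi.dna, 50)
        dic = imaging.subtract_background_dic(fieldi.dic, 25)
        nuclei = segmentation.detect_nuclei(dna)
        cells = segmentation.segment_cells(dic, nuclei)
        tables.append(extract_field_features(gfp, cells, nuclei, pattern))
    a = tables[0].iloc[:, 4:].to_numpy()
    b = tables[1].iloc[:, 4:].to_numpy()
    pooled_sd = np.sqrt((a.var(axis=0) + b.var(axis=0)) / 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.abs(a.mean(axis=0) - b.mean(axis=0)) / pooled_sd
    assert np.nanmax(d) > 2.0


def test_field_driver_emits_qc_columns(segmented):
    table = extract_field_features(segmented["gfp"], segmented["cells"], segmented["nuclei"], "S1")
    assert list(table.columns[:4]) == ["strain_id", "cell_id", "qc_area", "qc_solidity"]
    assert len(table) == segmented["cells"].n_labels
    assert table.shape[1] == 4 + 623
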