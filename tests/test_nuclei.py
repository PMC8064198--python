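import numpy as np
import pytest

from stilquant import types as T
from stilquant.nuclei import (
    LymphocyteThresholds,
    assemble_lymphocytes,
    attribute_cells,
    classify_lymphocytes,
    extract_nuclei,
)
from stilquant.types import RGBTile, SemanticMap


def semantic_from(labels: np.ndarray) -> SemanticMap:
    return SemanticMap(labels=labels.astype(np.int8))


def blank(h=64, w=64, fill=T.STROMA):
    return np.full((h, w), fill, dtype=np.int8)


def disc_mask(h, w, cr, cc, r):
    rr, cc_ = np.mgrid[:h, :w]
    return (rr - cr) ** 2 + (cc_ - cc) ** 2 <= r * r


def flat_tile(h=64, w=64, color=(60, 48, 78)):
    return RGBTile(np.tile(np.array(color, dtype=np.uint8), (h, w, 1)))


class TestExtractNuclei:
    def test_two_disjoint_squares(self):
        lab = blank()
        lab[5:10, 5:10] = T.NUCLEUS
        lab[20:25, 20:25] = T.NUCLEUS
        nuclei, img = extract_nuclei(semantic_from(lab), min_area=5)
        assert len(nuclei) == 2
        assert sorted(n.area for n in nuclei) == [25, 25]
        assert img.max() == 2

    def test_diagonal_touch_connectivity_contract(self):
        lab = blank()
        lab[5:10, 5:10] = T.NUCLEUS
        lab[10:15, 10:15] = T.NUCLEUS  # touches only at the corner (10,10)
        n8, _ = extract_nuclei(semantic_from(lab), min_area=5, connectivity=2)
        n4, _ = extract_nuclei(semantic_from(lab), min_area=5, connectivity=1)
        assert len(n8) == 1
        assert len(n4) == 2

    def test_no_nucleus_pixels_is_empty_not_error(self):
        nuclei, img = extract_nuclei(semantic_from(blank()))
        assert nuclei == []
        assert (img == 0).all()

    def test_min_area_filter(self):
        lab = blank()
        lab[5:7, 5:7] = T.NUCLEUS  # area 4
        lab[20:26, 20:26] = T.NUCLEUS  # area 36
        nuclei, _ = extract_nuclei(semantic_from(lab), min_area=15)
        assert len(nuclei) == 1
        assert nuclei[0].area == 36

    def test_counts_match_ground_truth_on_synthetic_tile(self, tile_and_truth, scored_tile):
        """Detected nucleus count reconciles with the generator's placement
        counts (lymphocytes + tumor nuclei, minus min-area losses)."""
        _, gt = tile_and_truth
        placed = gt.n_lymphocytes + gt.n_tumor_nuclei
        detected = len(scored_tile.nuclei)
        assert placed * 0.9 <= detected <= placed * 1.1


class TestShapeFeatures:
    def test_disc_is_round_and_not_eccentric(self):
        lab = blank(80, 80)
        lab[disc_mask(80, 80, 40, 40, 15)] = T.NUCLEUS
        nuclei, _ = extract_nuclei(semantic_from(lab), flat_tile(80, 80))
        (n,) = nuclei
        assert 0.9 <= n.roundness <= 1.05
        assert n.eccentricity <= 0.2

    def test_ellipse_eccentricity_closed_form(self):
        """Axis-aligned ellipse with semi-axes 20 and 10: eccentricity
        sqrt(1 - (10/20)^2) = 0.866 on the rasterized mask."""
        h = w = 96
        rr, cc = np.mgrid[:h, :w]
        lab = blank(h, w)
        lab[((cc - 48) / 20.0) ** 2 + ((rr - 48) / 10.0) ** 2 <= 1.0] = T.NUCLEUS
        nuclei, _ = extract_nuclei(semantic_from(lab), flat_tile(h, w))
        assert nuclei[0].eccentricity == pytest.approx(np.sqrt(1 - 0.25), abs=0.05)

    def test_constant_color_zero_staining_sd(self):
        lab = blank()
        lab[10:20, 10:20] = T.NUCLEUS
        nuclei, _ = extract_nuclei(semantic_from(lab), flat_tile())
        assert nuclei[0].staining_sd == pytest.approx(0.0, abs=1e-9)

    def test_relative_size_uses_tile_median(self):
        lab = blank(96, 96)
        lab[5:10, 5:10] = T.NUCLEUS  # 25
        lab[20:25, 20:25] = T.NUCLEUS  # 25
        lab[40:50, 40:50] = T.NUCLEUS  # 100
        nuclei, _ = extract_nuclei(semantic_from(lab), min_area=5)
        rel = sorted(n.relative_size for n in nuclei)
        assert rel == pytest.approx([1.0, 1.0, 4.0])


class TestCellAttribution:
    def test_no_adjacent_cytoplasm_ratio_one(self):
        lab = blank()
        lab[10:15, 10:15] = T.NUCLEUS
        sem = semantic_from(lab)
        nuclei, img = extract_nuclei(sem, min_area=5)
        attribute_cells(nuclei, sem, img)
        assert nuclei[0].nucleus_to_cell_ratio == 1.0

    def test_disc_in_cytoplasm_pixel_count_oracle(self):
        h = w = 64
        lab = blank(h, w)
        cyto = disc_mask(h, w, 32, 32, 7)
        nucl = disc_mask(h, w, 32, 32, 5)
        lab[cyto] = T.CYTOPLASM
        lab[nucl] = T.NUCLEUS
        sem = semantic_from(lab)
        nuclei, img = extract_nuclei(sem, min_area=5)
        attribute_cells(nuclei, sem, img, max_dilation=3)
        expected = nucl.sum() / cyto.sum()  # exact pixel counts of the construction
        assert nuclei[0].nucleus_to_cell_ratio == pytest.approx(expected, abs=0.05)
        # and close to the continuous-area ratio 25/49
        assert nuclei[0].nucleus_to_cell_ratio == pytest.approx(25 / 49, abs=0.08)

    def test_shared_cytoplasm_partition_contract(self):
        """Two nuclei growing into one cytoplasm region claim disjoint
        areas whose union stays within the cytoplasm region."""
        lab = blank(40, 60)
        lab[10:30, 10:50] = T.CYTOPLASM
        lab[15:25, 14:22] = T.NUCLEUS
        lab[15:25, 38:46] = T.NUCLEUS
        sem = semantic_from(lab)
        nuclei, img = extract_nuclei(sem, min_area=5)
        cells = attribute_cells(nuclei, sem, img, max_dilation=5)
        a = (cells == 1) & (img == 0)
        b = (cells == 2) & (img == 0)
        assert not (a & b).any()
        assert ((a | b) <= (lab == T.CYTOPLASM)).all()

    def test_growth_confined_to_cytoplasm(self, scored_tile):
        cells_outside = 0
        # cell pixels beyond the nucleus must be cytoplasm-class
        sem = scored_tile.semantic
        for ly in scored_tile.lymphocytes:
            rr, cc = ly.cytoplasm_pixels
            cells_outside += int((sem.labels[rr, cc] != T.CYTOPLASM).sum())
        assert cells_outside == 0


class TestClassification:
    def _nucleus(self, **kw):
        from stilquant.nuclei import NucleusObject

        base = dict(
            index=1,
            area=50,
            perimeter=25.0,
            centroid=(1.0, 1.0),
            roundness=0.95,
            eccentricity=0.2,
            staining_sd=3.0,
            relative_size=0.5,
            cell_area=70,
            nucleus_to_cell_ratio=0.7,
        )
        base.update(kw)
        return NucleusObject(**base)

    def test_relative_size_threshold_contract(self):
        """A lone nucleus has relative size exactly 1; a 0.8 cut-off
        excludes it regardless of the other features."""
        n = self._nucleus(relative_size=1.0)
        lymph, other = classify_lymphocytes([n], LymphocyteThresholds(max_relative_size=0.8))
        assert lymph == [] and other == [n]

    def test_vacuous_thresholds_accept_everything(self):
        nuclei = [self._nucleus(index=i, eccentricity=0.99, staining_sd=99) for i in range(3)]
        t = LymphocyteThresholds(
            max_relative_size=np.inf,
            min_roundness=0.0,
            max_eccentricity=1.0,
            min_nucleus_cell_ratio=0.0,
            max_staining_sd=np.inf,
        )
        lymph, other = classify_lymphocytes(nuclei, t)
        assert len(lymph) == 3 and other == []

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            classify_lymphocytes([])

    def test_monotone_in_every_threshold(self, rng):
        """Relaxing any cut-off never removes a lymphocyte."""
        nuclei = [
            self._nucleus(
                index=i,
                relative_size=rng.uniform(0.1, 3),
                roundness=rng.uniform(0.5, 1.1),
                eccentricity=rng.uniform(0, 1),
                nucleus_to_cell_ratio=rng.uniform(0.2, 1),
                staining_sd=rng.uniform(0, 40),
            )
            for i in range(50)
        ]
        tight = LymphocyteThresholds()
        loose = LymphocyteThresholds(
            max_relative_size=3.0,
            min_roundness=0.6,
            max_eccentricity=0.9,
            min_nucleus_cell_ratio=0.3,
            max_staining_sd=30.0,
        )
        lymph_tight, _ = classify_lymphocytes(nuclei, tight)
        lymph_loose, _ = classify_lymphocytes(nuclei, loose)
        assert {n.index for n in lymph_tight} <= {n.index for n in lymph_loose}

    def test_sensitivity_specificity_on_synthetic_tile(self, tile_and_truth, scored_tile):
        """Small-round lymphocyte nuclei vs large-elongated tumor nuclei:
        classification agrees with the ground-truth labels at >= 0.9
        sensitivity and specificity."""
        _, gt = tile_and_truth
        lymph_nuclei = [ly.nucleus for ly in scored_tile.lymphocytes]
        lymph_idx = {n.index for n in lymph_nuclei}

        def truth_at(n):
            r, c = (int(round(x)) for x in n.centroid)
            return gt.semantic[r, c]

        tp = sum(1 for n in lymph_nuclei if truth_at(n) == T.GT_LYMPH_NUCLEUS)
        tumor_detected = [n for n in scored_tile.nuclei if truth_at(n) == T.GT_TUMOR_NUCLEUS]
        fp = sum(1 for n in tumor_detected if n.index in lymph_idx)
        sensitivity = tp / gt.n_lymphocytes
        specificity = 1 - fp / max(len(tumor_detected), 1)
        assert sensitivity >= 0.9
        assert specificity >= 0.9


class TestAssembly:
    def test_nucleus_without_cytoplasm_has_empty_set(self):
        lab = blank()
        lab[10:15, 10:15] = T.NUCLEUS
        sem = semantic_from(lab)
        nuclei, img = extract_nuclei(sem, min_area=5)
        cells = attribute_cells(nuclei, sem, img)
        (ly,) = assemble_lymphocytes(nuclei, cells, img)
        assert len(ly.cytoplasm_pixels[0]) == 0
        assert ly.total_area == 25

    def test_pixel_conservation_and_disjointness(self, scored_tile):
        """Total lymphocyte pixels = nucleus + attributed cytoplasm, and no
        pixel belongs to two lymphocytes."""
        seen = set()
        for ly in scored_tile.lymphocytes:
            px = set(zip(*ly.cytoplasm_pixels))
            assert not (px & seen)
            seen |= px
            assert ly.total_area == ly.nucleus.area + len(px)

    def test_lymphocyte_area_close_to_truth(self, tile_and_truth, scored_tile):
        _, gt = tile_and_truth
        est = sum(ly.total_area for ly in scored_tile.lymphocytes)
        true = int(gt.lymphocyte_mask.sum())
        assert est == pytest.approx(true, rel=0.10)
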