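"""Normalization, isodose-band structures, objective templates, penalty."""

import numpy as np
import pytest

from dosemimic import (
    BandSpec,
    DoseGrid,
    DoseObjective,
    Prescription,
    StructureMask,
    StructureSet,
    build_objectives,
    extract_band,
    generate_optimization_structures,
    load_template,
    mask_subtract,
    merge_structure_sets,
    normalize_dose,
    objective_penalty,
)
from dosemimic.mimic import BODY_BANDS, LUNG_BANDS, PTV_BAND

from conftest import random_grid, random_mask

RX = Prescription()


def toy_anatomy(shape=(10, 10, 10)):
    g = DoseGrid((0, 0, 0), (2, 2, 2), np.zeros(shape))
    body = np.ones(shape, bool)
    ptv = np.zeros(shape, bool)
    ptv[3:7, 3:7, 3:7] = True
    ctv = np.zeros(shape, bool)
    ctv[4:6, 4:6, 4:6] = True
    lungs = np.zeros(shape, bool)
    lungs[1:9, 1:5, 1:9] = True
    sset = StructureSet()
    for name, occ in [("Body", body), ("PTV", ptv), ("CTV", ctv), ("Lungs", lungs)]:
        sset.add(StructureMask(name, occ, g.frame_id))
    return g, sset


class TestNormalize:
    def test_scale_factor_from_d50(self):
        g, sset = toy_anatomy()
        dose = g.with_values(np.full(g.shape, 57.0))
        out = normalize_dose(dose, sset["PTV"], RX)
        np.testing.assert_allclose(out.values, 57.0 * 60.0 / 57.0)
        d50 = np.median(out.values[sset["PTV"].occupancy])
        assert d50 == pytest.approx(60.0, rel=1e-12)

    def test_idempotent(self, small_case, rx):
        _, sset, dose = small_case
        once = normalize_dose(dose, sset["PTV"], rx)
        twice = normalize_dose(once, sset["PTV"], rx)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_zero_dose_rejected(self):
        g, sset = toy_anatomy()
        with pytest.raises(ValueError, match="D50"):
            normalize_dose(g.with_values(np.zeros(g.shape)), sset["PTV"], RX)


class TestBandExtraction:
    def test_uniform_field_fills_matching_band_only(self):
        g, sset = toy_anatomy()
        dose = g.with_values(np.full(g.shape, 0.5 * RX.total_dose))  # 50% of Rx
        hit = extract_band(dose, RX, BandSpec("b", 40.0, 60.0, "Body"), sset)
        np.testing.assert_array_equal(hit.occupancy, sset["Body"].occupancy)
        miss = extract_band(dose, RX, BandSpec("b", 60.0, 80.0, "Body"), sset)
        assert miss.voxel_count == 0

    def test_uniform_target_dose_empties_ptv_band(self):
        g, sset = toy_anatomy()
        dose = g.with_values(np.full(g.shape, RX.total_dose))  # 100% everywhere
        band = extract_band(dose, RX, PTV_BAND, sset)
        assert band.voxel_count == 0

    def test_half_open_interval_convention(self):
        g, sset = toy_anatomy()
        # voxel exactly at the 8.3% boundary belongs to the upper band
        dose = g.with_values(np.full(g.shape, 0.083 * RX.total_dose))
        lower = extract_band(dose, RX, BandSpec("a", 5.0, 8.3, "Body"), sset)
        upper = extract_band(dose, RX, BandSpec("b", 8.3, 33.0, "Body"), sset)
        assert lower.voxel_count == 0
        assert upper.voxel_count == sset["Body"].voxel_count

    def test_random_field_matches_per_voxel_oracle(self):
        rng = np.random.default_rng(0)
        g, sset = toy_anatomy((8, 8, 8))
        dose = g.with_values(rng.random(g.shape) * 70.0)
        for band in (*BODY_BANDS, *LUNG_BANDS):
            got = extract_band(dose, RX, band, sset).occupancy
            dom = sset[band.domain].occupancy
            for idx in np.ndindex(*g.shape):
                pct = dose.values[idx] / RX.total_dose * 100.0
                assert got[idx] == (dom[idx] and band.low <= pct < band.high)
        got = extract_band(dose, RX, PTV_BAND, sset).occupancy
        for idx in np.ndindex(*g.shape):
            pct = dose.values[idx] / RX.total_dose * 100.0
            assert got[idx] == (sset["PTV"].occupancy[idx] and not (99.0 <= pct < 110.0))

    def test_adjacent_bands_partition_their_range(self, small_case, rx):
        _, sset, dose = small_case
        a = extract_band(dose, rx, BODY_BANDS[0], sset)  # 5.0-8.3
        b = extract_band(dose, rx, BODY_BANDS[1], sset)  # 8.3-33.0
        assert not np.any(a.occupancy & b.occupancy)
        pct = dose.values / rx.total_dose * 100.0
        union_expected = sset["Body"].occupancy & (pct >= 5.0) & (pct < 33.0)
        np.testing.assert_array_equal(a.occupancy | b.occupancy, union_expected)

    def test_uniform_levels_sweep(self):
        # every integer level 1..110% lands in exactly the bands containing it
        g, sset = toy_anatomy((6, 6, 6))
        nbody = sset["Body"].voxel_count
        for level in range(1, 111):
            dose = g.with_values(np.full(g.shape, level / 100.0 * RX.total_dose))
            for band in BODY_BANDS:
                n = extract_band(dose, RX, band, sset).voxel_count
                assert n == (nbody if band.low <= level < band.high else 0)

    def test_unknown_domain_rejected(self):
        g, sset = toy_anatomy()
        with pytest.raises(ValueError):
            extract_band(g.with_values(np.zeros(g.shape)), RX,
                         BandSpec("x", 1, 2, "Esophagus"), sset)


class TestOptimizationStructures:
    def test_exactly_twelve_stable_names(self, small_case, rx):
        _, sset, dose = small_case
        out = generate_optimization_structures(dose, sset, rx)
        assert len(out) == 12
        expected = (
            [b.name for b in BODY_BANDS] + [b.name for b in LUNG_BANDS]
            + [PTV_BAND.name, "PTV-CTV"]
        )
        assert out.names == expected

    def test_ptv_ctv_is_exact_subtraction(self, small_case, rx):
        _, sset, dose = small_case
        out = generate_optimization_structures(dose, sset, rx)
        ref = mask_subtract(sset["PTV"], sset["CTV"])
        np.testing.assert_array_equal(out["PTV-CTV"].occupancy, ref.occupancy)

    def test_body_bands_contained_in_body(self, small_case, rx):
        _, sset, dose = small_case
        out = generate_optimization_structures(dose, sset, rx)
        for band in BODY_BANDS:
            assert not np.any(out[band.name].occupancy & ~sset["Body"].occupancy)
        for band in LUNG_BANDS:
            assert not np.any(out[band.name].occupancy & ~sset["Lungs"].occupancy)

    def test_missing_anatomy_rejected(self, small_case, rx):
        _, sset, dose = small_case
        partial = StructureSet()
        partial.add(sset["Body"])
        with pytest.raises(ValueError, match="Lungs"):
            generate_optimization_structures(dose, partial, rx)


class TestObjectiveTemplates:
    def test_mimicking_template_has_21_rows(self, small_case, rx):
        _, sset, dose = small_case
        merged = merge_structure_sets(sset, generate_optimization_structures(dose, sset, rx))
        objs = build_objectives(merged, "ratoguide")
        assert len(objs) == 21

    def test_mimicking_template_priorities(self, small_case, rx):
        _, sset, dose = small_case
        merged = merge_structure_sets(sset, generate_optimization_structures(dose, sset, rx))
        objs = build_objectives(merged, "ratoguide")
        assert {o.priority for o in objs} == {500, 550, 600, 700, 800, 950}

    def test_dvh_predicted_template_is_static_subset(self, small_case, rx):
        _, sset, dose = small_case
        merged = merge_structure_sets(sset, generate_optimization_structures(dose, sset, rx))
        objs = build_objectives(merged, "rapidplan_static")
        structures = {o.structure for o in objs}
        assert structures.isdisjoint({"Lungs", "Esophagus", "Heart"})
        assert {"CTV", "PTV", "PTV-CTV", "SpinalCord", "SpinalCord_PRV"} <= structures
        tpl = load_template("rapidplan_static")
        assert {row["structure"] for row in tpl["line_objectives"]} == {
            "Lungs", "Esophagus", "Heart",
        }
        assert tpl["normal_tissue_objective"]["falloff_cm"] == 0.25

    def test_missing_structures_listed_in_error(self):
        g, sset = toy_anatomy()  # no band structures present
        with pytest.raises(ValueError) as err:
            build_objectives(sset, "ratoguide")
        assert "PTV-CTV" in str(err.value) and "dose_5.0-8.3%" in str(err.value)


class TestObjectivePenalty:
    def test_satisfying_dose_scores_zero(self):
        g, sset = toy_anatomy()
        dose = g.with_values(np.full(g.shape, 50.0))
        objs = [
            DoseObjective("Body", "Upper", 0, 60.0, 100.0),
            DoseObjective("PTV", "Lower", 100, 40.0, 100.0),
        ]
        total, per = objective_penalty(dose, objs, sset)
        assert total == 0.0 and all(v == 0.0 for v in per.values())

    def test_single_voxel_direct_formula(self):
        g = DoseGrid((0, 0, 0), (2, 2, 2), np.full((1, 1, 1), 61.4))
        sset = StructureSet()
        sset.add(StructureMask("S", np.ones((1, 1, 1), bool), g.frame_id))
        total, _ = objective_penalty(g, [DoseObjective("S", "Upper", 0, 59.4, 800.0)], sset)
        assert total == pytest.approx(800.0 * 2.0**2, rel=1e-12)

    def test_random_dose_matches_bruteforce_sum(self):
        rng = np.random.default_rng(1)
        g, sset = toy_anatomy((8, 8, 8))
        dose = g.with_values(rng.random(g.shape) * 80.0)
        objs = [
            DoseObjective("PTV", "Lower", 100, 59.4, 950.0),
            DoseObjective("Body", "Upper", 0, 30.0, 500.0),
            DoseObjective("Lungs", "Upper", 0, 10.0, 800.0),
        ]
        total, per = objective_penalty(dose, objs, sset)
        brute = 0.0
        for obj in objs:
            occ = sset[obj.structure].occupancy
            acc = 0.0
            for idx in np.ndindex(*g.shape):
                if not occ[idx]:
                    continue
                d = dose.values[idx]
                v = max(0.0, d - obj.dose) if obj.kind == "Upper" else max(0.0, obj.dose - d)
                acc += v * v
            brute += obj.priority / occ.sum() * acc
        assert total == pytest.approx(brute, rel=1e-9)
        assert total == pytest.approx(sum(per.values()), rel=1e-12)

    def test_complementarity_zero_iff_no_violation(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g, sset = toy_anatomy((6, 6, 6))
            dose = g.with_values(rng.random(g.shape) * 80.0)
            obj = DoseObjective("Body", "Upper", 0, float(rng.uniform(20, 90)), 100.0)
            total, _ = objective_penalty(dose, [obj], sset)
            violated = np.any(dose.values > obj.dose)
            assert (total > 0) == bool(violated)

    def test_empty_structure_warns_and_contributes_zero(self):
        g, sset = toy_anatomy()
        sset.add(StructureMask("Empty", np.zeros(g.shape, bool), g.frame_id))
        dose = g.with_values(np.full(g.shape, 80.0))
        with pytest.warns(UserWarning, match="empty"):
            total, per = objective_penalty(dose, [DoseObjective("Empty", "Upper", 0, 1.0, 10.0)], sset)
        assert total == 0.0

    def test_unsupported_volume_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            DoseObjective("S", "Upper", 50, 30.0, 100.0)
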