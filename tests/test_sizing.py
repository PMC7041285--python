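"""Sizing rules: Pollard derivation, dimension and MeSD selection,
template construction."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from meniscus3d.bank import AllograftBank, BankEntry, RadiographMeasure
from meniscus3d.mesh_model import Laterality, Side, mirror_to_right
from meniscus3d.obb import MeniscusDimensions, measure_dimensions
from meniscus3d.sizing import (
    SizingMethod,
    SizingTemplate,
    build_template,
    pollard_derive,
    select_by_dims,
    select_by_mesd,
)
from meniscus3d.surface_distance import SurfaceDistanceEngine
from meniscus3d.synthetic import PopulationParams, generate_bank, generate_patient

from conftest import small_meniscus


class TestPollard:
    def test_medial_factor(self):
        dims = pollard_derive(RadiographMeasure(30.0, 50.0), Side.MEDIAL)
        assert (dims.width, dims.length) == (30.0, 40.0)

    def test_lateral_factor(self):
        dims = pollard_derive(RadiographMeasure(30.0, 50.0), Side.LATERAL)
        assert (dims.width, dims.length) == (30.0, 35.0)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            RadiographMeasure(0.0, 50.0)
        with pytest.raises(ValueError):
            RadiographMeasure(30.0, -1.0)


def _dims_bank(dims_list, side=Side.MEDIAL):
    """Bank of entries that differ only in dims (shared placeholder mesh)."""
    mesh = small_meniscus(seed=0)
    entries = []
    for i, (w, ln) in enumerate(dims_list):
        d = MeniscusDimensions(width=w, length=ln, height=9.0)
        d2 = MeniscusDimensions(width=w, length=ln, height=None)
        entries.append(BankEntry(
            entry_id=f"E{i:03d}", patient_id=f"P{i:03d}", side=side,
            source_laterality=Laterality.RIGHT, mesh=mesh,
            dims3d=d, dims2d=d2,
        ))
    return AllograftBank(entries)


class TestSelectByDims:
    def test_worked_example(self):
        bank = _dims_bank([(31, 46), (28, 44), (33, 43)])
        target = MeniscusDimensions(width=30, length=45, height=None)
        result = select_by_dims(target, bank, Side.MEDIAL)
        scores = dict(result.ranking)
        assert scores["E000"] == pytest.approx(2.0)
        assert scores["E001"] == pytest.approx(5.0)
        assert scores["E002"] == pytest.approx(13.0)
        assert result.selected_id == "E000"

    def test_exact_match_scores_zero(self):
        bank = _dims_bank([(31, 46), (30, 45)])
        target = MeniscusDimensions(width=30, length=45, height=None)
        result = select_by_dims(target, bank, Side.MEDIAL)
        assert result.selected_id == "E001"
        assert result.score == 0.0

    def test_tie_broken_by_smaller_id(self):
        bank = _dims_bank([(31, 45), (29, 45)])  # equidistant from (30, 45)
        target = MeniscusDimensions(width=30, length=45, height=None)
        result = select_by_dims(target, bank, Side.MEDIAL)
        assert result.selected_id == "E000"

    def test_exclusion_empties_pool(self):
        bank = _dims_bank([(31, 46)])
        target = MeniscusDimensions(width=30, length=45, height=None)
        with pytest.raises(ValueError):
            select_by_dims(target, bank, Side.MEDIAL, exclude_patient="P000")

    @given(st.lists(
        st.tuples(st.floats(20, 40), st.floats(30, 55)),
        min_size=1, max_size=20,
    ), st.floats(20, 40), st.floats(30, 55))
    def test_equals_bruteforce_argmin(self, dims_list, tw, tl):
        bank = _dims_bank(dims_list)
        target = MeniscusDimensions(width=tw, length=tl, height=None)
        result = select_by_dims(target, bank, Side.MEDIAL)
        brute = min(
            ((e.entry_id, (tw - e.dims3d.width) ** 2 + (tl - e.dims3d.length) ** 2)
             for e in bank.entries),
            key=lambda kv: (kv[1], kv[0]),
        )
        assert result.selected_id == brute[0]
        assert result.score == pytest.approx(brute[1])


def _mesh_bank(n=5, seed0=30):
    entries = []
    for i in range(n):
        mesh = small_meniscus(seed=seed0 + i, patient_id=f"P{i:03d}",
                              dims=(29 + i, 44 + (i % 3), 9 + 0.2 * i))
        d = measure_dimensions(mesh)
        entries.append(BankEntry(
            entry_id=f"E{i:03d}", patient_id=f"P{i:03d}", side=Side.MEDIAL,
            source_laterality=Laterality.RIGHT, mesh=mesh, dims3d=d,
            dims2d=MeniscusDimensions(d.width, d.length, None),
        ))
    return AllograftBank(entries)


class TestSelectByMesd:
    def test_exact_copy_dominates(self):
        bank = _mesh_bank()
        template = bank.entries[2].mesh
        result = select_by_mesd(template, bank, Side.MEDIAL,
                                engine=SurfaceDistanceEngine(density=1.0))
        assert result.selected_id == "E002"
        assert result.score < 1e-3

    def test_equals_bruteforce_pairwise_argmin(self):
        bank = _mesh_bank()
        engine = SurfaceDistanceEngine(density=1.0)
        template = small_meniscus(seed=99, patient_id="Q",
                                  dims=(30.5, 44.5, 9.1))
        result = select_by_mesd(template, bank, Side.MEDIAL, engine=engine)
        brute = min(
            ((e.entry_id, engine.distance(template, e.mesh).mesd)
             for e in bank.entries),
            key=lambda kv: (kv[1], kv[0]),
        )
        assert result.selected_id == brute[0]
        assert result.score == pytest.approx(brute[1], abs=1e-12)

    def test_excluded_patient_never_ranked(self):
        bank = _mesh_bank()
        template = bank.entries[0].mesh
        result = select_by_mesd(template, bank, Side.MEDIAL,
                                exclude_patient="P000",
                                engine=SurfaceDistanceEngine(density=1.0))
        assert all(eid != "E000" for eid, _ in result.ranking)

    def test_mirrored_partner_selected_at_zero_asymmetry(self):
        params = PopulationParams(seed=21, asymmetry_amplitude=0.0,
                                  n_arc=24, n_section=10)
        bank, _ = generate_bank(params, n_bilateral=3, n_unilateral=0)
        entries = bank.per_side(Side.MEDIAL)
        original = entries[0]
        partner = bank.contralateral(original)
        result = select_by_mesd(
            partner.mesh, bank, Side.MEDIAL,
            engine=SurfaceDistanceEngine(density=1.0),
        )
        # the template IS the partner's bank mesh; the original is its
        # zero-asymmetry mirror image, so one of the two tops the ranking
        assert result.ranking[0][0] in (original.entry_id, partner.entry_id)
        assert dict(result.ranking)[original.entry_id] < 0.05


class TestBuildTemplate:
    def test_mri3d_template_close_to_original(self):
        params = PopulationParams(seed=22, asymmetry_amplitude=0.0,
                                  n_arc=24, n_section=10)
        patient = generate_patient(params, "P1")
        template = build_template(SizingMethod.MRI3D, patient, Side.MEDIAL,
                                  Laterality.RIGHT)
        original = patient.menisci[(Laterality.RIGHT, Side.MEDIAL)]
        from meniscus3d.surface_distance import surface_distance

        res = surface_distance(template.template_mesh, original, density=2.0)
        assert res.mesd < 0.05

    def test_rx2d_template_zero_noise(self):
        params = PopulationParams(seed=23, rx_width_sd=0.0, rx_length_sd=0.0)
        patient = generate_patient(params, "P1")
        template = build_template(SizingMethod.RX2D, patient, Side.LATERAL,
                                  Laterality.RIGHT)
        true = measure_dimensions(patient.menisci[(Laterality.RIGHT, Side.LATERAL)])
        assert template.target_dims.width == pytest.approx(true.width, rel=0.02)
        assert template.target_dims.length == pytest.approx(true.length, rel=0.02)

    def test_mri2d_template_dims_within_asymmetry(self):
        params = PopulationParams(seed=24, asymmetry_amplitude=0.4,
                                  n_arc=24, n_section=10)
        devs = []
        for i in range(12):
            patient = generate_patient(params, f"P{i}")
            template = build_template(SizingMethod.MRI2D, patient, Side.MEDIAL,
                                      Laterality.RIGHT)
            true = measure_dimensions(
                patient.menisci[(Laterality.RIGHT, Side.MEDIAL)])
            devs.append(abs(template.target_dims.width - true.width))
            devs.append(abs(template.target_dims.length - true.length))
        # dim jitter SD is asymmetry/3; allow the ~3-sigma envelope
        assert np.mean(devs) < params.asymmetry_amplitude
        assert np.max(devs) < 4 * params.asymmetry_amplitude

    def test_template_field_requirements(self):
        with pytest.raises(ValueError):
            SizingTemplate(SizingMethod.MRI3D)
        with pytest.raises(ValueError):
            SizingTemplate(SizingMethod.RX2D)

    def test_missing_contralateral_raises(self):
        params = PopulationParams(seed=25, n_arc=24, n_section=10)
        patient = generate_patient(params, "P1")
        del patient.menisci[(Laterality.LEFT, Side.MEDIAL)]
        with pytest.raises(ValueError):
            build_template(SizingMethod.MRI3D, patient, Side.MEDIAL,
                           Laterality.RIGHT)
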