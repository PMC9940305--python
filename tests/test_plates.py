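"""Plate design: layout, sampling, volumes, picklist, 1536 interleave."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from nanomcr import (
    InfeasibleDesignError,
    WellAddress,
    build_campaign,
    compute_transfer_volume,
    export_picklist,
    generate_bank,
    layout_source_plate,
    map_to_1536,
    read_picklist,
    sample_sparse_matrix,
    theoretical_space_size,
)
from nanomcr.plates import PICKLIST_HEADER, row_index, row_letter, source_volume_audit


class TestSourceLayout:
    def test_study_bank_fits_one_plate(self, study_bank):
        source_map = layout_source_plate(study_bank)
        assert len(source_map) == 336
        plates = {a.plate_id for a in source_map.values()}
        assert plates == {"Source[1]"}  # 48 wells to spare
        assert len(set(source_map.values())) == 336  # bijective

    def test_column_major_order(self, tiny_bank):
        source_map = layout_source_plate(tiny_bank)
        first = source_map[tiny_bank.blocks[0].id]
        second = source_map[tiny_bank.blocks[1].id]
        assert (first.row, first.col) == ("A", 1)
        assert (second.row, second.col) == ("B", 1)

    def test_empty_bank_empty_map(self):
        assert layout_source_plate(generate_bank({}, seed=0)) == {}

    def test_oversized_bank_spills_with_warning(self, study_bank):
        class FakeBank:
            blocks = study_bank.blocks * 2  # 672 entries

            def __len__(self):
                return len(self.blocks)

        with pytest.warns(UserWarning):
            source_map = layout_source_plate(FakeBank())
        plates = {a.plate_id for a in source_map.values()}
        assert plates == {"Source[1]", "Source[2]"}


class TestSparseSampling:
    def test_distinct_and_seeded(self, registry, study_bank):
        a = sample_sparse_matrix(registry.get(1), study_bank, 96, seed=4)
        b = sample_sparse_matrix(registry.get(1), study_bank, 96, seed=4)
        assert a == b
        assert len(set(a)) == 96

    def test_full_space_returns_every_combination(self, registry):
        bank = generate_bank({"amidine": 2, "aldehyde": 3, "isocyanide": 2}, seed=3)
        scheme = registry.get(1)
        space = theoretical_space_size(scheme, bank)
        combos = sample_sparse_matrix(scheme, bank, space, seed=0)
        assert len(set(combos)) == space == 12

    def test_zero_request_is_empty(self, registry, study_bank):
        assert sample_sparse_matrix(registry.get(1), study_bank, 0, seed=0) == []

    def test_oversubscription_names_the_scheme(self, registry):
        bank = generate_bank({"amidine": 1, "aldehyde": 1, "isocyanide": 1}, seed=0)
        with pytest.raises(InfeasibleDesignError, match="GBB"):
            sample_sparse_matrix(registry.get(1), bank, 2, seed=0)


class TestTransferVolumes:
    @pytest.mark.parametrize(
        "scale,conc,expected",
        [(500, 0.5, 1000.0), (375, 0.25, 1500.0), (300, 0.16, 1875.0), (0, 0.5, 0.0)],
    )
    def test_hand_computed_volumes(self, scale, conc, expected):
        assert compute_transfer_volume(scale, conc, 2.5) == expected

    def test_rounds_up_to_droplet_multiple(self):
        # 300 nmol / 0.25 M = 1200 nL is a multiple; 301 is not
        assert compute_transfer_volume(301, 0.25, 2.5) == 1205.0

    def test_invalid_inputs_rejected(self):
        for bad in [(-1, 0.5, 2.5), (100, 0, 2.5), (100, 0.5, 0)]:
            with pytest.raises(ValueError):
                compute_transfer_volume(*bad)

    @settings(max_examples=100, deadline=None)
    @given(
        scale=st.floats(0.1, 1000),
        conc=st.sampled_from([0.5, 0.25, 0.16]),
    )
    def test_volume_is_droplet_multiple_and_sufficient(self, scale, conc):
        v = compute_transfer_volume(scale, conc, 2.5)
        assert v >= scale / conc - 1e-6  # never under-delivers
        assert abs(v / 2.5 - round(v / 2.5)) < 1e-9


class TestCampaign:
    def test_study_design_arithmetic(self, study_campaign):
        assert len(study_campaign.wells) == 1536
        assert len(study_campaign.destination_plates) == 4
        assert len(study_campaign.source_plates) == 1

    def test_blocks_are_scheme_contiguous(self, study_campaign):
        for k, well in enumerate(study_campaign.wells):
            assert well.scheme_id == k // 96 + 1
        # four schemes per destination plate, in scheme-id order
        for well in study_campaign.wells[:384]:
            assert well.destination.plate_id == "Destination[1]"

    def test_well_conservation_per_scheme(self, study_campaign, registry):
        for scheme in registry:
            wells = study_campaign.wells_for_scheme(scheme.scheme_id)
            assert len(wells) == 96
            assert len({w.slot_choice for w in wells}) == 96
            for w in wells:
                assert w.scale_nmol == scheme.scale_nmol

    def test_transfer_conservation(self, study_campaign, registry, study_bank):
        """Each well receives one transfer per slot plus its bank-held reagents."""
        by_dest = {}
        for t in study_campaign.transfers:
            by_dest.setdefault(t.destination, []).append(t)
        source_ids = set(study_campaign.source_map)
        for w in study_campaign.wells:
            scheme = registry.get(w.scheme_id)
            n_reagents = sum(1 for r in scheme.reagents if r["id"] in source_ids)
            assert len(by_dest[w.destination]) == len(scheme.slots) + n_reagents
            for t in by_dest[w.destination]:
                assert t.volume_nl > 0
                assert abs(t.volume_nl / 2.5 - round(t.volume_nl / 2.5)) < 1e-9

    def test_single_scheme_fills_one_plate(self, registry, study_bank):
        c = build_campaign([registry.get(1)], study_bank, 96, seed=0)
        assert len(c.wells) == 96
        assert len(c.destination_plates) == 1

    def test_overflow_recomputes_plate_count(self, registry, study_bank):
        c = build_campaign(list(registry), study_bank, 100, seed=0)
        assert len(c.wells) == 1600
        assert len(c.destination_plates) == math.ceil(1600 / 384) == 5

    def test_design_is_deterministic(self, registry, study_bank, study_campaign):
        again = build_campaign(list(registry), study_bank, 96, seed=1)
        assert export_picklist(again) == export_picklist(study_campaign)

    def test_source_audit_totals_match(self, study_campaign):
        audit = source_volume_audit(study_campaign)
        assert sum(audit.values()) == pytest.approx(
            sum(t.volume_nl for t in study_campaign.transfers)
        )


class TestPicklist:
    def test_header_is_exact(self, study_campaign):
        text = export_picklist(study_campaign)
        assert text.splitlines()[0] == PICKLIST_HEADER

    def test_row_count_lower_bound(self, study_campaign):
        # 1536 wells x >= 2 variable slots each
        assert len(study_campaign.transfers) >= 2 * 1536

    def test_round_trip_is_byte_identical(self, study_campaign):
        text = export_picklist(study_campaign)
        assert export_picklist(read_picklist(text)) == text

    def test_bad_header_rejected(self):
        with pytest.raises(ValueError):
            read_picklist("A,B,C\n1,2,3\n")


class TestQuadrantInterleave:
    def test_origin_fixed_point(self):
        mapper = map_to_1536(["P1", "P2", "P3", "P4"])
        out = mapper.forward(WellAddress("P1", "A", 1))
        assert (out.row, out.col) == ("A", 1)

    def test_bijective_with_exact_inverse(self):
        plates = ["P1", "P2", "P3", "P4"]
        mapper = map_to_1536(plates)
        targets = set()
        for pid in plates:
            for r in range(16):
                for c in range(24):
                    addr = WellAddress(pid, row_letter(r), c + 1)
                    out = mapper.forward(addr)
                    assert 0 <= row_index(out.row) < 32 and 1 <= out.col <= 48
                    targets.add((out.row, out.col))
                    assert mapper.inverse(out) == addr
        assert len(targets) == 1536

    def test_wrong_plate_count_rejected(self):
        with pytest.raises(ValueError):
            map_to_1536(["P1", "P2", "P3"])
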