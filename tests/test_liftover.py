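import pytest

from riboaudit.liftover import (
    UNMAPPED,
    build_position_map,
    detect_register_offset,
    lift_site,
    site_table,
    validate_known_sites,
)
from riboaudit.registry import ReferenceRecord, SiteAnnotation
from riboaudit.structure import ChainSequence, ResidueRecord
from riboaudit.synthetic import mutate


def as_chain(record, auth_start=1, model_id="M", chain_id="A"):
    return ChainSequence(
        model_id, chain_id,
        [ResidueRecord(auth_start + i, b) for i, b in enumerate(record.sequence)],
    )


def deleted_variant(record, start, end, record_id):
    """record with 1-based positions start..end removed."""
    seq = record.sequence[: start - 1] + record.sequence[end:]
    return ReferenceRecord(record_id, record.molecule_class, "synthetic", sequence=seq)


def test_identity_map_on_identical_sequences(ref_300):
    twin = ReferenceRecord("twin", "18S", "synthetic", sequence=ref_300.sequence)
    pmap = build_position_map(ref_300, twin)
    pmap.validate()
    assert all(pmap.lift(k) == k for k in range(1, 301))


def test_deleted_block_is_unmapped_and_downstream_shifts():
    # hand-built so removing positions 5-7 has no shift-equivalent placement
    a = ReferenceRecord("a24", "5S", "synthetic",
                        sequence="AACCGGUACAUGCAUGCAUGCGUA")
    b = deleted_variant(a, 5, 7, "bdel")
    pmap = build_position_map(a, b)
    pmap.validate()
    assert pmap.lift(4) == 4
    assert pmap.lift(5) is None and pmap.lift(6) is None and pmap.lift(7) is None
    assert pmap.lift(8) == 5
    assert pmap.lift(24) == 21


def test_map_inversion_round_trips(ref_300):
    b = deleted_variant(ref_300, 100, 110, "bdel2")
    pmap = build_position_map(ref_300, b)
    back = pmap.invert().invert()
    assert back.a_to_b == pmap.a_to_b


def test_position_maps_from_mutants_are_monotone(ref_300):
    for seed in range(5):
        chain, _ = mutate(ref_300, n_subs=3, n_ins=2, n_del=2, seed=seed)
        mutant = ReferenceRecord(f"mut{seed}", "18S", "synthetic", sequence=chain.sequence)
        build_position_map(ref_300, mutant).validate()


def test_lift_site_through_identity_and_deletion(ref_300):
    twin = ReferenceRecord("twin", "18S", "synthetic", sequence=ref_300.sequence)
    pmap = build_position_map(ref_300, twin)
    site = SiteAnnotation("s42", ref_300.record_id, 42, expected_base=ref_300.sequence[41])
    lifted = lift_site(pmap, site, twin)
    assert lifted.position == 42 and lifted.base_matches is True

    b = deleted_variant(ref_300, 40, 45, "bdel3")
    lifted = lift_site(build_position_map(ref_300, b), site)
    assert lifted.position == UNMAPPED

    with pytest.raises(ValueError, match="outside"):
        lift_site(pmap, SiteAnnotation("far", ref_300.record_id, 2000))
    with pytest.raises(ValueError, match="does not match map source"):
        lift_site(pmap, SiteAnnotation("other", "another_scheme", 42))


def test_site_table_shifts_past_an_insertion(ref_300):
    # scheme b = a with 2 nt inserted before position 50
    seq = ref_300.sequence[:49] + "CU" + ref_300.sequence[49:]
    # guard against ambiguous gap placement in this constructed example:
    # the inserted run must not extend a repeat of its flanking bases
    assert seq[48] != "U" and ref_300.sequence[49] != "C"
    b = ReferenceRecord("b_ins", "18S", "synthetic", sequence=seq)
    sites = [
        SiteAnnotation("early", ref_300.record_id, 20),
        SiteAnnotation("late", ref_300.record_id, 100),
    ]
    table = site_table([ref_300, b], sites)
    assert table.loc["early", ref_300.record_id] == 20
    assert table.loc["early", "b_ins"] == 20
    assert table.loc["late", "b_ins"] == 102

    own = site_table([ref_300], sites)
    assert list(own[ref_300.record_id]) == [20, 100]


def test_composition_consistency_on_disjoint_indels(ref_300):
    # a -> b deletes 60..62; b -> c deletes (b-coordinates) 150..151.
    b = deleted_variant(ref_300, 60, 62, "b")
    c = deleted_variant(b, 150, 151, "c")
    ab = build_position_map(ref_300, b)
    bc = build_position_map(b, c)
    ac = build_position_map(ref_300, c)
    for pos in range(1, 301):
        via_b = ab.lift(pos)
        composed = bc.lift(via_b) if via_b is not None else None
        assert composed == ac.lift(pos)


def test_register_offset_detection(ref_300):
    assert detect_register_offset(as_chain(ref_300, auth_start=2), ref_300) == 1
    assert detect_register_offset(as_chain(ref_300, auth_start=1), ref_300) == 0
    chain, _ = mutate(ref_300, n_subs=2, n_del=1, numbering_offset=-3, seed=8)
    assert detect_register_offset(chain, ref_300) == -3

    scrambled = as_chain(ref_300)
    for i, res in enumerate(scrambled.residues):
        res.auth_number = (i * 37) % 300 + 1  # no consistent offset
    assert detect_register_offset(scrambled, ref_300) is None


def test_validate_known_sites_reports_bases_and_range(ref_300):
    seq = ref_300.sequence
    sites = [
        SiteAnnotation("ok", ref_300.record_id, 183, expected_base=seq[182]),
        SiteAnnotation("wrong", ref_300.record_id, 184,
                       expected_base={"A": "C", "C": "A", "G": "U", "U": "G"}[seq[183]]),
        SiteAnnotation("beyond", ref_300.record_id, 1869, expected_base="C"),
    ]
    checks = validate_known_sites(ref_300, sites)
    assert [c.passed for c in checks] == [True, False, False]
    assert "out of range" in checks[2].detail
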