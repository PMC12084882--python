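import gemmi
import pytest

from riboaudit.audit import audit_chain
from riboaudit.correction import (
    apply_correction,
    changelog_to_tsv,
    plan_correction,
)
from riboaudit.registry import ReferenceRecord
from riboaudit.structure import extract_rna_chains, write_mmcif
from riboaudit.synthetic import make_mmcif_fixture, mutate


def test_offset_only_chain_needs_no_relabels(ref_300):
    chain, _ = mutate(ref_300, numbering_offset=1, seed=1)
    plan = plan_correction(audit_chain(chain, ref_300), chain)
    assert plan.relabels == []
    assert plan.unresolved == []
    assert all(r.new_auth == r.old_auth - 1 for r in plan.renumber)
    assert len(plan.renumber) == len(chain.residues)  # bijection on residues


def test_planted_substitution_becomes_relabel_to_template_base(ref_300):
    chain, truth = mutate(ref_300, n_subs=1, seed=2)
    pos, old_base, new_base = truth.substitutions[0]
    plan = plan_correction(audit_chain(chain, ref_300), chain)
    assert len(plan.relabels) == 1
    rl = plan.relabels[0]
    # the model's planted base is replaced by the template base
    assert (rl.template_pos, rl.old_base, rl.new_base) == (pos, new_base, old_base)
    assert rl.new_component == old_base


def test_insertion_residues_are_unresolved_not_relabelled(ref_300):
    chain, truth = mutate(ref_300, n_ins=1, seed=3)
    plan = plan_correction(audit_chain(chain, ref_300), chain)
    assert plan.relabels == []
    assert len(plan.unresolved) == 1
    anchor, inserted = truth.insertions[0]
    icoded = [r for r in plan.renumber if r.new_icode]
    assert len(icoded) == len(inserted)
    assert all(r.new_auth == anchor for r in icoded)


def test_plan_rejects_mismatched_chain(ref_300):
    chain, _ = mutate(ref_300, n_subs=1, seed=4)
    other, _ = mutate(ref_300, n_subs=1, seed=4, chain_id="Z")
    with pytest.raises(ValueError, match="audit is for"):
        plan_correction(audit_chain(chain, ref_300), other)


def test_empty_plan_is_a_no_op(ref_300, tmp_path):
    chain, _ = mutate(ref_300, seed=5)
    src = make_mmcif_fixture(chain, tmp_path / "in.cif")
    plan = plan_correction(audit_chain(chain, ref_300), chain)
    assert plan.is_empty
    _, log = apply_correction(src, plan, tmp_path / "out.cif")
    assert log == []
    back = extract_rna_chains(tmp_path / "out.cif")[0]
    assert back.sequence == chain.sequence
    assert [r.auth_number for r in back.residues] == [r.auth_number for r in chain.residues]


def test_correction_closure_and_conservation(ref_300, tmp_path):
    chain, _ = mutate(ref_300, n_subs=5, numbering_offset=1, seed=6)
    src = make_mmcif_fixture(chain, tmp_path / "in.cif")
    extracted = extract_rna_chains(src)[0]
    plan = plan_correction(audit_chain(extracted, ref_300), extracted)
    st, log = apply_correction(src, plan, tmp_path / "out.cif")

    corrected = extract_rna_chains(tmp_path / "out.cif")[0]
    assert len(corrected) == len(chain)  # no residues created or deleted
    report = audit_chain(corrected, ref_300)
    assert report.n_substitutions == 0
    assert all(r.auth_number == i for i, r in enumerate(corrected.residues, start=1))
    # change log covers the 5 relabels plus every renumbered residue
    n_renumbered = sum(1 for r in plan.renumber if r.changed)
    assert len(log) == len(plan.relabels) + n_renumbered

    # idempotence: re-planning on the corrected chain is empty
    replan = plan_correction(audit_chain(corrected, ref_300), corrected)
    assert replan.is_empty


def test_relabel_drops_base_specific_atoms(tmp_path):
    # template ACU vs model AGU: G at position 2 must become C, and the
    # purine-specific atoms must be dropped while shared ones survive
    ref = ReferenceRecord("tiny", "5S", "synthetic", sequence="ACUGAUCCGA")
    st = gemmi.Structure()
    st.name = "TINY"
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    model_seq = "AGUGAUCCGA"
    for i, base in enumerate(model_seq, start=1):
        res = gemmi.Residue()
        res.name = base
        res.seqid = gemmi.SeqId(i, " ")
        res.label_seq = i
        atoms = ["P", "C1'", "N1"] if i != 2 else ["P", "C1'", "N1", "N9", "O6", "N7"]
        for name in atoms:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(float(i), float(len(name)), 0.0)
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    src = tmp_path / "tiny.cif"
    write_mmcif(st, src)

    chain = extract_rna_chains(src)[0]
    plan = plan_correction(audit_chain(chain, ref), chain)
    assert [rl.new_component for rl in plan.relabels] == ["C"]
    st2, log = apply_correction(src, plan, tmp_path / "tiny_out.cif")
    relabel = [e for e in log if e.action == "relabel"][0]
    assert "N9" in relabel.detail and "O6" in relabel.detail and "N7" in relabel.detail
    res2 = st2[0]["A"][1]
    assert res2.name == "C"
    assert sorted(a.name for a in res2) == ["C1'", "N1", "P"]
    tsv = changelog_to_tsv(log)
    assert "relabel" in tsv


def test_plan_referencing_missing_residue_errors(ref_300, tmp_path):
    chain, _ = mutate(ref_300, n_subs=2, seed=7)
    src = make_mmcif_fixture(chain, tmp_path / "in.cif")
    plan = plan_correction(audit_chain(chain, ref_300), chain)
    plan.relabels[0].old_auth = 9999
    with pytest.raises(KeyError, match="9999"):
        apply_correction(src, plan)


def test_missing_chain_errors(ref_300, tmp_path):
    chain, _ = mutate(ref_300, seed=8)
    src = make_mmcif_fixture(chain, tmp_path / "in.cif")
    plan = plan_correction(audit_chain(chain, ref_300), chain)
    plan.chain_id = "Q"
    with pytest.raises(KeyError, match="chain 'Q'"):
        apply_correction(src, plan)
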