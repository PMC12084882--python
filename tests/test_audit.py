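import pytest

from riboaudit.audit import (
    audit_chain,
    audit_region,
    events_to_tsv,
    report_to_json,
    summarize_entries,
)
from riboaudit.registry import ReferenceRecord
from riboaudit.structure import ChainSequence, ResidueRecord
from riboaudit.synthetic import mutate


def chain_from(sequence, model_id="M", chain_id="A", components=None):
    comps = components or list(sequence)
    return ChainSequence(
        model_id, chain_id,
        [ResidueRecord(i, c) for i, c in enumerate(comps, start=1)],
    )


def test_identical_chain_audits_clean(ref_300):
    report = audit_chain(chain_from(ref_300.sequence), ref_300)
    assert report.events == []
    assert report.n_substitutions == 0
    assert report.identity.identity_gap_included == 100.0


def test_planted_substitutions_and_deletion_are_recovered(ref_300):
    seq = list(ref_300.sequence)
    planted = {}
    for pos in (10, 50, 100):
        old = seq[pos - 1]
        new = {"A": "C", "C": "A", "G": "U", "U": "G"}[old]
        seq[pos - 1] = new
        planted[pos] = (old, new)
    del seq[199:202]  # deletion of template positions 200-202
    report = audit_chain(chain_from("".join(seq)), ref_300)
    subs = {e.template_pos: (e.template_base, e.model_base) for e in report.substitutions}
    assert subs == planted
    assert report.n_substitutions == 3
    dels = [e for e in report.events if e.event_type == "deletion"]
    assert len(dels) == 1 and report.n_deletion_runs == 1
    assert dels[0].template_pos == 200 and dels[0].length == 3


def test_substitution_count_recovered_for_any_seed(ref_300):
    for seed in range(8):
        n = 1 + seed % 5
        chain, truth = mutate(ref_300, n_subs=n, seed=seed)
        report = audit_chain(chain, ref_300)
        assert report.n_substitutions == n
        assert [(e.template_pos, e.template_base, e.model_base) for e in report.substitutions] == truth.substitutions


def test_substitution_count_is_swap_invariant(ref_300):
    chain, truth = mutate(ref_300, n_subs=4, n_ins=1, n_del=1, seed=21)
    fwd = audit_chain(chain, ref_300)
    # swap the roles: audit the reference "as a chain" against the mutant
    mutant_ref = ReferenceRecord("mutant", ref_300.molecule_class, "synthetic", sequence=chain.sequence)
    rev = audit_chain(chain_from(ref_300.sequence), mutant_ref)
    assert fwd.n_substitutions == rev.n_substitutions == 4
    # insertions and deletions exchange roles under the swap
    assert fwd.n_insertion_runs == rev.n_deletion_runs
    assert fwd.n_deletion_runs == rev.n_insertion_runs


def test_modified_unknown_components_are_not_substitutions(ref_300):
    comps = list(ref_300.sequence)
    comps[41] = "ZZZ"  # unknown chemistry at template position 42
    report = audit_chain(chain_from(ref_300.sequence, components=comps), ref_300)
    assert report.n_substitutions == 0
    assert report.n_modified_unknown == 1
    assert report.identity.n_mismatch == 1  # N still counts against identity


def test_region_restriction_filters_events(ref_300):
    seq = list(ref_300.sequence)
    for pos in (10, 50, 100):
        seq[pos - 1] = {"A": "C", "C": "A", "G": "U", "U": "G"}[seq[pos - 1]]
    chain = chain_from("".join(seq))
    full = audit_chain(chain, ref_300)
    vacuous = audit_region(chain, ref_300, [(1, 300)])
    assert vacuous.n_substitutions == full.n_substitutions
    assert vacuous.identity.n_match == full.identity.n_match

    restricted = audit_region(chain, ref_300, [(40, 60)])
    assert [e.template_pos for e in restricted.substitutions] == [50]
    assert restricted.identity.n_columns == 21


def test_region_restriction_never_increases_tallies(ref_300):
    chain, _ = mutate(ref_300, n_subs=5, n_ins=1, n_del=1, seed=4)
    full = audit_chain(chain, ref_300)
    sub = audit_region(chain, ref_300, [(30, 120), (200, 280)])
    assert sub.n_substitutions <= full.n_substitutions
    assert sub.n_insertion_runs <= full.n_insertion_runs
    assert sub.n_deletion_runs <= full.n_deletion_runs


@pytest.mark.parametrize(
    "regions, message",
    [
        ([(965, 725)], "start exceeds end"),
        ([(0, 10)], "start must be >= 1"),
        ([(1, 400)], "exceeds reference length"),
        ([(10, 50), (40, 80)], "overlap"),
    ],
)
def test_malformed_regions_are_rejected(ref_300, regions, message):
    with pytest.raises(ValueError, match=message):
        audit_region(chain_from(ref_300.sequence), ref_300, regions)


def test_empty_chain_is_an_error(ref_300):
    with pytest.raises(ValueError, match="empty chain"):
        audit_chain(ChainSequence("M", "A", []), ref_300)


def test_summary_reports_substitution_range(ref_300):
    reports = []
    for i, n in enumerate((1, 2, 3)):
        chain, _ = mutate(ref_300, n_subs=n, seed=30 + i, model_id=f"M{i}")
        reports.append(audit_chain(chain, ref_300))
    summary = summarize_entries(reports)
    assert list(summary.table["n_substitutions"]) == [1, 2, 3]
    assert summary.min_substitutions == 1 and summary.max_substitutions == 3
    one = summarize_entries(reports[:1])
    assert one.min_substitutions == one.max_substitutions == 1
    with pytest.raises(ValueError):
        summarize_entries([])


def test_report_serializations(ref_300):
    chain, _ = mutate(ref_300, n_subs=2, n_del=1, seed=5)
    report = audit_chain(chain, ref_300)
    tsv = events_to_tsv(report)
    assert len(tsv.strip().splitlines()) == len(report.events) + 1
    js = report_to_json(report)
    assert '"n_substitutions": 2' in js
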