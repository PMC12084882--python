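"""Discrepancy auditing of model chains against reference templates.

The audit aligns a model-derived rRNA chain globally to its reference
template and classifies every non-match column:

* **substitution** — both bases present and definite, but different.  These
  are the headline "single-nucleotide changes"; indels are excluded from
  that count.
* **insertion** — a run of model residues absent from the template,
  anchored at the preceding template coordinate (0 at the start).
* **deletion** — a run of template positions absent from the model.

Contiguous gap columns merge into one insertion/deletion run, counted as a
run rather than per-base, because indels are features of a model, not
independent per-base events.  Residues whose chemical component could not
be mapped to a definite parent base (N) are tallied separately
(``n_modified_unknown``) and never counted as substitutions: unknown
chemistry is not evidence of a sequence change.

All template coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .alignment import (
    GAP,
    AlignmentParams,
    IdentityReport,
    PairwiseAlignment,
    global_align,
)
from .registry import ReferenceRecord
from .structure import ChainSequence

#: Per-model-residue alignment fate: ("aligned", template_pos) or
#: ("insertion", anchor_pos).
ResidueFate = tuple[str, int]


@dataclass
class DiscrepancyEvent:
    event_type: str  # substitution | insertion | deletion
    template_pos: Optional[int] = None  # absent for insertion
    anchor_pos: Optional[int] = None  # insertion only: preceding template pos
    model_pos: Optional[int] = None  # absent for deletion
    template_base: str = ""
    model_base: str = ""
    length: int = 1

    def __post_init__(self) -> None:
        if self.event_type == "substitution":
            assert self.template_pos is not None and self.model_pos is not None
            assert self.template_base != self.model_base
        elif self.event_type == "insertion":
            assert self.anchor_pos is not None and self.model_pos is not None
        elif self.event_type == "deletion":
            assert self.template_pos is not None and self.model_pos is None
        else:
            raise ValueError(f"unknown event type {self.event_type!r}")

    @property
    def position_in_template(self) -> int:
        """The template coordinate (or insertion anchor) of the event."""
        return self.template_pos if self.template_pos is not None else self.anchor_pos


@dataclass
class AuditReport:
    model_id: str
    chain_id: str
    reference_id: str
    events: list[DiscrepancyEvent]
    n_substitutions: int
    n_insertion_runs: int
    n_deletion_runs: int
    n_modified_unknown: int
    identity: IdentityReport
    regions: Optional[list[tuple[int, int]]] = None
    alignment: Optional[PairwiseAlignment] = field(default=None, repr=False)
    #: fate of each model residue, index-parallel to the chain
    residue_fates: list[ResidueFate] = field(default_factory=list, repr=False)

    @property
    def substitutions(self) -> list[DiscrepancyEvent]:
        return [e for e in self.events if e.event_type == "substitution"]


def _scan_columns(aln: PairwiseAlignment) -> tuple[list[DiscrepancyEvent], int, list[ResidueFate]]:
    """Walk alignment columns; return events, N tally, per-residue fates."""
    events: list[DiscrepancyEvent] = []
    fates: list[ResidueFate] = []
    n_unknown = 0
    t_pos = 0  # template positions consumed
    m_pos = 0  # model residues consumed
    run_type: Optional[str] = None
    run_start_t = run_start_m = run_anchor = 0
    run_bases: list[str] = []

    def flush_run() -> None:
        nonlocal run_type, run_bases
        if run_type == "deletion":
            events.append(
                DiscrepancyEvent(
                    event_type="deletion",
                    template_pos=run_start_t,
                    template_base="".join(run_bases),
                    length=len(run_bases),
                )
            )
        elif run_type == "insertion":
            events.append(
                DiscrepancyEvent(
                    event_type="insertion",
                    anchor_pos=run_anchor,
                    model_pos=run_start_m,
                    model_base="".join(run_bases),
                    length=len(run_bases),
                )
            )
        run_type = None
        run_bases = []

    for t_char, m_char in aln.columns:
        if t_char != GAP and m_char != GAP:
            t_pos += 1
            m_pos += 1
            if run_type:
                flush_run()
            fates.append(("aligned", t_pos))
            if t_char == "N" or m_char == "N":
                n_unknown += 1
            elif t_char != m_char:
                events.append(
                    DiscrepancyEvent(
                        event_type="substitution",
                        template_pos=t_pos,
                        model_pos=m_pos,
                        template_base=t_char,
                        model_base=m_char,
                    )
                )
        elif m_char == GAP:  # template base missing from model
            t_pos += 1
            if run_type != "deletion":
                if run_type:
                    flush_run()
                run_type = "deletion"
                run_start_t = t_pos
            run_bases.append(t_char)
        else:  # model residue absent from template
            m_pos += 1
            if run_type != "insertion":
                if run_type:
                    flush_run()
                run_type = "insertion"
                run_start_m = m_pos
                run_anchor = t_pos
            run_bases.append(m_char)
            fates.append(("insertion", t_pos))
    if run_type:
        flush_run()
    return events, n_unknown, fates


def _tally(events: list[DiscrepancyEvent]) -> tuple[int, int, int]:
    n_sub = sum(1 for e in events if e.event_type == "substitution")
    n_ins = sum(1 for e in events if e.event_type == "insertion")
    n_del = sum(1 for e in events if e.event_type == "deletion")
    return n_sub, n_ins, n_del


def audit_chain(
    chain: ChainSequence,
    reference: ReferenceRecord,
    params: Optional[AlignmentParams] = None,
) -> AuditReport:
    """Audit one chain against one reference template.

    The template is the alignment's first sequence, so event coordinates
    are template 1-based positions.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    if not reference.loaded:
        raise ValueError(f"reference {reference.record_id} has no sequence loaded")
    aln = global_align(
        reference.sequence,
        chain.sequence,
        params,
        a_id=reference.record_id,
        b_id=f"{chain.model_id}/{chain.chain_id}",
    )
    events, n_unknown, fates = _scan_columns(aln)
    n_sub, n_ins, n_del = _tally(events)

    from .alignment import identity as _identity

    return AuditReport(
        model_id=chain.model_id,
        chain_id=chain.chain_id,
        reference_id=reference.record_id,
        events=events,
        n_substitutions=n_sub,
        n_insertion_runs=n_ins,
        n_deletion_runs=n_del,
        n_modified_unknown=n_unknown,
        identity=_identity(aln),
        alignment=aln,
        residue_fates=fates,
    )


def _validate_regions(regions: list[tuple[int, int]], ref_length: int) -> list[tuple[int, int]]:
    norm: list[tuple[int, int]] = []
    for start, end in regions:
        if start < 1:
            raise ValueError(f"region start must be >= 1, got {start}")
        if start > end:
            raise ValueError(f"start exceeds end in region ({start}, {end})")
        if end > ref_length:
            raise ValueError(f"region end {end} exceeds reference length {ref_length}")
        norm.append((int(start), int(end)))
    norm.sort()
    for (s1, e1), (s2, _) in zip(norm, norm[1:]):
        if s2 <= e1:
            raise ValueError(f"regions overlap: ({s1}, {e1}) and starting {s2}")
    return norm


def _in_regions(pos: int, regions: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in regions)


def audit_region(
    chain: ChainSequence,
    reference: ReferenceRecord,
    regions: list[tuple[int, int]],
    params: Optional[AlignmentParams] = None,
) -> AuditReport:
    """Audit restricted to 1-based inclusive template intervals.

    Used for models whose sequence was only verified in high-confidence
    regions: events outside the union of intervals are dropped, and
    identity is recomputed over in-region columns only (insertion columns
    count with their anchor).
    """
    full = audit_chain(chain, reference, params)
    regions = _validate_regions(regions, len(reference.sequence))
    events = [e for e in full.events if _in_regions(e.position_in_template, regions)]
    n_sub, n_ins, n_del = _tally(events)

    n_match = n_mismatch = n_gap = n_unknown = 0
    t_pos = 0
    for t_char, m_char in full.alignment.columns:
        if t_char != GAP:
            t_pos += 1
        pos = t_pos  # letter and deletion columns sit at t_pos; insertions anchor there
        if not _in_regions(pos, regions):
            continue
        if t_char == GAP or m_char == GAP:
            n_gap += 1
        elif t_char == "N" or m_char == "N":
            n_mismatch += 1
            n_unknown += 1
        elif t_char == m_char:
            n_match += 1
        else:
            n_mismatch += 1

    return AuditReport(
        model_id=full.model_id,
        chain_id=full.chain_id,
        reference_id=full.reference_id,
        events=events,
        n_substitutions=n_sub,
        n_insertion_runs=n_ins,
        n_deletion_runs=n_del,
        n_modified_unknown=n_unknown,
        identity=IdentityReport(n_match=n_match, n_mismatch=n_mismatch, n_gap_columns=n_gap),
        regions=regions,
        alignment=full.alignment,
        residue_fates=full.residue_fates,
    )


@dataclass
class AuditSummary:
    table: pd.DataFrame
    min_substitutions: int
    max_substitutions: int


def summarize_entries(reports: list[AuditReport]) -> AuditSummary:
    """One row per audited (model, chain) plus the substitution-count range."""
    if not reports:
        raise ValueError("no reports to summarize")
    rows = []
    for r in reports:
        rows.append(
            {
                "model_id": r.model_id,
                "chain_id": r.chain_id,
                "reference_id": r.reference_id,
                "n_substitutions": r.n_substitutions,
                "n_insertion_runs": r.n_insertion_runs,
                "n_deletion_runs": r.n_deletion_runs,
                "n_modified_unknown": r.n_modified_unknown,
                "identity_gap_excluded": round(r.identity.identity_gap_excluded, 2),
                "identity_gap_included": round(r.identity.identity_gap_included, 2),
            }
        )
    table = pd.DataFrame(rows)
    return AuditSummary(
        table=table,
        min_substitutions=int(table["n_substitutions"].min()),
        max_substitutions=int(table["n_substitutions"].max()),
    )


def events_to_tsv(report: AuditReport) -> str:
    """Flat TSV of every discrepancy event."""
    header = (
        "model_id\tchain_id\treference_id\tevent_type\t"
        "template_pos\tanchor_pos\tmodel_pos\ttemplate_base\tmodel_base\tlength"
    )
    lines = [header]
    for e in report.events:
        lines.append(
            "\t".join(
                str(v) if v is not None else "."
                for v in (
                    report.model_id,
                    report.chain_id,
                    report.reference_id,
                    e.event_type,
                    e.template_pos,
                    e.anchor_pos,
                    e.model_pos,
                    e.template_base or ".",
                    e.model_base or ".",
                    e.length,
                )
            )
        )
    return "\n".join(lines) + "\n"


def report_to_json(report: AuditReport) -> str:
    """JSON rendering with events and tallies (alignment omitted)."""
    payload = {
        "model_id": report.model_id,
        "chain_id": report.chain_id,
        "reference_id": report.reference_id,
        "n_substitutions": report.n_substitutions,
        "n_insertion_runs": report.n_insertion_runs,
        "n_deletion_runs": report.n_deletion_runs,
        "n_modified_unknown": report.n_modified_unknown,
        "identity": {
            "n_match": report.identity.n_match,
            "n_mismatch": report.identity.n_mismatch,
            "n_gap_columns": report.identity.n_gap_columns,
            "gap_excluded_pct": round(report.identity.identity_gap_excluded, 4),
            "gap_included_pct": round(report.identity.identity_gap_included, 4),
        },
        "regions": report.regions,
        "events": [
            {
                "event_type": e.event_type,
                "template_pos": e.template_pos,
                "anchor_pos": e.anchor_pos,
                "model_pos": e.model_pos,
                "template_base": e.template_base,
                "model_base": e.model_base,
                "length": e.length,
            }
            for e in report.events
        ],
    }
    return json.dumps(payload, indent=2)
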