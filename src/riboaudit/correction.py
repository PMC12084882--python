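"""Conforming a model chain to its reference template.

A correction plan is pure bookkeeping derived from an audit: substituted
residues are relabelled to the template base, every aligned residue is
renumbered to its template coordinate (making the chain's author numbering
match the reference scheme), and indels are flagged unresolved.  No
coordinates are rebuilt and no residues are fabricated or deleted —
resolving an indel requires density, which is outside what a sequence
audit can verify.

Relabelling a residue across base identities keeps only atoms whose names
exist in the new base's standard atom set (backbone/ribose plus the new
base atoms); base-specific atoms of the old residue are dropped and
logged.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import gemmi

from .audit import AuditReport, DiscrepancyEvent
from .structure import ChainSequence, read_structure, standard_atom_set, write_mmcif


@dataclass
class RelabelEntry:
    template_pos: int
    old_auth: int
    old_icode: str
    old_component: str
    new_component: str
    old_base: str
    new_base: str


@dataclass
class RenumberEntry:
    old_auth: int
    old_icode: str
    new_auth: int
    new_icode: str

    @property
    def changed(self) -> bool:
        return (self.old_auth, self.old_icode) != (self.new_auth, self.new_icode)


@dataclass
class CorrectionPlan:
    model_id: str
    chain_id: str
    reference_id: str
    relabels: list[RelabelEntry]
    renumber: list[RenumberEntry]  # one entry per residue, in polymer order
    unresolved: list[DiscrepancyEvent]  # indel runs; recorded, never resolved
    provenance: str = ""

    @property
    def is_empty(self) -> bool:
        return not self.relabels and not any(r.changed for r in self.renumber)


_INSERTION_CODES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def plan_correction(audit: AuditReport, chain: ChainSequence) -> CorrectionPlan:
    """Derive the relabel/renumber operations from an audit of this chain.

    Aligned residues get the template position as their new author number;
    insertion-run residues keep their anchor's number with insertion codes
    A, B, ... and are flagged unresolved alongside deletions.
    """
    if (audit.model_id, audit.chain_id) != (chain.model_id, chain.chain_id):
        raise ValueError(
            f"audit is for {audit.model_id}/{audit.chain_id}, "
            f"chain is {chain.model_id}/{chain.chain_id}"
        )
    if len(audit.residue_fates) != len(chain.residues):
        raise ValueError("audit does not correspond to this chain (residue count mismatch)")

    relabels = []
    for e in audit.substitutions:
        res = chain.residues[e.model_pos - 1]
        relabels.append(
            RelabelEntry(
                template_pos=e.template_pos,
                old_auth=res.auth_number,
                old_icode=res.insertion_code,
                old_component=res.component_id,
                new_component=e.template_base,
                old_base=e.model_base,
                new_base=e.template_base,
            )
        )

    renumber = []
    prev_anchor: Optional[int] = None
    run_idx = 0
    for res, (kind, pos) in zip(chain.residues, audit.residue_fates):
        if kind == "aligned":
            renumber.append(RenumberEntry(res.auth_number, res.insertion_code, pos, ""))
            prev_anchor = None
        else:  # insertion residue: anchor number + insertion code A, B, ...
            run_idx = run_idx + 1 if prev_anchor == pos else 1
            prev_anchor = pos
            code = _INSERTION_CODES[(run_idx - 1) % len(_INSERTION_CODES)]
            renumber.append(RenumberEntry(res.auth_number, res.insertion_code, pos, code))

    unresolved = [e for e in audit.events if e.event_type in ("insertion", "deletion")]
    provenance = (
        f"rRNA sequence audit: chain {chain.chain_id} of {chain.model_id} corrected to "
        f"template {audit.reference_id}; {len(relabels)} base relabel(s), "
        f"{len(unresolved)} unresolved indel run(s); {_dt.date.today().isoformat()}"
    )
    return CorrectionPlan(
        model_id=chain.model_id,
        chain_id=chain.chain_id,
        reference_id=audit.reference_id,
        relabels=relabels,
        renumber=renumber,
        unresolved=unresolved,
        provenance=provenance,
    )


@dataclass
class ChangeLogEntry:
    chain_id: str
    old_number: int
    old_icode: str
    new_number: int
    new_icode: str
    old_component: str
    new_component: str
    action: str  # relabel | renumber
    detail: str = ""


def changelog_to_tsv(log: list[ChangeLogEntry]) -> str:
    header = "chain\told_number\tnew_number\told_component\tnew_component\taction\tdetail"
    lines = [header]
    for e in log:
        lines.append(
            "\t".join(
                [
                    e.chain_id,
                    f"{e.old_number}{e.old_icode}",
                    f"{e.new_number}{e.new_icode}",
                    e.old_component,
                    e.new_component,
                    e.action,
                    e.detail,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def apply_correction(
    structure: Union[str, Path, gemmi.Structure],
    plan: CorrectionPlan,
    out_path: Optional[Union[str, Path]] = None,
) -> tuple[gemmi.Structure, list[ChangeLogEntry]]:
    """Apply a correction plan to a structure, returning it with a change log.

    Only the plan's chain is touched; residue count is conserved.  When
    ``out_path`` is given the corrected model is written as mmCIF with the
    plan's provenance note embedded.
    """
    st = read_structure(structure) if not isinstance(structure, gemmi.Structure) else structure
    if len(st) == 0:
        raise ValueError("structure has no models")
    target = None
    for ch in st[0]:
        if ch.name == plan.chain_id:
            target = ch
            break
    if target is None:
        raise KeyError(f"chain {plan.chain_id!r} not found in structure")

    by_key: dict[tuple[int, str], gemmi.Residue] = {}
    for res in target:
        by_key[(res.seqid.num, (res.seqid.icode or "").strip())] = res

    def lookup(num: int, icode: str) -> gemmi.Residue:
        try:
            return by_key[(num, icode)]
        except KeyError:
            raise KeyError(
                f"residue {num}{icode} referenced by the plan is absent from chain {plan.chain_id}"
            ) from None

    log: list[ChangeLogEntry] = []
    n_before = len(target)

    for rl in plan.relabels:
        res = lookup(rl.old_auth, rl.old_icode)
        allowed = standard_atom_set(rl.new_base)
        dropped = [atom.name for atom in res if atom.name not in allowed]
        for name in dropped:
            for i in range(len(res) - 1, -1, -1):
                if res[i].name == name:
                    del res[i]
        res.name = rl.new_component
        detail = f"dropped atoms: {','.join(dropped)}" if dropped else ""
        log.append(
            ChangeLogEntry(
                chain_id=plan.chain_id,
                old_number=rl.old_auth,
                old_icode=rl.old_icode,
                new_number=rl.old_auth,
                new_icode=rl.old_icode,
                old_component=rl.old_component,
                new_component=rl.new_component,
                action="relabel",
                detail=detail,
            )
        )

    for rn in plan.renumber:
        if not rn.changed:
            lookup(rn.old_auth, rn.old_icode)  # existence check even when a no-op
            continue
        res = lookup(rn.old_auth, rn.old_icode)
        res.seqid = gemmi.SeqId(rn.new_auth, rn.new_icode or " ")
        log.append(
            ChangeLogEntry(
                chain_id=plan.chain_id,
                old_number=rn.old_auth,
                old_icode=rn.old_icode,
                new_number=rn.new_auth,
                new_icode=rn.new_icode,
                old_component=res.name,
                new_component=res.name,
                action="renumber",
            )
        )

    assert len(target) == n_before, "apply_correction must conserve residue count"

    if out_path is not None:
        write_mmcif(st, out_path, provenance=plan.provenance)
    return st, log
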