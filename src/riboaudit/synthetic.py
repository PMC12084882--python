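"""Synthetic references, mutated chains, and minimal mmCIF fixtures.

Every stage of the audit pipeline is testable offline by generating a
reference sequence, planting a known set of substitutions, insertions,
deletions and a numbering offset into a "model" chain, and writing that
chain as a minimal mmCIF file (one pseudo-atom per residue — atom-level
realism is irrelevant to sequence auditing, and a single phosphorus per
residue keeps fixtures tiny while exercising the real mmCIF reader).

The planted events are returned as a truth table against which audit
output can be compared exactly.  Events are placed away from the sequence
ends and from each other, and indel boundaries are constrained so the
optimal alignment recovers each event at its planted coordinates rather
than an equivalent shifted placement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import gemmi

from .registry import ReferenceRecord
from .structure import ChainSequence, ResidueRecord

_BASES = np.array(list("ACGU"))
_EDGE_MARGIN = 25
_EVENT_PADDING = 3
_INSERTION_CODES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class TruthTable:
    """The planted mutations of one synthetic model chain."""

    seed: int
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)  # (pos, old, new)
    insertions: list[tuple[int, str]] = field(default_factory=list)  # (anchor_pos, inserted)
    deletions: list[tuple[int, int]] = field(default_factory=list)  # (start, end) inclusive
    numbering_offset: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "substitutions": self.substitutions,
                "insertions": self.insertions,
                "deletions": self.deletions,
                "numbering_offset": self.numbering_offset,
            },
            indent=2,
        )


def make_reference(
    length: int,
    gc_fraction: float = 0.55,
    seed: int = 0,
    record_id: Optional[str] = None,
    molecule_class: str = "18S",
    species: str = "synthetic",
) -> ReferenceRecord:
    """A reproducible random reference sequence with a target GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    seq = "".join(rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at]))
    return ReferenceRecord(
        record_id=record_id or f"synth_{molecule_class}_{length}nt_seed{seed}",
        molecule_class=molecule_class,
        species=species,
        sequence=seq,
    )


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGU" if b != base]
    return choices[rng.integers(0, len(choices))]


def mutate(
    reference: ReferenceRecord,
    n_subs: int = 0,
    n_ins: int = 0,
    n_del: int = 0,
    max_indel_len: int = 4,
    numbering_offset: int = 0,
    seed: int = 0,
    model_id: str = "SYNTH",
    chain_id: str = "A",
) -> tuple[ChainSequence, TruthTable]:
    """Plant mutations into a reference, yielding a model chain plus truth.

    Author numbers are template positions plus ``numbering_offset``;
    insertion residues carry the anchor's number with insertion codes.
    Raises if the requested events cannot be placed without overlap after
    bounded retries.
    """
    if not reference.loaded:
        raise ValueError("reference has no sequence loaded")
    ref = reference.sequence
    L = len(ref)
    rng = np.random.default_rng(seed)
    occupied: set[int] = set()

    def claim(lo: int, hi: int) -> bool:
        span = set(range(lo - _EVENT_PADDING, hi + _EVENT_PADDING + 1))
        if span & occupied:
            return False
        occupied.update(span)
        return True

    def place(n_events: int, width_fn, check_fn) -> list:
        placed = []
        for _ in range(n_events):
            for _attempt in range(500):
                width = width_fn()
                lo = int(rng.integers(_EDGE_MARGIN + 1, L - _EDGE_MARGIN - width))
                event = check_fn(lo, width)
                if event is not None and claim(lo, lo + width - 1):
                    placed.append(event)
                    break
            else:
                raise ValueError(
                    f"cannot place {n_events} events in a {L}-nt reference without overlap"
                )
        return placed

    # deletions: run [s, e]; forbid shift-equivalent placements
    def check_del(s: int, width: int):
        e = s + width - 1
        if ref[s - 2] == ref[e - 1] or ref[s - 1] == ref[e]:
            return None  # deleting here is ambiguous with a shifted run
        return (s, e)

    deletions = place(n_del, lambda: int(rng.integers(1, max_indel_len + 1)), check_del)

    # insertions: anchored after template position a
    def check_ins(a: int, width: int):
        ins = "".join(rng.choice(_BASES, size=width))
        # first inserted base must differ from the next template base and
        # the last from the anchor base, else the optimal alignment can
        # slide the gap
        if ins[0] == ref[a] or ins[-1] == ref[a - 1]:
            return None
        return (a, ins)

    insertions = place(n_ins, lambda: int(rng.integers(1, max_indel_len + 1)), check_ins)

    def check_sub(p: int, _width: int):
        return (p, ref[p - 1], _other_base(rng, ref[p - 1]))

    substitutions = place(n_subs, lambda: 1, check_sub)

    substitutions.sort()
    insertions.sort()
    deletions.sort()
    truth = TruthTable(
        seed=seed,
        substitutions=substitutions,
        insertions=insertions,
        deletions=deletions,
        numbering_offset=numbering_offset,
    )

    sub_at = {p: new for p, _, new in substitutions}
    ins_at = dict(insertions)
    deleted = set()
    for s, e in deletions:
        deleted.update(range(s, e + 1))

    residues: list[ResidueRecord] = []
    for p in range(1, L + 1):
        if p not in deleted:
            base = sub_at.get(p, ref[p - 1])
            residues.append(
                ResidueRecord(auth_number=p + numbering_offset, component_id=base)
            )
        if p in ins_at:
            for k, base in enumerate(ins_at[p]):
                residues.append(
                    ResidueRecord(
                        auth_number=p + numbering_offset,
                        component_id=base,
                        insertion_code=_INSERTION_CODES[k % len(_INSERTION_CODES)],
                    )
                )
    chain = ChainSequence(model_id=model_id, chain_id=chain_id, residues=residues)
    return chain, truth


def make_mmcif_fixture(chain: ChainSequence, path: str | Path) -> Path:
    """Write a chain as a minimal mmCIF file (one phosphorus per residue).

    The fixture parses back through :func:`riboaudit.structure.extract_rna_chains`
    to a chain with identical sequence, numbering and component ids, and is
    byte-identical for identical inputs.
    """
    st = gemmi.Structure()
    st.name = chain.model_id
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain.chain_id)
    for i, rr in enumerate(chain.residues, start=1):
        res = gemmi.Residue()
        res.name = rr.component_id
        res.seqid = gemmi.SeqId(rr.auth_number, rr.insertion_code or " ")
        res.label_seq = i
        atom = gemmi.Atom()
        atom.name = "P"
        atom.element = gemmi.Element("P")
        atom.pos = gemmi.Position(float(i) * 6.0, 0.0, 0.0)
        atom.occ = 1.0
        atom.b_iso = 20.0
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    path = Path(path)
    doc.write_file(str(path))
    return path
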