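"""Coordinate liftover between rRNA numbering schemes.

The same functional nucleotide carries a different number in each
reference scheme (human vs rabbit vs yeast 18S, or successive versions of
one species' reference).  A global alignment between two schemes induces a
monotone position map; lifting a site through that map translates its
coordinate.  Positions falling in alignment gaps are *unmapped* and are
reported as an explicit marker, never as 0 or -1.

The same machinery detects register offsets: a chain whose author
numbering is systematically shifted against template coordinates (the
"+1" numbering pathology seen in some deposited models).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

from .alignment import GAP, AlignmentParams, global_align
from .registry import ReferenceRecord, SiteAnnotation
from .structure import ChainSequence

UNMAPPED = "unmapped"


@dataclass
class PositionMap:
    """Monotone injection from scheme ``a`` coordinates into scheme ``b``.

    ``a_to_b[p]`` is the 1-based position of ``b`` aligned to position
    ``p`` of ``a``; positions in gap columns are absent from the dict.
    """

    a_id: str
    b_id: str
    a_to_b: dict[int, int]
    length_a: int
    length_b: int

    def lift(self, position: int) -> Optional[int]:
        if not 1 <= position <= self.length_a:
            raise ValueError(
                f"position {position} outside 1..{self.length_a} of {self.a_id}"
            )
        return self.a_to_b.get(position)

    def invert(self) -> "PositionMap":
        return PositionMap(
            a_id=self.b_id,
            b_id=self.a_id,
            a_to_b={v: k for k, v in self.a_to_b.items()},
            length_a=self.length_b,
            length_b=self.length_a,
        )

    def validate(self) -> None:
        items = sorted(self.a_to_b.items())
        for (a1, b1), (a2, b2) in zip(items, items[1:]):
            if not (a1 < a2 and b1 < b2):
                raise ValueError("position map is not strictly increasing")


def build_position_map(
    a: ReferenceRecord,
    b: ReferenceRecord,
    params: Optional[AlignmentParams] = None,
) -> PositionMap:
    """Position map induced by the global alignment of two references."""
    if not (a.loaded and b.loaded):
        raise ValueError("both references must have sequences loaded")
    aln = global_align(a.sequence, b.sequence, params, a_id=a.record_id, b_id=b.record_id)
    mapping: dict[int, int] = {}
    pa = pb = 0
    for ca, cb in aln.columns:
        if ca != GAP:
            pa += 1
        if cb != GAP:
            pb += 1
        if ca != GAP and cb != GAP:
            mapping[pa] = pb
    return PositionMap(a_id=a.record_id, b_id=b.record_id, a_to_b=mapping, length_a=len(a.sequence), length_b=len(b.sequence))


@dataclass
class LiftedSite:
    site_name: str
    from_scheme: str
    to_scheme: str
    position: Union[int, str]  # lifted 1-based position or UNMAPPED
    base_matches: Optional[bool] = None  # vs expected_base, when checkable


def lift_site(
    pmap: PositionMap,
    site: SiteAnnotation,
    target_record: Optional[ReferenceRecord] = None,
) -> LiftedSite:
    """Lift one site through a position map.

    When the site carries an expected base and the target record's
    sequence is available, the base at the lifted position is checked.
    """
    if site.scheme_id != pmap.a_id:
        raise ValueError(
            f"site scheme {site.scheme_id!r} does not match map source {pmap.a_id!r}"
        )
    lifted = pmap.lift(site.position)  # raises if out of range
    if lifted is None:
        return LiftedSite(site.site_name, pmap.a_id, pmap.b_id, UNMAPPED)
    base_ok = None
    if site.expected_base and target_record is not None and target_record.loaded:
        base_ok = target_record.sequence[lifted - 1] == site.expected_base
    return LiftedSite(site.site_name, pmap.a_id, pmap.b_id, lifted, base_ok)


def site_table(
    schemes: list[ReferenceRecord],
    sites: list[SiteAnnotation],
    params: Optional[AlignmentParams] = None,
) -> pd.DataFrame:
    """Matrix of lifted positions: one row per site, one column per scheme.

    Each site's own scheme must be among ``schemes``; its own column holds
    the annotated position, other columns the lifted positions (or the
    unmapped marker).
    """
    by_id = {s.record_id: s for s in schemes}
    maps: dict[tuple[str, str], PositionMap] = {}

    def get_map(src: str, dst: str) -> PositionMap:
        key = (src, dst)
        if key not in maps:
            maps[key] = build_position_map(by_id[src], by_id[dst], params)
        return maps[key]

    rows = []
    for site in sites:
        if site.scheme_id not in by_id:
            raise ValueError(f"site {site.site_name!r} scheme {site.scheme_id!r} not among schemes")
        row: dict[str, Union[int, str]] = {"site": site.site_name}
        for scheme in schemes:
            if scheme.record_id == site.scheme_id:
                row[scheme.record_id] = site.position
            else:
                lifted = lift_site(get_map(site.scheme_id, scheme.record_id), site, scheme)
                row[scheme.record_id] = lifted.position
        rows.append(row)
    return pd.DataFrame(rows).set_index("site")


def detect_register_offset(
    chain: ChainSequence,
    reference: ReferenceRecord,
    params: Optional[AlignmentParams] = None,
    threshold: float = 0.95,
) -> Optional[int]:
    """Constant shift between author numbering and template coordinates.

    Returns ``k`` when ``auth_number == template_pos + k`` for at least
    ``threshold`` of aligned residue pairs (tolerating local indels), else
    ``None``.  Residues with insertion codes are excluded from the vote.
    """
    if not reference.loaded:
        raise ValueError("reference has no sequence loaded")
    aln = global_align(reference.sequence, chain.sequence, params)
    offsets: Counter[int] = Counter()
    n_pairs = 0
    t_pos = m_idx = 0
    for t_char, m_char in aln.columns:
        if t_char != GAP:
            t_pos += 1
        if m_char != GAP:
            m_idx += 1
        if t_char != GAP and m_char != GAP:
            res = chain.residues[m_idx - 1]
            if res.insertion_code:
                continue
            n_pairs += 1
            offsets[res.auth_number - t_pos] += 1
    if n_pairs == 0:
        return None
    offset, count = offsets.most_common(1)[0]
    if count / n_pairs >= threshold:
        return offset
    return None


@dataclass
class SiteCheck:
    site_name: str
    position: int
    passed: bool
    detail: str


def validate_known_sites(record: ReferenceRecord, sites: list[SiteAnnotation]) -> list[SiteCheck]:
    """Check expected bases at annotated positions of one record.

    Out-of-range positions become failure entries, not exceptions (a
    too-short reference failing a site check is a finding, not a bug).
    """
    if not record.loaded:
        raise ValueError("record has no sequence loaded")
    checks = []
    for site in sites:
        if site.scheme_id != record.record_id:
            raise ValueError(f"site {site.site_name!r} is not in scheme {record.record_id!r}")
        if site.position > len(record.sequence):
            checks.append(
                SiteCheck(site.site_name, site.position, False,
                          f"position {site.position} out of range (length {len(record.sequence)})")
            )
            continue
        actual = record.sequence[site.position - 1]
        if site.expected_base is None:
            checks.append(SiteCheck(site.site_name, site.position, True, f"base {actual} (no expectation)"))
        else:
            ok = actual == site.expected_base
            checks.append(
                SiteCheck(site.site_name, site.position, ok,
                          f"expected {site.expected_base}, found {actual}")
            )
    return checks
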