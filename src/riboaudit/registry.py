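"""Reference rRNA sequence registry.

Holds the curated reference (template) sequences that model-derived rRNA
chains are audited against: the OryCun2.0 rabbit templates plus the human,
yeast and boar comparison schemes.  Sequences are normalized to the RNA
alphabet ``{A, C, G, U, N}`` on load; templates sourced from genomic (DNA)
records are therefore interchangeable with RNA-database records.

The built-in manifest ships accession metadata only; sequences are attached
from FASTA files (or the optional :mod:`riboaudit.fetch` utility) so the core
package works fully offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MOLECULE_CLASSES = ("18S", "28S", "5.8S", "5S")

RNA_ALPHABET = frozenset("ACGUN")


def normalize_sequence(raw: str) -> str:
    """Normalize a raw sequence string to the RNA alphabet.

    Whitespace is removed, letters are upper-cased and T is mapped to U so
    genomic (DNA) and RNA-database sources can be mixed.  Any character
    outside ``{A, C, G, U, N}`` after this mapping is rejected: the audit
    semantics assume definite bases, so IUPAC ambiguity codes other than N
    are an error rather than silently remapped.

    Raises
    ------
    ValueError
        If the sequence is empty after whitespace removal, or contains an
        illegal character (the message names the character and its 1-based
        offset in the cleaned sequence).
    """
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    if not cleaned:
        raise ValueError("empty sequence")
    for i, ch in enumerate(cleaned):
        if ch not in RNA_ALPHABET:
            raise ValueError(
                f"illegal character {ch!r} at offset {i + 1} "
                "(expected one of A, C, G, U, N)"
            )
    return cleaned


@dataclass
class ReferenceRecord:
    """A named reference rRNA sequence.

    ``sequence`` is ``None`` for manifest stubs that have not had a sequence
    attached yet; :func:`builtin_manifest` returns such stubs.
    """

    record_id: str
    molecule_class: str
    species: str
    accessions: list[str] = field(default_factory=list)
    sequence: Optional[str] = None
    expected_length: Optional[int] = None
    is_template: bool = False

    def __post_init__(self) -> None:
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValueError(
                f"unknown molecule class {self.molecule_class!r}; "
                f"expected one of {MOLECULE_CLASSES}"
            )
        if self.sequence is not None:
            self.sequence = normalize_sequence(self.sequence)

    @property
    def length(self) -> Optional[int]:
        return None if self.sequence is None else len(self.sequence)

    @property
    def loaded(self) -> bool:
        return self.sequence is not None

    def with_sequence(self, sequence: str) -> "ReferenceRecord":
        return replace(self, sequence=sequence)


@dataclass
class SiteAnnotation:
    """A functional-site annotation in one numbering scheme.

    ``scheme_id`` names the :class:`ReferenceRecord` whose 1-based
    coordinates ``position`` refers to.  ``expected_base`` is optional;
    ``scheme_verified`` is False for sites quoted in the literature without
    an explicit numbering scheme.
    """

    site_name: str
    scheme_id: str
    position: int
    note: str = ""
    expected_base: Optional[str] = None
    scheme_verified: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        if self.expected_base is not None:
            base = self.expected_base.upper().replace("T", "U")
            if base not in ("A", "C", "G", "U"):
                raise ValueError(f"expected_base must be a single RNA letter, got {self.expected_base!r}")
            self.expected_base = base


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    record_id: str
    checks: list[ValidationCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)


def _manifest_json() -> list[dict]:
    text = resources.files("riboaudit.data").joinpath("manifest.json").read_text()
    return json.loads(text)


def builtin_manifest() -> list[ReferenceRecord]:
    """The curated accession manifest, as unloaded :class:`ReferenceRecord` stubs.

    Covers the designated rabbit templates (RNA Central URS00009AB771_9986
    28S, URS00006F07B6_9986 18S, URS00006CE1FB_9986 5.8S, URS00006C8ED4_9986
    5S plus the OryCun2.0 genomic source accessions) and the comparison
    schemes: human/yeast 18S RefSeqs, the 1982 rabbit 18S RefSeq, and the
    boar/human 28S RNA Central entries.
    """
    return [
        ReferenceRecord(
            record_id=e["record_id"],
            molecule_class=e["molecule_class"],
            species=e["species"],
            accessions=list(e["accessions"]),
            expected_length=e.get("expected_length"),
            is_template=e.get("is_template", False),
        )
        for e in _manifest_json()
    ]


def builtin_sites() -> list[SiteAnnotation]:
    """Shipped functional-site annotations for the 18S numbering schemes.

    Includes the five A/P-site nucleotides (human numbering), the rabbit
    diagnostic positions G183/C1513 and the h18 G613/C614 pair, plus
    literature sites whose numbering scheme is unverified
    (``scheme_verified=False``).
    """
    text = resources.files("riboaudit.data").joinpath("sites_18s.json").read_text()
    return [
        SiteAnnotation(
            site_name=e["site_name"],
            scheme_id=e["scheme_id"],
            position=e["position"],
            note=e.get("note", ""),
            expected_base=e.get("expected_base"),
            scheme_verified=e.get("scheme_verified", True),
        )
        for e in json.loads(text)
    ]


def manifest_lookup(query: str, manifest: Optional[list[ReferenceRecord]] = None) -> ReferenceRecord:
    """Look up a manifest entry by a "<species> <molecule class>" query.

    ``manifest_lookup("rabbit 18S")`` returns the designated rabbit 18S
    template stub.  The molecule class token must be one of 18S/28S/5.8S/5S.

    Raises
    ------
    KeyError
        ``"unknown molecule class"`` if the class token is not recognized,
        or if no manifest entry matches the species.
    """
    if manifest is None:
        manifest = builtin_manifest()
    tokens = query.split()
    if not tokens:
        raise KeyError("empty query")
    mol = tokens[-1].upper()
    if mol not in MOLECULE_CLASSES:
        raise KeyError(f"unknown molecule class {tokens[-1]!r}")
    species_q = " ".join(tokens[:-1]).lower()
    aliases = {
        "rabbit": "oryctolagus cuniculus",
        "human": "homo sapiens",
        "boar": "sus scrofa",
        "pig": "sus scrofa",
        "yeast": "saccharomyces cerevisiae",
    }
    species_q = aliases.get(species_q, species_q)
    candidates = [r for r in manifest if r.molecule_class == mol and species_q in r.species.lower()]
    if not candidates:
        raise KeyError(f"no manifest entry for {query!r}")
    # prefer the designated template when several schemes share a class
    for r in candidates:
        if r.is_template:
            return r
    return candidates[0]


def validate_reference(record: ReferenceRecord, expected_length: Optional[int] = None) -> ValidationReport:
    """Validate a loaded reference record.

    Runs an alphabet check and, when ``expected_length`` is given (explicitly
    or via the record's manifest metadata), a length check.  Failures are
    report entries, not exceptions.
    """
    checks: list[ValidationCheck] = []
    if record.sequence is None:
        checks.append(ValidationCheck("loaded", False, "sequence not loaded"))
        return ValidationReport(record.record_id, checks)

    bad = sorted({c for c in record.sequence if c not in RNA_ALPHABET})
    checks.append(
        ValidationCheck(
            "alphabet",
            not bad,
            "all characters in {A,C,G,U,N}" if not bad else f"illegal characters: {bad}",
        )
    )
    if expected_length is None:
        expected_length = record.expected_length
    if expected_length is not None:
        ok = record.length == expected_length
        checks.append(
            ValidationCheck(
                "length",
                ok,
                f"expected {expected_length}, actual {record.length}",
            )
        )
    return ValidationReport(record.record_id, checks)


def read_fasta(path: str | Path, molecule_class: str = "18S", species: str = "") -> list[ReferenceRecord]:
    """Read one or more reference records from a FASTA file.

    The first whitespace-separated token of each header is the record id.
    ``molecule_class``/``species`` apply to every record and default to
    placeholders; callers attaching sequences to manifest stubs should
    prefer :func:`load_registry`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ReferenceRecord(
                record_id=rec.id,
                molecule_class=molecule_class,
                species=species,
                sequence=str(rec.seq),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ReferenceRecord], path: str | Path, width: int = 70) -> None:
    """Write loaded records to FASTA (record_id as the header token)."""
    seq_records = []
    for r in records:
        if r.sequence is None:
            raise ValueError(f"record {r.record_id} has no sequence loaded")
        desc = f"{r.species} {r.molecule_class} rRNA".strip()
        seq_records.append(SeqRecord(Seq(r.sequence), id=r.record_id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def load_registry(fasta_path: str | Path, manifest: Optional[list[ReferenceRecord]] = None) -> list[ReferenceRecord]:
    """Attach sequences from a FASTA file to manifest stubs.

    FASTA ids are matched against manifest record ids and accessions
    (version suffixes tolerated).  Records with no match in the manifest are
    returned as standalone entries with molecule class inferred from the
    header when possible.
    """
    if manifest is None:
        manifest = builtin_manifest()
    by_key: dict[str, ReferenceRecord] = {}
    for r in manifest:
        by_key[r.record_id] = r
        for acc in r.accessions:
            by_key[acc] = r
            by_key[acc.split(".")[0]] = r

    loaded: list[ReferenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        stub = by_key.get(rec.id) or by_key.get(rec.id.split(".")[0])
        if stub is not None and stub.record_id not in seen:
            loaded.append(stub.with_sequence(str(rec.seq)))
            seen.add(stub.record_id)
        elif stub is None:
            mol = next((m for m in MOLECULE_CLASSES if m.lower() in rec.description.lower()), "18S")
            loaded.append(
                ReferenceRecord(record_id=rec.id, molecule_class=mol, species="", sequence=str(rec.seq))
            )
    if not loaded:
        raise ValueError(f"no usable records in {fasta_path}")
    ids = [r.record_id for r in loaded]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate record ids after manifest matching")
    return loaded
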