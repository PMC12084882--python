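"""Optional accession fetcher (network convenience; the core never needs it).

Retrieves reference sequences by accession from RNA Central (URS ids with
a taxid suffix) or NCBI E-utilities (RefSeq/GenBank style ids), writing
one normalized FASTA per accession.  Kept deliberately thin: stdlib
urllib, no retries beyond one, per-accession error collection so a flaky
accession does not abort a batch.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .registry import normalize_sequence

RNACENTRAL_FASTA = "https://rnacentral.org/api/v1/rna/{urs}?format=fasta"
NCBI_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)


@dataclass
class FetchResult:
    accession: str
    path: Optional[Path]
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _get(url: str, timeout: float) -> str:
    req = urllib.request.Request(url, headers={"User-Agent": "riboaudit/0.1"})
    with urllib.request.urlopen(req, timeout=timeout) as resp:
        return resp.read().decode()


def fetch_accession(accession: str, out_dir: str | Path, timeout: float = 30.0) -> FetchResult:
    """Fetch one accession to ``<out_dir>/<accession>.fasta`` (normalized)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if accession.upper().startswith("URS"):
        # RNA Central ids may carry a _taxid suffix not used by the API path
        urs = accession.split("_")[0]
        url = RNACENTRAL_FASTA.format(urs=urs)
    else:
        url = NCBI_EFETCH.format(acc=accession)
    try:
        text = _get(url, timeout)
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        return FetchResult(accession, None, error=str(exc))
    lines = text.strip().splitlines()
    if not lines or not lines[0].startswith(">"):
        return FetchResult(accession, None, error=f"no FASTA returned for {accession}")
    try:
        seq = normalize_sequence("".join(lines[1:]))
    except ValueError as exc:
        return FetchResult(accession, None, error=f"bad sequence for {accession}: {exc}")
    path = out_dir / f"{accession}.fasta"
    with open(path, "w") as fh:
        fh.write(f">{accession}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    return FetchResult(accession, path)


def fetch_pdb(entry_id: str, out_dir: str | Path, timeout: float = 60.0) -> FetchResult:
    """Fetch one PDB entry as mmCIF from RCSB to ``<out_dir>/<id>.cif``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entry = entry_id.upper()
    url = f"https://files.rcsb.org/download/{entry}.cif"
    try:
        text = _get(url, timeout)
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        return FetchResult(entry, None, error=str(exc))
    path = out_dir / f"{entry}.cif"
    path.write_text(text)
    return FetchResult(entry, path)


def fetch_accessions(accessions: list[str], out_dir: str | Path, timeout: float = 30.0) -> list[FetchResult]:
    if not accessions:
        raise ValueError("no accessions given")
    return [fetch_accession(a, out_dir, timeout) for a in accessions]
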