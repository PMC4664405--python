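"""Minimal remote sequence retrieval (UniProt REST)."""

from __future__ import annotations

import urllib.request

__all__ = ["fetch_uniprot_sequence"]

_UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


def fetch_uniprot_sequence(accession: str, timeout: float = 10.0) -> str:
    """Fetch one UniProt entry's sequence (requires network access)."""
    url = _UNIPROT_URL.format(accession=accession)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    lines = [l.strip() for l in text.splitlines() if l and not l.startswith(">")]
    seq = "".join(lines).upper()
    if not seq:
        raise ValueError(f"no sequence returned for {accession}")
    return seq
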