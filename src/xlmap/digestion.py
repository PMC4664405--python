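"""In-silico tryptic digestion, peptide filtering, and decoy databases.

Trypsin cleaves C-terminal to K or R except when the next residue is
proline.  Peptides are enumerated for 0..max_missed missed cleavages and
filtered to a length window; each carries provenance (parent id, 1-based
inclusive start/end) so cross-link positions can be mapped back onto the
protein.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .peptide_chem import AA_LETTERS, Peptide, Provenance

__all__ = [
    "DigestParams",
    "DecoyMode",
    "digest",
    "make_decoy",
    "read_fasta",
    "build_database",
    "DECOY_PREFIX",
]

DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class DigestParams:
    enzyme: str = "trypsin"
    max_missed: int = 4
    min_len: int = 6
    max_len: int = 50

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


@dataclass(frozen=True)
class DecoyMode:
    mode: str = "reversed"          # "reversed" | "randomized"
    seed: int | None = None         # randomized mode only

    def __post_init__(self) -> None:
        if self.mode not in ("reversed", "randomized"):
            raise ValueError(f"decoy mode must be 'reversed' or 'randomized', got {self.mode!r}")
        if self.mode == "randomized" and self.seed is None:
            raise ValueError("randomized decoy mode requires a seed")


def _validate_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence, start=1):
        if aa not in AA_LETTERS:
            raise ValueError(f"unknown residue letter {aa!r} at position {i}")


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(protein: tuple[str, str], params: DigestParams = DigestParams()) -> list[Peptide]:
    """All tryptic peptides of one protein within the configured limits.

    Returns peptides ordered by (start, end); fully tryptic only (both
    termini at cleavage sites or protein termini).
    """
    protein_id, sequence = protein
    if not sequence:
        raise ValueError(f"protein {protein_id!r} has an empty sequence")
    _validate_sequence(sequence)

    # Segment boundaries: 0, each cut point + 1, len.
    cuts = cleavage_sites(sequence)
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [len(sequence)]  # exclusive

    peptides: list[Peptide] = []
    for si, start in enumerate(starts):
        for missed in range(params.max_missed + 1):
            ei = si + missed
            if ei >= len(ends):
                break
            end = ends[ei]
            if not params.min_len <= end - start <= params.max_len:
                continue
            peptides.append(
                Peptide(
                    sequence[start:end],
                    provenance=Provenance(protein_id, start + 1, end),
                )
            )
    return peptides


def make_decoy(sequence: str, decoy: DecoyMode = DecoyMode()) -> str:
    """Decoy sequence: same length and residue composition as the target."""
    if not sequence:
        raise ValueError("cannot build a decoy of an empty sequence")
    _validate_sequence(sequence)
    if decoy.mode == "reversed":
        return sequence[::-1]
    rng = random.Random(decoy.seed)
    letters = list(sequence)
    rng.shuffle(letters)
    return "".join(letters)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) records; the id is the first whitespace token of the header."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def build_database(
    targets: list[tuple[str, str]],
    decoy: DecoyMode | None = DecoyMode(),
    decoy_of: list[str] | None = None,
) -> list[tuple[str, str, bool]]:
    """Target + decoy protein list as (id, sequence, is_decoy) triples.

    ``decoy_of`` names the target ids to derive decoys from (default: all);
    the study reversed/randomized only its receptor sequences, so the choice
    is explicit rather than implied.
    """
    db: list[tuple[str, str, bool]] = [(pid, seq, False) for pid, seq in targets]
    if decoy is None:
        return db
    wanted = set(decoy_of) if decoy_of is not None else {pid for pid, _ in targets}
    for pid, seq in targets:
        if pid in wanted:
            db.append((DECOY_PREFIX + pid, make_decoy(seq, decoy), True))
    return db
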