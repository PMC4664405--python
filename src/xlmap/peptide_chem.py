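"""Mass tables and m/z arithmetic for linear and BS3 cross-linked peptides.

The unit of work is a :class:`CrossLinkedPair`: two tryptic peptides joined
through a lysine (or protein N-terminal amine) by the homobifunctional
amine-reactive linker BS3.  A BS3 bridge adds the mass of the suberate
diester minus its two sulfo-NHS leaving groups, 138.06808 Da (C8H10O2).

Fragment-ion generation follows the non-cleavable-linker convention: every
b/y ion of one chain that spans that chain's linked residue carries, as an
appendage, the full (modified) mass of the partner peptide plus the linker
delta.  This is what makes cross-linked spectra diagnostic: the y-ion ladder
of each chain jumps by the partner mass exactly at the linked position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "MASS",
    "MassConstants",
    "Modification",
    "Provenance",
    "Peptide",
    "CrossLinkedPair",
    "FragmentIon",
    "peptide_mass",
    "pair_mass",
    "precursor_mz",
    "fragment_ions",
    "CAM_DELTA",
    "BS3_XLINK_DELTA",
]

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), Da.
CAM_DELTA = 57.02146
#: Mass added by one BS3 bridge between two amines (C8H10O2), Da.
BS3_XLINK_DELTA = 138.06808


def _average_residue_masses() -> dict[str, float]:
    return {
        aa: _pmass.calculate_mass(composition=_pmass.std_aa_comp[aa], average=True)
        for aa in AA_LETTERS
    }


@dataclass(frozen=True)
class MassConstants:
    """Residue and small-molecule masses used throughout, in daltons."""

    residue_mono: dict[str, float]
    residue_avg: dict[str, float]
    water: float = 18.01056
    proton: float = 1.00728
    cam_delta: float = CAM_DELTA
    bs3_xlink_delta: float = BS3_XLINK_DELTA

    def residues(self, scale: str) -> dict[str, float]:
        if scale == "mono":
            return self.residue_mono
        if scale == "average":
            return self.residue_avg
        raise ValueError(f"unknown mass scale {scale!r}; expected 'mono' or 'average'")


#: Module-wide mass constants (monoisotopic residue masses from the standard
#: amino-acid table; average masses from elemental composition).
MASS = MassConstants(
    residue_mono={aa: _pmass.std_aa_mass[aa] for aa in AA_LETTERS},
    residue_avg=_average_residue_masses(),
)


@dataclass(frozen=True)
class Modification:
    """A positional mass modification (1-based position within the peptide)."""

    position: int
    delta: float
    name: str = ""


@dataclass(frozen=True)
class Provenance:
    """Where a peptide came from: parent protein id and 1-based inclusive span."""

    protein_id: str
    start: int
    end: int


@dataclass(frozen=True)
class Peptide:
    sequence: str
    mods: tuple[Modification, ...] = ()
    provenance: Provenance | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in AA_LETTERS:
                raise ValueError(
                    f"unknown residue letter {aa!r} at position {i} in {self.sequence!r}"
                )
        object.__setattr__(self, "mods", tuple(self.mods))
        for m in self.mods:
            if not 1 <= m.position <= len(self.sequence):
                raise ValueError(
                    f"modification position {m.position} outside 1..{len(self.sequence)}"
                )
        if self.provenance is not None:
            span = self.provenance.end - self.provenance.start + 1
            if span != len(self.sequence):
                raise ValueError(
                    f"provenance span {span} does not match sequence length "
                    f"{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def mod_delta_in(self, lo: int, hi: int) -> float:
        """Summed modification deltas with position in [lo, hi] (1-based)."""
        return sum(m.delta for m in self.mods if lo <= m.position <= hi)

    def is_protein_nterm(self) -> bool:
        return self.provenance is not None and self.provenance.start == 1


def with_cam(sequence: str, provenance: Provenance | None = None) -> Peptide:
    """Build a peptide with fixed carbamidomethylation on every cysteine."""
    mods = tuple(
        Modification(i, CAM_DELTA, "Carbamidomethyl")
        for i, aa in enumerate(sequence, start=1)
        if aa == "C"
    )
    return Peptide(sequence, mods, provenance)


@dataclass(frozen=True)
class CrossLinkedPair:
    """Two peptides bridged by a linker at 1-based positions link_a / link_b.

    Linked residues must be lysines, or position 1 when that peptide is a
    protein N-terminus (BS3 also reacts with the free alpha-amine).
    """

    peptide_a: Peptide
    peptide_b: Peptide
    link_a: int
    link_b: int
    linker_delta: float = BS3_XLINK_DELTA

    def __post_init__(self) -> None:
        for pep, pos, tag in (
            (self.peptide_a, self.link_a, "A"),
            (self.peptide_b, self.link_b, "B"),
        ):
            if not 1 <= pos <= len(pep):
                raise ValueError(f"link position {pos} outside chain {tag}")
            if pep.sequence[pos - 1] != "K" and not (pos == 1 and pep.is_protein_nterm()):
                raise ValueError(
                    f"chain {tag} link site {pos} ({pep.sequence[pos - 1]}) is neither "
                    "a lysine nor a protein N-terminus"
                )
        if self.linker_delta <= 0:
            raise ValueError("linker_delta must be positive")

    def id_string(self) -> str:
        """Deterministic identity used for tie-breaking and reporting."""
        a = f"{self.peptide_a.sequence}:{self.link_a}"
        b = f"{self.peptide_b.sequence}:{self.link_b}"
        return f"{a}--{b}" if a <= b else f"{b}--{a}"


Scale = Literal["mono", "average"]


def peptide_mass(p: Peptide, scale: Scale = "mono", constants: MassConstants = MASS) -> float:
    """Neutral peptide mass: residue sum on the chosen scale + water + mods."""
    table = constants.residues(scale)
    return (
        sum(table[aa] for aa in p.sequence)
        + constants.water
        + sum(m.delta for m in p.mods)
    )


def sequence_mass(sequence: str, scale: Scale = "average", constants: MassConstants = MASS) -> float:
    """Neutral mass of a plain sequence (no modifications), in Da."""
    return peptide_mass(Peptide(sequence), scale=scale, constants=constants)


def construct_mass_kda(
    sequence: str,
    start: int,
    end: int,
    scale: Scale = "average",
    constants: MassConstants = MASS,
) -> float:
    """Average (default) mass in kDa of a construct spanning residues
    start..end (1-based inclusive) of a protein sequence."""
    if not 1 <= start <= end <= len(sequence):
        raise ValueError(f"range {start}..{end} outside sequence of length {len(sequence)}")
    return sequence_mass(sequence[start - 1 : end], scale=scale, constants=constants) / 1000.0


def pair_mass(x: CrossLinkedPair, scale: Scale = "mono", constants: MassConstants = MASS) -> float:
    """Neutral mass of a cross-linked pair: mass(A) + mass(B) + linker."""
    return (
        peptide_mass(x.peptide_a, scale, constants)
        + peptide_mass(x.peptide_b, scale, constants)
        + x.linker_delta
    )


def precursor_mz(
    mass_da: float,
    z: int,
    decimals: int | None = None,
    constants: MassConstants = MASS,
) -> float:
    """m/z of an ion of the given neutral mass at charge z (protonation)."""
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    mz = (mass_da + z * constants.proton) / z
    return round(mz, decimals) if decimals is not None else mz


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical product ion, e.g. label 'A.y9.+1'."""

    chain: str          # "A" or "B"
    series: str         # "b" or "y"
    index: int          # ladder index, 1-based
    charge: int
    mz: float
    carries_link: bool  # True when the fragment spans the linked residue

    @property
    def label(self) -> str:
        return f"{self.chain}.{self.series}{self.index}.+{self.charge}"


def _chain_fragments(
    pep: Peptide,
    link_pos: int,
    appendage: float,
    chain_tag: str,
    series: Sequence[str],
    charges: Iterable[int],
    constants: MassConstants,
) -> list[FragmentIon]:
    table = constants.residue_mono
    n = len(pep)
    prefix = [0.0] * (n + 1)
    for i, aa in enumerate(pep.sequence, start=1):
        prefix[i] = prefix[i - 1] + table[aa]
    total_residues = prefix[n]

    out: list[FragmentIon] = []
    for z in charges:
        if "b" in series:
            # b ions span residues 1..i; full-length b_n is not emitted.
            for i in range(1, n):
                carries = link_pos <= i
                neutral = prefix[i] + pep.mod_delta_in(1, i)
                if carries:
                    neutral += appendage
                out.append(
                    FragmentIon(chain_tag, "b", i, z,
                                (neutral + z * constants.proton) / z, carries)
                )
        if "y" in series:
            for i in range(1, n + 1):
                lo = n - i + 1
                carries = link_pos >= lo
                neutral = (total_residues - prefix[lo - 1]) + pep.mod_delta_in(lo, n) + constants.water
                if carries:
                    neutral += appendage
                out.append(
                    FragmentIon(chain_tag, "y", i, z,
                                (neutral + z * constants.proton) / z, carries)
                )
    return out


def fragment_ions(
    x: CrossLinkedPair,
    series: Sequence[str] = ("b", "y"),
    max_fragment_charge: int = 1,
    constants: MassConstants = MASS,
) -> list[FragmentIon]:
    """All theoretical b/y ions of both chains at charges 1..max_fragment_charge.

    A fragment whose residue span contains its chain's linked position carries
    the linker delta plus the full modified mass of the partner peptide.
    Returned sorted by (chain, series, index, charge) for stable output.
    """
    bad = set(series) - {"b", "y"}
    if bad:
        raise ValueError(f"unsupported ion series: {sorted(bad)}")
    charges = range(1, max_fragment_charge + 1)
    app_a = x.linker_delta + peptide_mass(x.peptide_b, "mono", constants)
    app_b = x.linker_delta + peptide_mass(x.peptide_a, "mono", constants)
    ions = _chain_fragments(x.peptide_a, x.link_a, app_a, "A", series, charges, constants)
    ions += _chain_fragments(x.peptide_b, x.link_b, app_b, "B", series, charges, constants)
    ions.sort(key=lambda f: (f.chain, f.series, f.index, f.charge))
    return ions
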