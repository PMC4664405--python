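"""Cross-linked peptide-spectrum matching with target-decoy scoring.

Candidate enumeration pairs every two database peptides (self-pairs
included) that carry an eligible amine link site and whose cross-linked
mass falls within the precursor tolerance.  Each candidate is fragmented in
silico and matched against the observed peak list.  Three scores are
reported per match:

``score``
    number of theoretical b/y ions found within the fragment tolerance;
``pp``
    -log10 of the binomial upper-tail probability that at least ``score``
    of the theoretical ions would match by chance, with per-ion random
    match probability p = n_peaks * 2 * tol / observed m/z span;
``pp2``
    -log10 of the permutation probability that a random peak subset of the
    matched size has total intensity at least as large as the matched
    intensity.

Per spectrum, only the highest-scoring match is retained (ties broken by
higher pp, then by pair identity string), and matches below the configured
thresholds are discarded.  Decoy hits estimate the false discovery rate.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from scipy import stats

from .digestion import DecoyMode, DigestParams, DECOY_PREFIX, build_database, digest
from .peptide_chem import (
    BS3_XLINK_DELTA,
    CAM_DELTA,
    MASS,
    CrossLinkedPair,
    Modification,
    Peptide,
    fragment_ions,
    pair_mass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumRecord",
    "SearchParams",
    "MatchScores",
    "PSM",
    "read_mgf",
    "write_mgf",
    "eligible_link_sites",
    "candidate_pairs",
    "assumed_charges",
    "match_spectrum",
    "run_search",
    "decoy_fdr",
    "psms_to_dataframe",
]


@dataclass(frozen=True)
class SpectrumRecord:
    """One MS/MS peak list with precursor information."""

    spectrum_id: str
    precursor_mz: float
    declared_charge: int | None
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        mz = np.asarray(self.mz, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if mz.shape != it.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", it[order])

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class SearchParams:
    precursor_tol_ppm: float = 10.0
    fragment_tol: float = 0.02          # Da
    charge_list: tuple[int, ...] = (1, 2, 3)
    linker_delta: float = BS3_XLINK_DELTA
    digest: DigestParams = field(default_factory=DigestParams)
    decoy: DecoyMode | None = field(default_factory=DecoyMode)
    min_score: int = 5
    min_pp: float = 2.0
    min_pp2: float = 0.0
    n_permutations: int = 1000
    seed: int = 0
    cam_fixed: bool = True              # carbamidomethylate every Cys

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not self.charge_list:
            raise ValueError("charge_list must be non-empty")


@dataclass(frozen=True)
class MatchScores:
    score: int
    pp: float
    pp2: float

    def __post_init__(self) -> None:
        if self.score < 0 or self.pp < 0 or self.pp2 < 0:
            raise ValueError("scores must be non-negative")


@dataclass(frozen=True)
class PSM:
    spectrum_id: str
    pair: CrossLinkedPair
    charge: int
    scores: MatchScores
    is_decoy: bool


# ---------------------------------------------------------------------------
# MGF I/O

def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read an MGF peak-list file into SpectrumRecord objects."""
    out: list[SpectrumRecord] = []
    with _mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            title = str(params.get("title", f"spectrum_{i}"))
            pepmass = params["pepmass"]
            mz0 = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge")
            declared = int(charge[0]) if charge else None
            out.append(
                SpectrumRecord(title, mz0, declared, spec["m/z array"], spec["intensity array"])
            )
    return out


def write_mgf(path: str | Path, spectra: Iterable[SpectrumRecord]) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.spectrum_id, "pepmass": s.precursor_mz}
        if s.declared_charge is not None:
            params["charge"] = s.declared_charge
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Candidate enumeration

def eligible_link_sites(p: Peptide, protein_length: int | None = None) -> list[int]:
    """1-based positions where BS3 can attach on this peptide.

    Lysines are eligible unless they sit at the peptide C-terminus as a
    cleavage product boundary: a BS3-blocked lysine is not cleaved by
    trypsin, so a C-terminal K can only be linked when it is also the
    protein C-terminus.  Position 1 is eligible regardless of residue when
    the peptide starts the protein (free alpha-amine).
    """
    n = len(p)
    prov = p.provenance
    sites = []
    for i, aa in enumerate(p.sequence, start=1):
        if aa != "K":
            continue
        if i == n:
            at_protein_cterm = (
                prov is not None
                and protein_length is not None
                and prov.end == protein_length
            )
            if not at_protein_cterm:
                continue
        sites.append(i)
    if prov is not None and prov.start == 1 and 1 not in sites:
        sites.insert(0, 1)
    return sites


def candidate_pairs(
    peptides: Sequence[Peptide],
    precursor_mass: float,
    tol_ppm: float,
    linker_delta: float = BS3_XLINK_DELTA,
    protein_lengths: dict[str, int] | None = None,
) -> list[CrossLinkedPair]:
    """All cross-linked pairs whose mass is within tol of the precursor.

    Every unordered peptide pair (self-pairs allowed) contributes one
    candidate per combination of eligible link sites.
    """
    if precursor_mass <= 0:
        raise ValueError("precursor mass must be positive")
    lengths = protein_lengths or {}
    masses = []
    sites: list[list[int]] = []
    from .peptide_chem import peptide_mass

    for p in peptides:
        masses.append(peptide_mass(p, "mono"))
        plen = lengths.get(p.provenance.protein_id) if p.provenance else None
        sites.append(eligible_link_sites(p, plen))

    tol = precursor_mass * tol_ppm * 1e-6
    out: list[CrossLinkedPair] = []
    for i in range(len(peptides)):
        if not sites[i]:
            continue
        for j in range(i, len(peptides)):
            if not sites[j]:
                continue
            m = masses[i] + masses[j] + linker_delta
            if abs(m - precursor_mass) > tol:
                continue
            for si in sites[i]:
                for sj in sites[j]:
                    out.append(
                        CrossLinkedPair(peptides[i], peptides[j], si, sj, linker_delta)
                    )
    return out


def assumed_charges(s: SpectrumRecord, params: SearchParams) -> list[int]:
    """Charges to search: the declared charge when known; otherwise every
    configured charge except 1 (spectra not determined as singly charged are
    searched as multiply charged)."""
    if s.declared_charge is not None:
        return [s.declared_charge]
    return [z for z in params.charge_list if z != 1]


# ---------------------------------------------------------------------------
# Scoring

def match_spectrum(
    s: SpectrumRecord,
    x: CrossLinkedPair,
    z: int,
    params: SearchParams,
    rng: np.random.Generator | None = None,
) -> MatchScores:
    """Score one candidate pair against one spectrum at assumed charge z."""
    if s.n_peaks == 0:
        return MatchScores(0, 0.0, 0.0)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    max_fz = max(1, min(z - 1, 2))
    theo = fragment_ions(x, ("b", "y"), max_fragment_charge=max_fz)
    theo_mz = np.array([f.mz for f in theo])
    n_theo = theo_mz.size

    # A theoretical ion matches when any observed peak lies within tol.
    idx = np.searchsorted(s.mz, theo_mz)
    matched_ion = np.zeros(n_theo, dtype=bool)
    matched_peaks: set[int] = set()
    for k, (mi, pos) in enumerate(zip(theo_mz, idx)):
        for cand in (pos - 1, pos):
            if 0 <= cand < s.n_peaks and abs(s.mz[cand] - mi) <= params.fragment_tol:
                matched_ion[k] = True
                matched_peaks.add(int(cand))
    score = int(matched_ion.sum())
    if score == 0:
        return MatchScores(0, 0.0, 0.0)

    span = float(s.mz[-1] - s.mz[0])
    if span <= 0:
        p_rand = 1.0
    else:
        p_rand = min(1.0, s.n_peaks * 2.0 * params.fragment_tol / span)
    # Upper tail P(X >= score) for X ~ Binomial(n_theo, p_rand).
    p_count = float(stats.binom.sf(score - 1, n_theo, p_rand))
    pp = -math.log10(max(p_count, 1e-300))

    # Permutation test on matched abundance.
    k = min(len(matched_peaks), s.n_peaks)
    observed = float(s.intensity[sorted(matched_peaks)].sum())
    if k == 0 or k == s.n_peaks:
        pp2 = 0.0
    else:
        draws = np.empty(params.n_permutations)
        for t in range(params.n_permutations):
            subset = rng.choice(s.n_peaks, size=k, replace=False)
            draws[t] = s.intensity[subset].sum()
        p_abund = (1.0 + float((draws >= observed - 1e-12).sum())) / (params.n_permutations + 1.0)
        pp2 = -math.log10(p_abund)
    return MatchScores(score, max(pp, 0.0), max(pp2, 0.0))


# ---------------------------------------------------------------------------
# Search driver

def _digest_database(
    database: Sequence[tuple[str, str, bool]],
    params: SearchParams,
) -> tuple[list[Peptide], dict[str, int], set[str]]:
    peptides: list[Peptide] = []
    lengths: dict[str, int] = {}
    decoy_ids: set[str] = set()
    for pid, seq, is_decoy in database:
        lengths[pid] = len(seq)
        if is_decoy:
            decoy_ids.add(pid)
        for p in digest((pid, seq), params.digest):
            if params.cam_fixed and "C" in p.sequence:
                mods = tuple(
                    Modification(i, CAM_DELTA, "Carbamidomethyl")
                    for i, aa in enumerate(p.sequence, start=1)
                    if aa == "C"
                )
                p = Peptide(p.sequence, mods, p.provenance)
            peptides.append(p)
    return peptides, lengths, decoy_ids


def run_search(
    spectra: Sequence[SpectrumRecord],
    database: Sequence[tuple[str, str, bool]],
    params: SearchParams = SearchParams(),
) -> tuple[list[PSM], dict]:
    """Search spectra against a target+decoy database.

    ``database`` rows are (protein id, sequence, is_decoy); use
    :func:`xlmap.digestion.build_database` to append decoys.  Returns the
    best PSM per spectrum passing thresholds, plus a JSON-able run report.
    """
    peptides, lengths, _ = _digest_database(database, params)
    rng = np.random.default_rng(params.seed)

    psms: list[PSM] = []
    n_unmatched = 0
    n_failed = 0
    for s in sorted(spectra, key=lambda r: r.spectrum_id):
        try:
            best: tuple | None = None
            for z in assumed_charges(s, params):
                precursor_mass = s.precursor_mz * z - z * MASS.proton
                if precursor_mass <= 0:
                    continue
                for cand in candidate_pairs(
                    peptides, precursor_mass, params.precursor_tol_ppm,
                    params.linker_delta, lengths,
                ):
                    sc = match_spectrum(s, cand, z, params, rng)
                    key = (sc.score, sc.pp, _neg_lex(cand.id_string()))
                    if best is None or key > best[0]:
                        best = (key, cand, z, sc)
            if best is None:
                n_unmatched += 1
                continue
            _, cand, z, sc = best
            if (
                sc.score < params.min_score
                or sc.pp < params.min_pp
                or sc.pp2 < params.min_pp2
            ):
                n_unmatched += 1
                continue
            is_decoy = any(
                p.provenance is not None and p.provenance.protein_id.startswith(DECOY_PREFIX)
                for p in (cand.peptide_a, cand.peptide_b)
            )
            psms.append(PSM(s.spectrum_id, cand, z, sc, is_decoy))
        except Exception as exc:  # unreadable/degenerate spectrum: skip, count
            logger.warning("spectrum %s skipped: %s", s.spectrum_id, exc)
            n_failed += 1

    report = {
        "n_spectra": len(spectra),
        "n_psms": len(psms),
        "n_below_threshold_or_unmatched": n_unmatched,
        "n_failed": n_failed,
        "n_target_psms": sum(not p.is_decoy for p in psms),
        "n_decoy_psms": sum(p.is_decoy for p in psms),
        "params": {
            "precursor_tol_ppm": params.precursor_tol_ppm,
            "fragment_tol": params.fragment_tol,
            "charge_list": list(params.charge_list),
            "min_score": params.min_score,
            "min_pp": params.min_pp,
            "min_pp2": params.min_pp2,
            "n_permutations": params.n_permutations,
            "seed": params.seed,
        },
    }
    return psms, report


class _neg_lex(str):
    """Reverse lexicographic ordering so that max() prefers the smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def decoy_fdr(psms: Sequence[PSM]) -> pd.DataFrame:
    """Per-score-cutoff target/decoy counts and estimated FDR = D/T.

    Rows are sorted by ascending cutoff; FDR is NaN (with flag) where no
    target survives the cutoff.
    """
    if not psms:
        return pd.DataFrame(
            columns=["score_cutoff", "n_target", "n_decoy", "fdr", "flag"]
        )
    scores = np.array([p.scores.score for p in psms])
    decoys = np.array([p.is_decoy for p in psms])
    rows = []
    no_decoys = not decoys.any()
    for cut in np.unique(scores):
        keep = scores >= cut
        n_t = int((keep & ~decoys).sum())
        n_d = int((keep & decoys).sum())
        if n_t == 0:
            fdr, flag = float("nan"), "no_target_psms"
        elif no_decoys:
            fdr, flag = 0.0, "no_decoy_psms"
        else:
            fdr, flag = n_d / n_t, ""
        rows.append(
            {"score_cutoff": int(cut), "n_target": n_t, "n_decoy": n_d, "fdr": fdr, "flag": flag}
        )
    return pd.DataFrame(rows)


def psms_to_dataframe(psms: Sequence[PSM]) -> pd.DataFrame:
    rows = []
    for p in psms:
        a, b = p.pair.peptide_a, p.pair.peptide_b
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "proteinA": a.provenance.protein_id if a.provenance else "",
                "pepA": a.sequence,
                "posA": p.pair.link_a,
                "proteinB": b.provenance.protein_id if b.provenance else "",
                "pepB": b.sequence,
                "posB": p.pair.link_b,
                "z": p.charge,
                "score": p.scores.score,
                "pp": p.scores.pp,
                "pp2": p.scores.pp2,
                "decoy": p.is_decoy,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "spectrum_id", "proteinA", "pepA", "posA", "proteinB", "pepB",
            "posB", "z", "score", "pp", "pp2", "decoy",
        ],
    )


def write_psm_tsv(path: str | Path, psms: Sequence[PSM]) -> None:
    psms_to_dataframe(psms).to_csv(path, sep="\t", index=False)


def write_report_json(path: str | Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
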