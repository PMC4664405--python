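"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators mirror the statistical structure of the study's inputs:

* two-chain receptor structures with lysine anchors placed at controlled
  pairwise distances (for restraint-geometry tests),
* docking-pose ensembles of 100 poses with a planted fraction of
  restraint-satisfying placements (for the screening workflow),
* MS/MS spectra of known cross-linked peptide pairs with configurable
  fragment coverage and log-normal noise peaks in a 300–1650 m/z window,
* replicate bound/input densitometry tables with stated condition means
  (defaults 1.08 / 0.74 / 0.76, n = 3) and replicate noise.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .peptide_chem import CrossLinkedPair, pair_mass, precursor_mz, fragment_ions
from .pose_pipeline import PoseSet
from .structure_restraints import (
    AnchorSpec,
    DEFAULT_CAP,
    Residue,
    StructureModel,
    XLRestraint,
)
from .xl_search import SpectrumRecord

__all__ = [
    "StructureSimConfig",
    "PoseSimConfig",
    "SpectrumSimConfig",
    "DensitometrySimConfig",
    "SimConfig",
    "make_structure_fixture",
    "make_pose_ensemble",
    "make_xl_spectra",
    "make_densitometry",
]


@dataclass(frozen=True)
class StructureSimConfig:
    """Anchor identities and target pairwise NZ-NZ distances (Å)."""

    anchors: tuple[tuple[str, int], ...] = (("A", 10), ("B", 10))
    distances: tuple[tuple[float, ...], ...] = ((0.0, 11.2), (11.2, 0.0))
    tolerance: float = 0.01


@dataclass(frozen=True)
class PoseSimConfig:
    n_poses: int = 100                  # ensemble size of the docking run
    satisfying_fraction: float = 0.07
    cap: float = DEFAULT_CAP
    receptor_anchor_sep: float = 10.0   # Å between the two receptor anchors
    control_distance: float = 11.2      # Å, receptor-internal control pair
    jitter_sd: float = 0.0              # Å, extra noise on placements

    def __post_init__(self) -> None:
        if not 0.0 <= self.satisfying_fraction <= 1.0:
            raise ValueError("satisfying fraction must be in [0, 1]")
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")


@dataclass(frozen=True)
class SpectrumSimConfig:
    coverage: float = 1.0               # fraction of theoretical ions present
    n_noise_peaks: int = 30
    scan_range: tuple[float, float] = (300.0, 1650.0)
    signal_log_mu: float = math.log(1e5)
    noise_log_mu: float = math.log(1e3)
    log_sigma: float = 0.5
    charge: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


@dataclass(frozen=True)
class DensitometrySimConfig:
    """Condition -> (true mean ratio, replicate SD); defaults mirror a
    three-condition pull-down with n = 3 per condition."""

    conditions: tuple[tuple[str, str, float, float], ...] = (
        ("alpha", "PDI", 1.08, 0.13 * math.sqrt(3)),
        ("beta", "PDI", 0.74, 0.02 * math.sqrt(3)),
        ("alphabeta", "PDI", 0.76, 0.06 * math.sqrt(3)),
    )
    n_replicates: int = 3
    input_log_mu: float = math.log(100.0)
    input_log_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")


@dataclass(frozen=True)
class SimConfig:
    seed: int
    structure: StructureSimConfig = field(default_factory=StructureSimConfig)
    poses: PoseSimConfig = field(default_factory=PoseSimConfig)
    spectra: SpectrumSimConfig = field(default_factory=SpectrumSimConfig)
    densitometry: DensitometrySimConfig = field(default_factory=DensitometrySimConfig)


# ---------------------------------------------------------------------------
# Structure fixtures

def _embed_distances(d: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Classical multidimensional scaling into <= 3 dimensions."""
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    # Triangle-inequality screen first, to name a violating triple.
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if d[i, j] > d[i, k] + d[k, j] + 1e-9:
                    raise ValueError(
                        f"distances not realizable: triangle inequality violated "
                        f"by anchors ({i}, {j}, {k}): "
                        f"d[{i},{j}]={d[i, j]:.3f} > {d[i, k]:.3f} + {d[k, j]:.3f}"
                    )
    d2 = d**2
    j_mat = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j_mat @ d2 @ j_mat
    w, v = np.linalg.eigh(b)
    if np.any(w < -max(tol, 1e-6 * max(w.max(), 1.0))):
        raise ValueError("distance matrix is not embeddable in Euclidean space")
    w = np.clip(w, 0.0, None)
    order = np.argsort(w)[::-1][:3]
    if np.sum(w) - np.sum(w[order]) > tol * max(np.sum(w), 1.0):
        raise ValueError("distance matrix requires more than 3 dimensions")
    coords = v[:, order] * np.sqrt(w[order])
    if coords.shape[1] < 3:
        coords = np.hstack([coords, np.zeros((n, 3 - coords.shape[1]))])
    return coords


def make_structure_fixture(cfg: StructureSimConfig) -> StructureModel:
    """Lysine-anchor structure whose NZ atoms realise the target distances.

    Each anchor becomes a LYS residue with an NZ atom at the embedded
    coordinate and a CA atom 1.5 Å away, grouped into the requested chains.
    Achieved pairwise distances are verified to cfg.tolerance.
    """
    d = np.asarray(cfg.distances, dtype=float)
    if d.shape[0] != len(cfg.anchors):
        raise ValueError("distance matrix size must match the anchor count")
    coords = _embed_distances(d)
    achieved = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    err = np.abs(achieved - d)
    if err.max() > cfg.tolerance:
        i, j = np.unravel_index(np.argmax(err), err.shape)
        raise ValueError(
            f"embedding error {err.max():.4f} A exceeds tolerance for anchors {i},{j}"
        )
    chains: dict[str, dict[int, Residue]] = {}
    for (chain, resnum), nz in zip(cfg.anchors, coords):
        chains.setdefault(chain, {})[resnum] = Residue(
            "LYS", {"NZ": nz.copy(), "CA": nz + np.array([1.5, 0.0, 0.0])}
        )
    return StructureModel("synthetic_anchors", chains)


# ---------------------------------------------------------------------------
# Pose ensembles

def make_pose_ensemble(
    cfg: PoseSimConfig, seed: int
) -> tuple[PoseSet, list[XLRestraint], dict[str, bool]]:
    """Receptor + n docking poses, exactly floor(f*n) of them satisfying.

    The receptor carries two evidence anchors (chains A and B) and a
    receptor-internal control lysine pair at the configured control
    distance.  The ligand (chain L) is a rigid two-anchor body congruent to
    the receptor anchor pair; a satisfying pose offsets it by a vector well
    inside the cap, a violating pose by one well outside.  Returns the pose
    set, the restraint list (two evidence + one control), and the
    ground-truth label per pose id.
    """
    rng = np.random.default_rng(seed)
    sep = cfg.receptor_anchor_sep
    r1 = np.zeros(3)
    r2 = np.array([sep, 0.0, 0.0])
    c_half = cfg.control_distance / 2.0
    ctrl1 = np.array([sep / 2.0 - c_half, 8.0, 0.0])
    ctrl2 = np.array([sep / 2.0 + c_half, 8.0, 0.0])

    def lys(nz: np.ndarray) -> Residue:
        return Residue("LYS", {"NZ": nz.copy(), "CA": nz + np.array([0.0, 1.5, 0.0])})

    receptor = StructureModel(
        "synthetic_receptor",
        {
            "A": {10: lys(r1), 20: lys(ctrl1)},
            "B": {10: lys(r2), 20: lys(ctrl2)},
        },
    )
    restraints = [
        XLRestraint(AnchorSpec("A", 10), AnchorSpec("L", 10), cap=cfg.cap,
                    label="receptorA-ligand1", role="evidence"),
        XLRestraint(AnchorSpec("B", 10), AnchorSpec("L", 20), cap=cfg.cap,
                    label="receptorB-ligand2", role="evidence"),
        XLRestraint(AnchorSpec("A", 20), AnchorSpec("B", 20), cap=cfg.cap,
                    label="internal-control", role="control"),
    ]
    n_sat = math.floor(cfg.satisfying_fraction * cfg.n_poses)
    labels = [True] * n_sat + [False] * (cfg.n_poses - n_sat)
    rng.shuffle(labels)

    margin = 2.0 + 3.0 * cfg.jitter_sd
    poses: list[tuple[str, StructureModel]] = []
    truth: dict[str, bool] = {}
    for i, satisfying in enumerate(labels):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        if satisfying:
            radius = rng.uniform(1.0, max(cfg.cap - margin, 1.5))
            if cfg.jitter_sd > 0:
                radius = float(
                    np.clip(radius + rng.normal(0.0, cfg.jitter_sd), 0.5, cfg.cap - 0.5)
                )
        else:
            radius = rng.uniform(cfg.cap + margin + 5.0, cfg.cap + margin + 50.0)
            if cfg.jitter_sd > 0:
                radius = float(max(radius + rng.normal(0.0, cfg.jitter_sd), cfg.cap + 5.0))
        offset = direction * radius
        pose_id = f"pose_{i:03d}"
        ligand = StructureModel(
            pose_id, {"L": {10: lys(r1 + offset), 20: lys(r2 + offset)}}
        )
        poses.append((pose_id, ligand))
        truth[pose_id] = satisfying
    return PoseSet(receptor, poses), restraints, truth


# ---------------------------------------------------------------------------
# Spectra

def make_xl_spectra(
    cfg: SpectrumSimConfig, pairs: list[CrossLinkedPair], seed: int
) -> tuple[list[SpectrumRecord], pd.DataFrame]:
    """One spectrum per cross-linked pair, plus a ground-truth table.

    Each spectrum contains a random ``coverage`` fraction of the pair's
    theoretical b/y ions (cross-link-carrying ions included) at the
    intensity model's signal level, and ``n_noise_peaks`` uniform-m/z noise
    peaks at the noise level.  The precursor m/z is exact for the
    configured charge, which is also declared in the record.
    """
    rng = np.random.default_rng(seed)
    spectra: list[SpectrumRecord] = []
    rows = []
    lo, hi = cfg.scan_range
    max_fz = max(1, min(cfg.charge - 1, 2))
    for i, pair in enumerate(pairs):
        ions = fragment_ions(pair, ("b", "y"), max_fragment_charge=max_fz)
        theo_mz = np.array([f.mz for f in ions])
        n_keep = int(round(cfg.coverage * theo_mz.size))
        keep_idx = rng.choice(theo_mz.size, size=n_keep, replace=False) if n_keep else []
        signal_mz = theo_mz[sorted(keep_idx)] if n_keep else np.empty(0)
        signal_int = rng.lognormal(cfg.signal_log_mu, cfg.log_sigma, size=signal_mz.size)
        noise_mz = rng.uniform(lo, hi, size=cfg.n_noise_peaks)
        noise_int = rng.lognormal(cfg.noise_log_mu, cfg.log_sigma, size=cfg.n_noise_peaks)
        mz = np.concatenate([signal_mz, noise_mz])
        intensity = np.concatenate([signal_int, noise_int])
        sid = f"synthetic_{i:03d}"
        spectra.append(
            SpectrumRecord(
                sid,
                precursor_mz(pair_mass(pair), cfg.charge),
                cfg.charge,
                mz,
                intensity,
            )
        )
        rows.append(
            {
                "spectrum_id": sid,
                "pepA": pair.peptide_a.sequence,
                "posA": pair.link_a,
                "pepB": pair.peptide_b.sequence,
                "posB": pair.link_b,
                "z": cfg.charge,
                "n_signal": int(n_keep),
                "n_noise": cfg.n_noise_peaks,
            }
        )
    return spectra, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Densitometry

def make_densitometry(
    cfg: DensitometrySimConfig, seed: int
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Replicate bound/input table with known condition means.

    Replicate ratios are Normal(mean, SD) truncated at zero (redrawn);
    inputs are log-normal; bound = ratio * input.  Returns the table and
    the true mean per 'construct:partner' condition.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, float] = {}
    for construct, partner, mean, sd in cfg.conditions:
        truth[f"{construct}:{partner}"] = mean
        for rep in range(1, cfg.n_replicates + 1):
            ratio = rng.normal(mean, sd)
            while ratio <= 0:
                ratio = rng.normal(mean, sd)
            input_sig = rng.lognormal(cfg.input_log_mu, cfg.input_log_sigma)
            rows.append(
                {
                    "construct": construct,
                    "partner": partner,
                    "replicate": rep,
                    "bound": ratio * input_sig,
                    "input": input_sig,
                }
            )
    return pd.DataFrame(rows), truth
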