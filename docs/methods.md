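# Methods

This note records the models, parameter choices and numerical conventions
behind each pipeline stage, and what the synthetic-data tests do and do not
demonstrate about real data.

## Mass arithmetic and fragment model

Peptide masses are residue sums (monoisotopic or average tables derived
from the standard amino-acid compositions) plus water (18.01056 Da) plus
positional modification deltas. Fixed modifications: carbamidomethylation
of every cysteine (+57.02146 Da), reflecting iodoacetamide alkylation
before digestion. The BS3 cross-link adds 138.06808 Da (C8H10O2, the
suberate bridge after loss of both sulfo-NHS groups); mono-links and
hydrolyzed dead-ends are not modelled. m/z uses a proton mass of
1.00728 Da and is reported to 2 decimals by convention.

Fragmention follows the non-cleavable-linker convention: b-ions are
emitted for ladder indices 1..n−1, y-ions for 1..n, and any fragment whose
residue span contains its chain's linked position carries the linker delta
plus the full modified mass of the partner peptide. Chains are labelled
A/B (not α/β, which name the receptor subunits). a/x/c/z series, neutral
losses and isotope envelopes are out of scope.

A charge-state note: for the identified α/β catalytic-domain pair
(YCLFGNNVTLANKFESCSVPR × TETTGEKGK, both Cys carbamidomethylated), the
printed precursor m/z of 891.68 is arithmetically consistent with charge
4+ (a 6+ ion of that mass would appear at 594.79). The package never
hard-codes a charge for this pair; the charge is always an explicit
argument.

## Digestion and decoys

Trypsin cleaves C-terminal to K/R, suppressed before proline. Defaults:
≤ 4 missed cleavages, peptide length 6–50. Eligible BS3 sites are
lysines — except a peptide C-terminal lysine, which cannot be a cleavage
product boundary when linker-blocked (unless it is the protein
C-terminus) — plus position 1 of a protein N-terminal peptide (free
α-amine). Decoys are reversed (deterministic) or seeded permutations;
which targets get decoys is an explicit argument, since decoy sets need
not cover every database entry.

## Spectrum matching and significance

Candidates are all unordered peptide pairs (self-pairs included) with an
eligible site on each chain whose bridged mass lies within the precursor
tolerance (default 10 ppm). Fragment matching uses an absolute tolerance
(default 0.02 Da); both are instrument-class defaults and configurable.
Spectra with a declared charge are searched at that charge; spectra of
unknown charge are searched as 2+ and 3+ (singly charged spectra only as
1+). Product-ion charges run 1..min(z−1, 2); at z = 1 this is taken as
{1} so singly charged precursors still yield a ladder.

Scores:

* `score` — number of theoretical ions matched within tolerance.
* `pp` — −log10 of the binomial upper tail P(X ≥ score) with
  X ~ Binomial(N_theoretical, p), p = min(1, n_peaks · 2·tol / m/z span):
  the chance that at least this many ions match a random peak list of the
  same density. The tail probability is floored at 1e-300 before the log.
* `pp2` — −log10 of a permutation p-value: among 1000 seeded random peak
  subsets of the matched size, the fraction (with add-one smoothing)
  whose total intensity reaches the matched intensity.

These are analogues of published count- and abundance-randomness scores,
re-specified so they are exactly testable; they are not a reimplementation
of any proprietary scoring function. Per spectrum the top match is kept
(ties: higher pp, then lexicographically smaller pair id — deterministic
output). Threshold defaults (score ≥ 5, pp ≥ 2) are package choices
exposed in configuration, not published values. FDR is estimated as
#decoy/#target above a score cutoff; with no decoy hits it is reported as
0 with a flag, with no target hits as undefined.

## Restraint geometry

Anchor atom preference NZ → CB → CA; fallbacks are logged and the same
cap applies regardless (whether published caps refer to NZ or Cα is
unstated; NZ is the default, Cα selectable). The acceptance cap defaults
to 15 Å — lysine side-chain reach on both sides plus the 11.3 Å BS3
spacer — and a distance exactly at the cap is satisfied (≤). Residues are
addressed by author numbering with an optional per-chain offset.
Multi-copy crystals keep the first instance of each chain id. Alternate
locations resolve to the highest-occupancy atom.

Bridging feasibility: "paper" mode treats the two ligand anchors as
colocated, feasible iff d_receptor ≤ 2·cap (30 Å at the default); the
"triangle" mode uses the rigid-geometry necessary-and-sufficient bound
|d_receptor − d_ligand| ≤ 2·cap. Paper mode is the headline rule; both
are reported. Paper-mode feasibility implies triangle-mode feasibility
whenever d_ligand ≤ 2·cap.

Pose screening accepts a pose iff all evidence restraints hold and the
receptor-internal control passes. Control rule default: ≤ cap; a stricter
mode (≤ spacer + 1 Å slack) is available, motivated by a control pair
observed at essentially the spacer length (11.2 Å vs 11.3 Å). Which
restraint subset applies to which docking scenario (α-side vs β-side
poses) is the caller's choice — the screen takes explicit restraint lists
rather than guessing.

## Tail sampler

Published tail distances came from all-atom MD on modelled C-terminal
extensions. That machinery extracts a purely geometric quantity — the
closest achievable distance between two tail lysines — so it is replaced
here by a Cα-level estimator: self-avoiding chains grown from the last
resolved CA with fixed 3.8 Å virtual bonds, uniform random directions,
4.0 Å hard clash radius against fixed CAs (excluding the bonded
predecessor) and non-adjacent tail residues, 50 retries per step.
`closest_pair_distance` is the minimum over the cross product of two
ensembles: an upper bound on the geometric minimum that is monotone
non-increasing in ensemble size and respects the analytic lower bound
d(anchors) − 3.8·(LA + LB). On a two-single-residue toy (anchors 20 Å
apart) it converges to the closed-form 12.4 Å within 0.5 Å at n = 5000.
The MD-derived numbers themselves (61.3 Å, 11.2 Å) are *inputs* to the
feasibility logic here, not reproduced quantities. Reported positions are
Cα-based; a configurable +6.4 Å side-chain extension (off by default)
bridges to amine-based caps. No force field, torsional realism or
trajectory statistics are claimed.

## Densitometry statistics

Ratios are bound/input per replicate; condition summaries are mean and
SEM = sample SD/√n (the standard convention for "±" with n = 3; SEM is
flagged undefined at n = 1). "Student's t-test" is interpreted as
two-sample, pooled-variance, two-sided (df = nA + nB − 2); Welch is a
flag. Zero pooled variance with equal means gives t = 0, p = 1; with
unequal means it is flagged degenerate with p reported as 0. No
multiple-testing correction is applied — deliberately, matching the
analysis this mirrors — and none is silently added.

## Synthetic data: what it emulates, and what passing tests show

* **Structures**: lysine anchors embedded (classical MDS) at exact target
  pairwise distances (±0.01 Å), written as valid PDB. Unrealizable
  requests fail naming a violating triangle triple.
* **Poses**: a rigid two-anchor ligand offset from the receptor by a
  vector whose norm is drawn well inside (satisfying) or well outside
  (violating) the cap, exactly floor(f·n) satisfying by construction;
  defaults n = 100, f = 0.07. Optional jitter stays clamped inside the
  guarantee bands.
* **Spectra**: a chosen fraction of the theoretical b/y ions (appendage
  ions included) at log-normal signal intensity, plus uniform-m/z noise
  peaks (default window 300–1650 m/z) at log-normal noise intensity; the
  precursor m/z is exact for the declared charge. The noise model is a
  package choice — no published noise model exists for these data.
* **Densitometry**: replicate ratios Normal(mean, SD) truncated at 0 by
  redraw, inputs log-normal, bound = ratio·input; default condition means
  1.08/0.74/0.76 with SD = printed SEM·√3 and n = 3.

All generators are pure functions of (config, seed). Passing
planted-truth tests shows the pipeline's logic is correct and calibrated
on data satisfying its assumptions; it does not show robustness to
co-eluting peptides, isotope envelopes, systematic mass error, partially
disordered receptors, or non-normal densitometry noise, none of which the
generators emulate.

A calibration subtlety: "mean within 2 SEM of truth in ~95% of runs" is a
z-interval statement. At n = 3 the exact coverage of a 2-SEM interval
with estimated SD is P(|t₂| ≤ 2) ≈ 81.6%, and the generator reproduces
that value; the ~95% (≥ 93% asserted) behaviour emerges at large n
(tested at n = 100). Both facts are asserted rather than loosening either
check.

## Problem sizes used by the default test run

Suite-wide sizes are chosen for seconds-scale runs: 500-spectrum null
simulations, 100-geometry Monte-Carlo placement oracle, 5000-conformer
tail ensembles, 50-seed pose-rate studies, 1000-seed type-I-error and
coverage simulations. The acceptance script's computation (one peptide
pair, 30 residues) is exact and instantaneous.

## Known limitations

* Loop-links, mono-links and protein-level inference are out of scope.
* The triangle bridging bound ignores steric exclusion by the protein
  bodies; it is necessary, not sufficient, on real structures.
* The tail sampler's excluded-volume model is a single hard radius; real
  tails have sequence-dependent stiffness and side-chain bulk.
* mmCIF input is not supported (PDB text only).
* The construct-mass utility computes unmodified average masses; real
  constructs may carry tags that shift apparent MW.
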