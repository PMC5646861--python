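"""Seeded synthetic-data generators for every downstream analysis.

The generators invert the models the analysis modules fit, so parameter
recovery can be tested end to end:

* titrations — peaks move by bound-fraction x per-residue maximal shift
  (fast exchange, exact 1:1 quadratic equilibrium), with independent
  Gaussian position noise per axis and optional exchange broadening
  modelled as peak deletion once the bound fraction crosses a per-residue
  cutoff;
* relaxation — mono-exponential decays I0*exp(-t/T) with additive Gaussian
  intensity noise on the standard T1/T2 delay grids;
* coordinate ensembles — a smoothed self-avoiding CA random walk with
  3.8 A spacing carrying N, CA, C, O backbone atoms, perturbed per model by
  small noise in the core and larger noise in designated flexible ranges
  (emulating disordered termini around a rigid folded core);
* motif-bearing sequences — random background with SUMOylation-consensus
  and SIM motifs planted at stated positions; the ground truth returned is
  a brute-force rescan of the final sequence, because random background can
  create extra legitimate hits.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidDesignError
from .ensemble import AtomRecord, StructureEnsemble
from .motifs import (
    PSI_DEFAULT,
    MotifHit,
    SequenceRecord,
    scan_sim,
    scan_sumo_consensus,
)
from .relaxation import T1_DELAYS, RelaxationSeries
from .titration import Peak, TitrationPoint, TitrationSeries, fraction_bound

AA_BACKGROUND = "ACDEFGHIKLMNPQRSTVWY"

# Default ligand:protein molar ratios.  Only the 1:5 endpoint is dictated by
# the experimental protocol being emulated; the intermediate steps are a
# package choice (see docs/methods.md).
DEFAULT_RATIOS = (0.0, 0.25, 0.5, 1.0, 2.0, 5.0)


@dataclass
class TitrationDesign:
    """Ground truth for a synthetic fast-exchange titration.

    ``interface_residues`` maps residue id -> (dH_max, dN_max) in ppm: the
    full free-to-bound displacement along each axis.  ``broadened_residues``
    maps residue id -> bound-fraction cutoff above which the residue's peak
    disappears from the list.
    """

    protein_total: float = 50.0  # uM
    ligand_ratios: Sequence[float] = DEFAULT_RATIOS
    true_kd: float = 31.0  # uM
    n_residues: int = 40
    interface_residues: Mapping[int, tuple[float, float]] = field(default_factory=dict)
    broadened_residues: Mapping[int, float] = field(default_factory=dict)
    noise_sd: float = 0.0  # ppm, per axis
    min_peak_separation: float = 0.5  # ppm, weighted distance between free peaks
    seed: int = 0

    def validate(self) -> None:
        r = list(self.ligand_ratios)
        if not r or r[0] != 0 or any(b <= a for a, b in zip(r, r[1:])):
            raise InvalidDesignError("ligand_ratios must start at 0 and be strictly increasing")
        if self.true_kd <= 0:
            raise InvalidDesignError("true_kd must be > 0")
        if self.protein_total <= 0:
            raise InvalidDesignError("protein_total must be > 0")
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be >= 0")
        all_res = set(range(1, self.n_residues + 1))
        if not set(self.interface_residues) <= all_res:
            raise InvalidDesignError("interface residues outside 1..n_residues")
        if not set(self.broadened_residues) <= all_res:
            raise InvalidDesignError("broadened residues outside 1..n_residues")


@dataclass
class RelaxationDesign:
    """Ground truth for synthetic mono-exponential relaxation decays."""

    delays: Sequence[float] = T1_DELAYS
    true_t: Mapping[int, float] = field(default_factory=lambda: {1: 0.45})  # s
    i0: Mapping[int, float] = field(default_factory=lambda: {1: 100.0})
    noise_sd: float = 0.0
    seed: int = 0
    kind: str = "T1"

    def validate(self) -> None:
        d = list(self.delays)
        if any(x < 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise InvalidDesignError("delays must be non-negative and strictly increasing")
        if any(t <= 0 for t in self.true_t.values()):
            raise InvalidDesignError("true T must be > 0")
        if set(self.true_t) != set(self.i0):
            raise InvalidDesignError("true_t and i0 must cover the same residues")
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be >= 0")


@dataclass
class EnsembleDesign:
    """Synthetic multi-model ensemble: rigid core, noisy flexible ranges."""

    n_models: int = 10
    n_residues: int = 60
    flexible_ranges: Sequence[tuple[int, int]] = ((1, 10), (51, 60))
    core_noise_sd: float = 0.3  # Angstrom
    tail_noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_models < 2:
            raise InvalidDesignError("n_models must be >= 2")
        if self.n_residues < 2:
            raise InvalidDesignError("n_residues must be >= 2")
        if not (self.tail_noise_sd >= self.core_noise_sd >= 0):
            raise InvalidDesignError("need tail_noise_sd >= core_noise_sd >= 0")
        for lo, hi in self.flexible_ranges:
            if lo < 1 or hi > self.n_residues or lo > hi:
                raise InvalidDesignError(f"flexible range ({lo},{hi}) outside chain")


def default_interface(seed: int = 0, n_interface: int = 8, n_residues: int = 40):
    """A plausible interface map: dH_max 0.05-0.25 ppm, dN_max 0.2-1.2 ppm."""
    rng = np.random.default_rng(seed)
    resids = sorted(rng.choice(np.arange(10, n_residues + 1), size=n_interface, replace=False))
    return {
        int(r): (float(rng.uniform(0.05, 0.25)), float(rng.uniform(0.2, 1.2)))
        for r in resids
    }


def gen_titration(design: TitrationDesign) -> TitrationSeries:
    """Synthesize Sparky-style peak lists over the design's titration.

    Free positions are drawn once per residue from the typical amide
    region (1H 7.0-10.0 ppm, 15N 103-133 ppm), rejection-sampled so that
    no two free peaks sit closer than ``min_peak_separation`` in the
    weighted shift distance — assigned peak lists come from resolved
    spectra, and downstream peak tracking assumes resolvable peaks.  At
    each titration point the interface residues are displaced by
    f_bound * (dH_max, dN_max) and all peaks get independent Gaussian
    jitter of ``noise_sd`` per axis.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    resids = list(range(1, design.n_residues + 1))
    free_h = np.empty(design.n_residues)
    free_n = np.empty(design.n_residues)
    for i in range(design.n_residues):
        for _attempt in range(1000):
            h = rng.uniform(7.0, 10.0)
            n = rng.uniform(103.0, 133.0)
            d = np.hypot(free_h[:i] - h, (free_n[:i] - n) / 5.0)
            if i == 0 or d.min() >= design.min_peak_separation:
                break
        else:
            raise InvalidDesignError(
                "could not place peaks with the requested minimum separation"
            )
        free_h[i], free_n[i] = h, n

    points = []
    for ratio in design.ligand_ratios:
        lt = ratio * design.protein_total
        fb = fraction_bound(design.protein_total, lt, design.true_kd) if lt > 0 else 0.0
        peaks = []
        for i, resid in enumerate(resids):
            cutoff = design.broadened_residues.get(resid)
            if cutoff is not None and fb > cutoff:
                continue
            dh_max, dn_max = design.interface_residues.get(resid, (0.0, 0.0))
            h = free_h[i] + fb * dh_max
            n = free_n[i] + fb * dn_max
            if design.noise_sd > 0:
                h += rng.normal(0.0, design.noise_sd)
                n += rng.normal(0.0, design.noise_sd)
            peaks.append(Peak(resid, float(h), float(n)))
        points.append(TitrationPoint(design.protein_total, lt, peaks))
    return TitrationSeries(points)


def gen_relaxation(design: RelaxationDesign) -> RelaxationSeries:
    """Mono-exponential decay tables I0*exp(-t/T) + N(0, noise_sd)."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    delays = tuple(float(t) for t in design.delays)
    t = np.array(delays)
    intensities = {}
    for resid in sorted(design.true_t):
        y = design.i0[resid] * np.exp(-t / design.true_t[resid])
        if design.noise_sd > 0:
            y = y + rng.normal(0.0, design.noise_sd, size=t.size)
        intensities[resid] = y
    return RelaxationSeries(
        kind=design.kind,
        intensities=intensities,
        delays=delays,
        noise_estimate=design.noise_sd,
    )


def _smoothed_walk(n: int, rng: np.random.Generator, step: float = 3.8) -> np.ndarray:
    """Self-avoiding smoothed random CA trace with fixed step length."""
    pts = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    for _ in range(n - 1):
        for _attempt in range(200):
            proposal = direction + 0.4 * rng.normal(size=3)
            proposal /= np.linalg.norm(proposal)
            cand = pts[-1] + step * proposal
            prior = np.array(pts[:-1]) if len(pts) > 1 else np.empty((0, 3))
            if prior.size == 0 or np.min(np.linalg.norm(prior - cand, axis=1)) > 0.9 * step:
                break
        pts.append(cand)
        direction = proposal
    return np.array(pts)


# Fixed local offsets (Angstrom) of the other backbone atoms relative to CA,
# expressed in the frame (chain direction e1, perpendicular e2, e1 x e2).
_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.8, 0.0]),
    "C": np.array([1.2, 0.7, 0.0]),
    "O": np.array([1.6, 1.8, 0.3]),
}


def gen_ensemble(design: EnsembleDesign) -> StructureEnsemble:
    """Build an ensemble around one base trace with per-region positional noise."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    ca = _smoothed_walk(design.n_residues, rng)

    atoms: list[AtomRecord] = []
    base: list[np.ndarray] = []
    for i in range(design.n_residues):
        nxt = ca[min(i + 1, design.n_residues - 1)]
        prv = ca[max(i - 1, 0)]
        e1 = nxt - prv
        e1 = e1 / (np.linalg.norm(e1) or 1.0)
        ref = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(e1, ref)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        frame = np.stack([e1, e2, e3], axis=1)
        for name in ("N", "CA", "C", "O"):
            atoms.append(AtomRecord(i + 1, "ALA", name))
            offset = np.zeros(3) if name == "CA" else frame @ _BACKBONE_OFFSETS[name]
            base.append(ca[i] + offset)
    base_arr = np.array(base)

    sigma = np.full(len(atoms), design.core_noise_sd)
    for lo, hi in design.flexible_ranges:
        for k, a in enumerate(atoms):
            if lo <= a.residue_id <= hi:
                sigma[k] = design.tail_noise_sd

    coords = np.empty((design.n_models, len(atoms), 3))
    for m in range(design.n_models):
        coords[m] = base_arr + rng.normal(size=base_arr.shape) * sigma[:, None]
    return StructureEnsemble(atoms, coords)


_MOTIF_TEMPLATES = {
    "sumo_consensus": 4,
    "sim": 9,
}


def gen_motif_sequence(
    length: int,
    planted: Sequence[tuple[int, str]] = (),
    seed: int = 0,
) -> tuple[SequenceRecord, list[MotifHit]]:
    """Random protein sequence with motifs planted at 1-based positions.

    Returns the sequence together with a ground-truth hit list obtained by
    rescanning the final string.  The background is uniform over the 20
    standard amino acids, so accidental extra hits next to (or away from)
    the planted sites are possible and intended: consumers should compare
    scanner output against a rescan of the returned sequence, not against
    the plant list alone.  Tests that need an independent oracle use their
    own brute-force window scan.
    """
    rng = np.random.default_rng(seed)
    seq = [AA_BACKGROUND[i] for i in rng.integers(0, len(AA_BACKGROUND), size=length)]

    spans = []
    for pos, kind in planted:
        if kind not in _MOTIF_TEMPLATES:
            raise InvalidDesignError(f"unknown motif kind {kind!r}")
        mlen = _MOTIF_TEMPLATES[kind]
        if pos < 1 or pos + mlen - 1 > length:
            raise InvalidDesignError(f"motif {kind} at {pos} does not fit in length {length}")
        spans.append((pos - 1, pos - 1 + mlen, kind))
    spans.sort()
    for (s0, e0, _), (s1, e1, _) in zip(spans, spans[1:]):
        if s1 < e0:
            raise InvalidDesignError("planted motifs overlap")

    for s0, e0, kind in spans:
        if kind == "sumo_consensus":
            psi = sorted(PSI_DEFAULT)[rng.integers(0, len(PSI_DEFAULT))]
            x = AA_BACKGROUND[rng.integers(0, len(AA_BACKGROUND))]
            motif = psi + "K" + x + "E"
        else:  # sim: hydrophobic core with acidic/serine flanks
            core = "".join(sorted("VIL")[rng.integers(0, 3)] for _ in range(4))
            motif = "DS" + core + "EDE"
        seq[s0:e0] = list(motif)

    record = SequenceRecord(f"synthetic_seed{seed}", "".join(seq))
    truth = scan_sumo_consensus(record) + scan_sim(record)
    return record, truth
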