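"""Structural-ensemble superposition, RMSD/RMSF statistics and NOE restraint classes.

An NMR structure is deposited as an ensemble of models.  Ensemble precision
is summarised, PSVS-style, as the RMSD of each model to the mean coordinates
after iterative superposition, over a stated residue range and atom class
(backbone = N, CA, C; heavy = all non-hydrogen).  Per-residue RMSF measures
local spread and exposes flexible termini.  Cross-structure comparison uses
sequence alignment to pair CA atoms, Kabsch superposition and iterative
outlier pruning.  NOE distance restraints are classified by sequence
separation: short |i-j| <= 1, medium 1 < |i-j| < 5, long |i-j| >= 5.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, SelectionError

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass(frozen=True)
class AtomRecord:
    residue_id: int
    residue_name: str
    atom_name: str


@dataclass
class StructureEnsemble:
    """Multi-model coordinates over a shared atom inventory.

    ``coords`` has shape (n_models, n_atoms, 3) in Angstrom, parallel to
    ``atoms``.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_ids(self) -> list[int]:
        seen = dict.fromkeys(a.residue_id for a in self.atoms)
        return list(seen)

    def select(
        self,
        residue_range: tuple[int, int] | None = None,
        atom_class: str = "backbone",
    ) -> np.ndarray:
        """Indices of atoms in the inclusive residue range and atom class."""
        if atom_class == "backbone":
            names = set(BACKBONE_ATOMS)
        elif atom_class == "ca":
            names = {"CA"}
        elif atom_class == "heavy":
            names = None  # hydrogens are already dropped on read
        else:
            raise ValueError(f"unknown atom class {atom_class!r}")
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if (names is None or a.atom_name in names)
            and (residue_range is None or residue_range[0] <= a.residue_id <= residue_range[1])
        ]
        if not idx:
            raise SelectionError(
                f"selection (range={residue_range}, class={atom_class}) matched no atoms"
            )
        return np.array(idx)

    def sequence(self) -> str:
        """One-letter sequence derived from the residue records."""
        import gemmi

        letters = []
        for resid in self.residue_ids:
            name = next(a.residue_name for a in self.atoms if a.residue_id == resid)
            info = gemmi.find_tabulated_residue(name)
            letters.append(info.one_letter_code.upper() if info else "X")
        return "".join(letters)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation applied to the moving set
    translation: np.ndarray  # applied after rotation, Angstrom
    rmsd: float
    n_pairs: int


@dataclass(frozen=True)
class DistanceRestraint:
    """One NOE-derived upper distance bound between two residues."""

    residue_i: int
    residue_j: int
    atom_i: str
    atom_j: str
    upper_bound: float  # Angstrom

    def __post_init__(self):
        if self.residue_i < 1 or self.residue_j < 1:
            raise ValueError("residue ids must be positive")
        if self.upper_bound <= 0:
            raise ValueError("upper bound must be positive")

    @property
    def separation_class(self) -> str:
        d = abs(self.residue_i - self.residue_j)
        if d <= 1:
            return "short"
        if d < 5:
            return "medium"
        return "long"


@dataclass
class EnsembleStats:
    mean_rmsd: float
    sd_rmsd: float
    min_rmsd: float
    max_rmsd: float
    per_model: np.ndarray


def kabsch(
    moving: np.ndarray,
    fixed: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal weighted rigid-body superposition of `moving` onto `fixed`.

    Minimises the weighted RMSD over proper rotations and translations;
    reflections are excluded.  Apply as ``moving @ R.T + t``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("moving and fixed must be matching (n, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()

    cm = wn @ moving
    cf = wn @ fixed
    m0 = moving - cm
    f0 = fixed - cf
    if np.linalg.matrix_rank(m0[w > 0], tol=1e-8) < 2:
        raise DegenerateGeometryError("moving points are collinear or coincident")

    rot, _ = Rotation.align_vectors(f0, m0, weights=w)
    R = rot.as_matrix()
    t = cf - R @ cm
    diff = (m0 @ R.T) - f0
    rmsd = float(np.sqrt((wn * (diff * diff).sum(axis=1)).sum()))
    return SuperpositionResult(R, t, rmsd, n)


def _superpose_to_mean(coords: np.ndarray, tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Iteratively superpose all models onto their mean until the mean converges."""
    work = coords.copy()
    mean = work[0].copy()
    for _ in range(max_iter):
        for m in range(work.shape[0]):
            res = kabsch(work[m], mean)
            work[m] = work[m] @ res.rotation.T + res.translation
        new_mean = work.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if shift < tol:
            break
    return work


def ensemble_stats(
    ensemble: StructureEnsemble,
    residue_range: tuple[int, int] | None = None,
    atom_class: str = "backbone",
) -> EnsembleStats:
    """Mean (+/-SD) (min..max) per-model RMSD to the mean coordinates.

    Models are iteratively superposed onto the evolving mean over the
    selection before the per-model RMSDs are measured.
    """
    if ensemble.n_models < 2:
        raise ValueError("need >= 2 models for ensemble statistics")
    idx = ensemble.select(residue_range, atom_class)
    work = _superpose_to_mean(ensemble.coords[:, idx, :])
    mean = work.mean(axis=0)
    per_model = np.sqrt(((work - mean) ** 2).sum(axis=2).mean(axis=1))
    return EnsembleStats(
        mean_rmsd=float(per_model.mean()),
        sd_rmsd=float(per_model.std(ddof=1)),
        min_rmsd=float(per_model.min()),
        max_rmsd=float(per_model.max()),
        per_model=per_model,
    )


def per_residue_rmsf(
    ensemble: StructureEnsemble,
    atom_class: str = "backbone",
    superpose_range: tuple[int, int] | None = None,
) -> dict[int, float]:
    """RMS fluctuation about the mean coordinates, per residue.

    Models are first superposed (over ``superpose_range``, default the whole
    chain) so that RMSF reports internal spread, not rigid-body scatter.
    RMSF_r = sqrt(mean over models and the residue's atoms of the squared
    deviation from the mean position).
    """
    idx = ensemble.select(superpose_range, atom_class)
    # Superpose full models using the (possibly core-restricted) selection.
    full = ensemble.coords.copy()
    sel = full[:, idx, :]
    mean = sel[0].copy()
    for _ in range(100):
        for m in range(full.shape[0]):
            res = kabsch(full[m, idx, :], mean)
            full[m] = full[m] @ res.rotation.T + res.translation
        new_mean = full[:, idx, :].mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if shift < 1e-6:
            break

    all_idx = ensemble.select(None, atom_class)
    mean_all = full[:, all_idx, :].mean(axis=0)
    sq_dev = ((full[:, all_idx, :] - mean_all) ** 2).sum(axis=2)  # models x atoms
    out: dict[int, float] = {}
    for resid in ensemble.residue_ids:
        cols = [k for k, i in enumerate(all_idx) if ensemble.atoms[i].residue_id == resid]
        if cols:
            out[resid] = float(np.sqrt(sq_dev[:, cols].mean()))
    return out


def align_superpose(
    a: StructureEnsemble,
    b: StructureEnsemble,
    prune_cutoff: float = 2.0,
    model_a: int = 0,
    model_b: int = 0,
    max_iter: int = 20,
) -> SuperpositionResult:
    """Sequence-alignment-guided CA superposition of model ``model_a`` of `a` onto `b`.

    A global sequence alignment pairs CA atoms; after an initial Kabsch
    fit, pairs deviating more than (current RMSD + ``prune_cutoff``) are
    removed and the fit repeated until the pair set is stable, so a locally
    displaced loop does not inflate the core RMSD.
    """
    from .motifs import SequenceRecord, global_align

    aln = global_align(SequenceRecord("a", a.sequence()), SequenceRecord("b", b.sequence()))
    resids_a = a.residue_ids
    resids_b = b.residue_ids
    ca_a = {rec.residue_id: i for i, rec in enumerate(a.atoms) if rec.atom_name == "CA"}
    ca_b = {rec.residue_id: i for i, rec in enumerate(b.atoms) if rec.atom_name == "CA"}

    pairs = []
    ia = ib = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            ra, rb = resids_a[ia], resids_b[ib]
            if ra in ca_a and rb in ca_b:
                pairs.append((ca_a[ra], ca_b[rb]))
        ia += ca != "-"
        ib += cb != "-"
    if len(pairs) < 3:
        raise DegenerateGeometryError(f"only {len(pairs)} aligned CA pairs")

    keep = np.arange(len(pairs))
    xa = np.array([a.coords[model_a, i] for i, _ in pairs])
    xb = np.array([b.coords[model_b, j] for _, j in pairs])
    result = kabsch(xa, xb)
    for _ in range(max_iter):
        moved = xa[keep] @ result.rotation.T + result.translation
        dev = np.linalg.norm(moved - xb[keep], axis=1)
        new_keep = keep[dev <= result.rmsd + prune_cutoff]
        if len(new_keep) < 3:
            raise DegenerateGeometryError(
                f"pruning left {len(new_keep)} pairs (< 3); structures may be unrelated"
            )
        if len(new_keep) == len(keep):
            break
        keep = new_keep
        result = kabsch(xa[keep], xb[keep])
    return SuperpositionResult(result.rotation, result.translation, result.rmsd, len(keep))


def classify_restraints(restraints: Iterable[DistanceRestraint]) -> dict[str, int]:
    """Count restraints per sequence-separation class; includes the total."""
    counts = Counter(r.separation_class for r in restraints)
    out = {"short": counts.get("short", 0), "medium": counts.get("medium", 0),
           "long": counts.get("long", 0)}
    out["total"] = sum(out.values())
    return out
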