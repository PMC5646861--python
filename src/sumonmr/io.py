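"""Readers and writers for the text formats the pipeline consumes and produces.

Formats
-------
* Sparky-style peak lists: ``<Res><Num>N-H  <w1 ppm (15N)>  <w2 ppm (1H)>
  [height]``, one line per assigned amide; ``#`` starts a comment.  ppm
  values are written with 3 decimals.
* Titration manifest: CSV with columns ``path, protein_total, ligand_total``
  (uM); the first entry must be the zero-ligand reference.
* Relaxation tables: CSV, residues in rows; decay tables have one column
  per delay (header = delay in seconds), hetNOE tables have columns
  ``sat, unsat``.
* Multi-model PDB (MODEL/ENDMDL) via gemmi; hydrogens and alternate
  locations are dropped on read, and model inventories are reconciled by
  intersection with a warning.
* Distance restraints: whitespace-separated
  ``resid1 resname1 atom1 resid2 resname2 atom2 upper_A`` (CYANA .upl
  column layout).
* FASTA via Biopython.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import AtomRecord, DistanceRestraint, StructureEnsemble
from .errors import ParseError
from .motifs import SequenceRecord
from .relaxation import RelaxationSeries
from .titration import Peak, TitrationPoint, TitrationSeries

logger = logging.getLogger(__name__)

_PEAK_RE = re.compile(r"^([A-Z])(\d+)N-H$")


@dataclass
class RunConfig:
    """All tunable thresholds, with the package's documented defaults.

    The config is serialized into every report for provenance; re-running
    from an embedded config reproduces deterministic outputs exactly.
    """

    seed: int = 0
    peak_match_gate: float = 0.15  # ppm, weighted distance
    interface_sd_multiplier: float = 2.0
    interface_sd_ddof: int = 0  # population SD
    bootstrap_resamples: int = 500
    hetnoe_flexible_cutoff: float = 0.5
    prune_cutoff: float = 2.0  # Angstrom, superposition outlier pruning
    identity_denominator: str = "alignment"
    ligand_ratios: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 5.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ligand_ratios"] = list(d["ligand_ratios"])
        return d

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value TOML file; keyword overrides win over the file."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "ligand_ratios" in data:
            data["ligand_ratios"] = tuple(data["ligand_ratios"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Sparky peak lists


def read_peaklist(path: str | Path) -> list[Peak]:
    peaks: list[Peak] = []
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line or line.lower().startswith("assignment"):
                continue
            fields = line.split()
            if len(fields) not in (3, 4):
                raise ParseError(f"expected 3 or 4 fields, got {len(fields)}", lineno)
            m = _PEAK_RE.match(fields[0])
            if not m:
                raise ParseError(f"malformed assignment {fields[0]!r}", lineno)
            resid = int(m.group(2))
            if resid in seen:
                raise ParseError(f"duplicate residue {resid}", lineno)
            seen.add(resid)
            try:
                w1 = float(fields[1])  # 15N
                w2 = float(fields[2])  # 1H
                height = float(fields[3]) if len(fields) == 4 else None
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
            peaks.append(Peak(resid, delta_h=w2, delta_n=w1, intensity=height))
    if not peaks:
        logger.warning("peak list %s is empty", path)
    return peaks


def write_peaklist(path: str | Path, peaks: list[Peak], residue_letter: str = "X") -> None:
    with open(path, "w") as fh:
        fh.write("# Assignment  w1(15N)  w2(1H)  [height]\n")
        for p in sorted(peaks, key=lambda p: p.residue_id):
            line = f"{residue_letter}{p.residue_id}N-H  {p.delta_n:.3f}  {p.delta_h:.3f}"
            if p.intensity is not None:
                line += f"  {p.intensity:.3f}"
            fh.write(line + "\n")


def read_manifest(path: str | Path) -> TitrationSeries:
    """Read a titration manifest CSV and the peak lists it names."""
    df = pd.read_csv(path)
    required = {"path", "protein_total", "ligand_total"}
    if not required <= set(df.columns):
        raise ParseError(f"manifest needs columns {sorted(required)}")
    base = Path(path).parent
    points = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        peaks = read_peaklist(p)
        points.append(
            TitrationPoint(float(row["protein_total"]), float(row["ligand_total"]), peaks)
        )
    return TitrationSeries(points)


def write_titration(
    directory: str | Path, series: TitrationSeries, prefix: str = "point"
) -> Path:
    """Write each point as a peak list plus a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, point in enumerate(series.points):
        name = f"{prefix}_{i:02d}.list"
        write_peaklist(directory / name, point.peaks)
        rows.append({"path": name, "protein_total": point.protein_total,
                     "ligand_total": point.ligand_total})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# Relaxation tables


def write_relaxation_csv(path: str | Path, series: RelaxationSeries) -> None:
    if series.kind == "hetNOE":
        df = pd.DataFrame(
            {
                "residue": sorted(series.intensities),
                "sat": [series.intensities[r][0] for r in sorted(series.intensities)],
                "unsat": [series.intensities[r][1] for r in sorted(series.intensities)],
            }
        )
    else:
        df = pd.DataFrame(
            [series.intensities[r] for r in sorted(series.intensities)],
            index=pd.Index(sorted(series.intensities), name="residue"),
            columns=[str(d) for d in series.delays],
        ).reset_index()
    df.to_csv(path, index=False)


def read_relaxation_csv(
    path: str | Path, kind: str, noise_estimate: float = 0.0
) -> RelaxationSeries:
    df = pd.read_csv(path)
    if "residue" not in df.columns:
        raise ParseError("relaxation table needs a 'residue' column")
    if kind == "hetNOE":
        if not {"sat", "unsat"} <= set(df.columns):
            raise ParseError("hetNOE table needs 'sat' and 'unsat' columns")
        intensities = {
            int(r.residue): np.array([r.sat, r.unsat]) for r in df.itertuples()
        }
        return RelaxationSeries(kind, intensities, noise_estimate=noise_estimate)
    delay_cols = [c for c in df.columns if c != "residue"]
    delays = tuple(float(c) for c in delay_cols)
    intensities = {
        int(row["residue"]): row[delay_cols].to_numpy(dtype=float)
        for _, row in df.iterrows()
    }
    return RelaxationSeries(kind, intensities, delays=delays, noise_estimate=noise_estimate)


# ---------------------------------------------------------------------------
# Multi-model PDB


def read_ensemble_pdb(path: str | Path) -> StructureEnsemble:
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")

    per_model: list[dict[tuple, np.ndarray]] = []
    for model in st:
        inventory: dict[tuple, np.ndarray] = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    key = (res.seqid.num, res.name, atom.name)
                    inventory[key] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        per_model.append(inventory)
    if not per_model or not per_model[0]:
        raise ParseError(f"{path}: no ATOM records")

    common = set(per_model[0])
    for inv in per_model[1:]:
        common &= set(inv)
    if any(len(inv) != len(common) for inv in per_model):
        logger.warning(
            "%s: models differ in atom inventory; using the %d common atoms",
            path,
            len(common),
        )
    if not common:
        raise ParseError(f"{path}: models share no atoms")
    keys = [k for k in per_model[0] if k in common]  # keep first-model atom order
    atoms = [AtomRecord(k[0], k[1], k[2]) for k in keys]
    coords = np.array([[inv[k] for k in keys] for inv in per_model])
    return StructureEnsemble(atoms, coords)


def write_ensemble_pdb(path: str | Path, ensemble: StructureEnsemble) -> None:
    import gemmi

    st = gemmi.Structure()
    for m in range(ensemble.n_models):
        model = gemmi.Model(m + 1)
        chain = gemmi.Chain("A")
        current_res = None
        for a, xyz in zip(ensemble.atoms, ensemble.coords[m]):
            if current_res is None or current_res.seqid.num != a.residue_id:
                current_res = gemmi.Residue()
                current_res.name = a.residue_name
                current_res.seqid = gemmi.SeqId(a.residue_id, " ")
                chain.add_residue(current_res)
                current_res = chain[-1]
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.element = gemmi.Element(a.atom_name[0])
            atom.pos = gemmi.Position(*xyz)
            current_res.add_atom(atom)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Distance restraints (CYANA .upl column layout)


def read_restraints(path: str | Path) -> list[DistanceRestraint]:
    restraints = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 7:
                raise ParseError(f"expected 7 columns, got {len(fields)}", lineno)
            try:
                restraints.append(
                    DistanceRestraint(
                        residue_i=int(fields[0]),
                        residue_j=int(fields[3]),
                        atom_i=fields[2],
                        atom_j=fields[5],
                        upper_bound=float(fields[6]),
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
    return restraints


def write_restraints(path: str | Path, restraints: list[DistanceRestraint]) -> None:
    with open(path, "w") as fh:
        for r in restraints:
            fh.write(
                f"{r.residue_i:>4d} ALA  {r.atom_i:<4s} {r.residue_j:>4d} ALA  "
                f"{r.atom_j:<4s} {r.upper_bound:6.2f}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    from Bio import SeqIO

    return [
        SequenceRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: str | Path, records: list[SequenceRecord]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord as BioSeqRecord
    from Bio import SeqIO

    SeqIO.write(
        [BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def write_motif_hits(path: str | Path, seq_id: str, hits) -> None:
    """Tab-separated hit list; coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("# columns: sequence_id\tstart\tend\tkind\tmatched_text (1-based inclusive)\n")
        for h in hits:
            fh.write(f"{seq_id}\t{h.start}\t{h.end}\t{h.kind}\t{h.matched_text}\n")


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
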