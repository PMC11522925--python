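"""Shared data model and file I/O.

The package operates on three core objects:

``MolecularSystem``
    A topology (atoms with charges and Lennard-Jones parameters) annotated
    with the catalytic machinery of a serine hydrolase -- the triad serine's
    gamma-oxygen, the two oxyanion-hole amide hydrogens -- and the polymer
    chain's repeat units and ester-bond atom triplets.

``Trajectory``
    Frames x atoms x 3 coordinates with optional orthorhombic box, per-frame
    time stamps, and optional replica index / statistical weight per frame
    (for pooled replica-exchange ensembles).

``AnalysisConfig``
    The tunable distance and energy thresholds used throughout the pipeline.

Supported on-disk formats: PDB for topologies, multi-model PDB or a plain
whitespace frame table for trajectories, and a TSV table for nonbonded
parameters.  Coordinates are Angstrom everywhere; energies kcal/mol; free
energies are converted to kJ/mol only at the free-energy-surface stage.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

__all__ = [
    "MolecularSystem",
    "Trajectory",
    "AnalysisConfig",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_parameter_table",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Distance/energy thresholds and physical constants for every stage.

    Defaults follow the study conditions: residue-polymer contacts within
    3 A held for 75% of the time, proximal/distal split at 12 A from the
    catalytic serine, productive poses at <=4 A, entry outer boundary 6 A,
    pathway-PCA feature radius 10 A, binding-onset energy threshold
    -10 kcal/mol, temperature 303 K.
    """

    contact_cutoff: float = 3.0          # A
    persistence_fraction: float = 0.75
    proximal_radius: float = 12.0        # A
    productive_cutoff: float = 4.0       # A
    outer_boundary: float = 6.0          # A
    pca_radius: float = 10.0             # A
    binding_energy_threshold: float = -10.0  # kcal/mol
    temperature: float = 303.0           # K
    coulomb_constant: float = 332.0636   # kcal*A/(mol*e^2)
    nonbonded_cutoff: float = 12.0       # A
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "proximal_radius", "productive_cutoff",
                     "outer_boundary", "pca_radius", "nonbonded_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.persistence_fraction <= 1.0):
            raise ValueError("persistence_fraction must lie in (0, 1]")
        if self.productive_cutoff >= self.outer_boundary:
            raise ValueError("productive_cutoff must be smaller than outer_boundary")


@dataclass
class MolecularSystem:
    """Annotated topology of one enzyme + polymer system.

    Atom arrays are index-aligned; ``atom_id`` holds the (unique) PDB
    serials.  ``segment`` is ``"enzyme"`` or ``"polymer"`` per atom.
    Charges are in e, Lennard-Jones sigma in A, epsilon in kcal/mol; when no
    parameter table was supplied they are zero and ``params_present`` is
    False.
    """

    atom_id: np.ndarray          # (n,) int
    name: np.ndarray             # (n,) str
    element: np.ndarray          # (n,) str
    charge: np.ndarray           # (n,) float, e
    lj_sigma: np.ndarray         # (n,) float, A
    lj_epsilon: np.ndarray       # (n,) float, kcal/mol
    residue_index: np.ndarray    # (n,) int, author numbering as read
    residue_name: np.ndarray     # (n,) str
    segment: np.ndarray          # (n,) str: enzyme | polymer

    serine_ogamma: int           # atom id of the catalytic Ser gamma-oxygen
    histidine_residue: int
    aspartate_residue: int
    oxyanion_donors: tuple[int, int]        # two amide-H atom ids
    polymer_units: list[np.ndarray]         # ordered atom-id sets
    ester_bonds: list[tuple[int, int, int]]  # (carbonyl C, carbonyl O, ester O)

    params_present: bool = False
    serine_name: str = "SER"

    def __post_init__(self) -> None:
        self._id_to_index = {int(a): i for i, a in enumerate(self.atom_id)}
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        ids = self.atom_id
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate atom ids in topology")
        poly = set(ids[self.segment == "polymer"].tolist())
        enz = set(ids[self.segment == "enzyme"].tolist())
        for c, o, oe in self.ester_bonds:
            for a in (c, o, oe):
                if a not in self._id_to_index:
                    raise ValueError(f"ester-bond atom id {a} not in topology")
                if a not in poly:
                    raise ValueError(f"ester-bond atom id {a} is not a polymer atom")
        for h in self.oxyanion_donors:
            if h not in self._id_to_index:
                raise ValueError(f"oxyanion donor atom id {h} not in topology")
            if h not in enz:
                raise ValueError(f"oxyanion donor atom id {h} is not an enzyme atom")
        seen: set[int] = set()
        for unit in self.polymer_units:
            u = set(int(a) for a in unit)
            if u & seen:
                raise ValueError("polymer units are not disjoint")
            seen |= u
        i = self.index_of(self.serine_ogamma)
        if self.residue_name[i] != self.serine_name:
            raise ValueError(
                f"serine gamma-oxygen atom {self.serine_ogamma} sits in residue "
                f"{self.residue_name[i]}, expected {self.serine_name}")

    # -- helpers -----------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    def index_of(self, atom_id: int) -> int:
        """Array index of an atom id."""
        try:
            return self._id_to_index[int(atom_id)]
        except KeyError:
            raise KeyError(f"atom id {atom_id} not in topology") from None

    def indices_of(self, atom_ids: Sequence[int]) -> np.ndarray:
        return np.array([self.index_of(a) for a in atom_ids], dtype=int)

    @property
    def enzyme_mask(self) -> np.ndarray:
        return self.segment == "enzyme"

    @property
    def polymer_mask(self) -> np.ndarray:
        return self.segment == "polymer"

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def enzyme_residues(self) -> np.ndarray:
        """Sorted unique enzyme residue indices."""
        return np.unique(self.residue_index[self.enzyme_mask])

    def residue_atom_indices(self, residue: int, heavy_only: bool = False,
                             segment: str = "enzyme") -> np.ndarray:
        m = (self.residue_index == residue) & (self.segment == segment)
        if heavy_only:
            m &= self.heavy_mask
        return np.where(m)[0]

    def residue_name_of(self, residue: int) -> str:
        m = self.residue_index == residue
        if not m.any():
            raise KeyError(f"residue {residue} not in topology")
        return str(self.residue_name[m][0])


@dataclass
class Trajectory:
    """Coordinate frames for one system.

    ``coordinates`` is (n_frames, n_atoms, 3) in A.  ``box`` is per-frame
    orthorhombic edge lengths or None (free space).  ``frame_weight``
    defaults to 1 per frame; ``replica_index`` is optional.
    """

    coordinates: np.ndarray
    time: np.ndarray                       # ns, strictly increasing
    box: np.ndarray | None = None          # (n_frames, 3) or None
    replica_index: np.ndarray | None = None
    frame_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        self.time = np.asarray(self.time, dtype=float)
        if len(self.time) != self.n_frames:
            raise ValueError("time length does not match frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.frame_weight is None:
            self.frame_weight = np.ones(self.n_frames)
        else:
            self.frame_weight = np.asarray(self.frame_weight, dtype=float)
            if np.any(self.frame_weight < 0) or not np.any(self.frame_weight > 0):
                raise ValueError("frame weights must be >= 0 with at least one > 0")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")
        if self.replica_index is not None:
            self.replica_index = np.asarray(self.replica_index, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame_box(self, f: int) -> np.ndarray | None:
        return None if self.box is None else self.box[f]

    def check_system(self, system: MolecularSystem) -> None:
        if self.n_atoms != system.n_atoms:
            raise ValueError(
                f"trajectory has {self.n_atoms} atoms but system has {system.n_atoms}")


# --------------------------------------------------------------------------
# topology I/O
# --------------------------------------------------------------------------

_GUESS_ELEMENTS = {"OG": "O", "HN": "H"}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name in _GUESS_ELEMENTS:
        return _GUESS_ELEMENTS[name]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read a nonbonded parameter TSV.

    Columns: atom_name, residue_name, charge (e), sigma (A),
    epsilon (kcal/mol).  Matching is by (residue_name, atom_name).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"atom_name", "residue_name", "charge", "sigma", "epsilon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return df


def read_topology(path: str | Path, annotations: Mapping,
                  parameters: pd.DataFrame | str | Path | None = None) -> MolecularSystem:
    """Read a PDB topology and attach catalytic-site / polymer annotations.

    ``annotations`` is a mapping with keys:

    - ``polymer_chains``: list of chain ids forming the polymer segment
      (all other chains are the enzyme);
    - ``serine``: ``{"residue": int, "atom": str}`` naming the catalytic
      serine gamma-oxygen (atom defaults to ``"OG"``);
    - ``histidine_residue`` / ``aspartate_residue``: triad residue indices;
    - ``oxyanion_donors``: two ``{"residue": int, "atom": str}`` entries for
      the amide hydrogens of the oxyanion hole;
    - ``ester_template``: ``{"carbon": str, "carbonyl_oxygen": str,
      "ester_oxygen": str}`` atom names matched per polymer residue to
      derive the ester triplets, or ``ester_bonds`` as explicit id triplets;
    - optional ``serine_name``: residue-name override for the serine check.

    Polymer units default to one unit per polymer residue.  When
    ``parameters`` is None, charges and LJ parameters are zero and the
    system is flagged ``params_present=False``.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("topology", str(path))
    model = next(structure.get_models())
    polymer_chains = set(annotations.get("polymer_chains", []))

    ids, names, elements, resids, resnames, segments, coords = [], [], [], [], [], [], []
    for chain in model:
        seg = "polymer" if chain.id in polymer_chains else "enzyme"
        for residue in chain:
            for atom in residue:
                ids.append(atom.serial_number)
                names.append(atom.get_name())
                el = (atom.element or "").strip()
                elements.append(el if el else _guess_element(atom.get_name()))
                resids.append(residue.id[1])
                resnames.append(residue.get_resname())
                segments.append(seg)
                coords.append(atom.coord)
    ids = np.asarray(ids, dtype=int)
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"duplicate atom serials in {path}")
    names = np.asarray(names)
    resids_arr = np.asarray(resids, dtype=int)
    resnames_arr = np.asarray(resnames)
    segments_arr = np.asarray(segments)

    def _find_atom(residue: int, atom: str, segment: str) -> int:
        m = (resids_arr == residue) & (names == atom) & (segments_arr == segment)
        hits = ids[m]
        if len(hits) == 0:
            raise ValueError(f"{atom} atom not found in {segment} residue {residue}")
        return int(hits[0])

    ser = annotations["serine"]
    ser_id = _find_atom(int(ser["residue"]), ser.get("atom", "OG"), "enzyme")
    donors = []
    for d in annotations["oxyanion_donors"]:
        donors.append(_find_atom(int(d["residue"]), d.get("atom", "HN"), "enzyme"))
    if len(donors) != 2:
        raise ValueError("exactly two oxyanion donors required")

    # polymer units: one per polymer residue, chain order
    poly_mask = segments_arr == "polymer"
    units = []
    for r in pd.unique(resids_arr[poly_mask]):
        units.append(ids[poly_mask & (resids_arr == r)])

    if "ester_bonds" in annotations:
        esters = [tuple(int(a) for a in t) for t in annotations["ester_bonds"]]
    else:
        tpl = annotations["ester_template"]
        esters = []
        for r in pd.unique(resids_arr[poly_mask]):
            m = poly_mask & (resids_arr == r)
            names_r = names[m]
            if tpl["carbon"] in names_r:
                esters.append((
                    _find_atom(int(r), tpl["carbon"], "polymer"),
                    _find_atom(int(r), tpl["carbonyl_oxygen"], "polymer"),
                    _find_atom(int(r), tpl["ester_oxygen"], "polymer"),
                ))
        if not esters:
            raise ValueError("ester template matched no polymer residue")

    charge = np.zeros(len(ids))
    sigma = np.zeros(len(ids))
    eps = np.zeros(len(ids))
    params_present = False
    if parameters is not None:
        if not isinstance(parameters, pd.DataFrame):
            parameters = read_parameter_table(parameters)
        lookup = {(row.residue_name, row.atom_name): (row.charge, row.sigma, row.epsilon)
                  for row in parameters.itertuples()}
        for i in range(len(ids)):
            key = (str(resnames_arr[i]), str(names[i]))
            if key in lookup:
                charge[i], sigma[i], eps[i] = lookup[key]
            else:
                warnings.warn(f"no nonbonded parameters for {key}; using zeros")
        params_present = True

    system = MolecularSystem(
        atom_id=ids, name=names, element=np.asarray(elements),
        charge=charge, lj_sigma=sigma, lj_epsilon=eps,
        residue_index=resids_arr, residue_name=resnames_arr, segment=segments_arr,
        serine_ogamma=ser_id,
        histidine_residue=int(annotations.get("histidine_residue", -1)),
        aspartate_residue=int(annotations.get("aspartate_residue", -1)),
        oxyanion_donors=(donors[0], donors[1]),
        polymer_units=units,
        ester_bonds=esters,
        params_present=params_present,
        serine_name=annotations.get("serine_name", "SER"),
    )
    system.reference_coordinates = np.asarray(coords, dtype=float)  # type: ignore[attr-defined]
    return system


_PDB_ATOM = ("ATOM  {serial:>5d} {name:<4s}{alt:1s}{resn:<3s} {chain:1s}{resi:>4d}"
             "{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n")


def _format_atom_name(name: str) -> str:
    # PDB convention: single-letter elements start in column 14
    return f" {name:<3s}" if len(name) < 4 else name


def _write_pdb_frame(fh: io.TextIOBase, system: MolecularSystem, coords: np.ndarray,
                     chain_of_segment: Mapping[str, str]) -> None:
    for i in range(system.n_atoms):
        fh.write(_PDB_ATOM.format(
            serial=int(system.atom_id[i]),
            name=_format_atom_name(str(system.name[i])),
            alt=" ", resn=str(system.residue_name[i]),
            chain=chain_of_segment[str(system.segment[i])],
            resi=int(system.residue_index[i]), icode=" ",
            x=coords[i, 0], y=coords[i, 1], z=coords[i, 2],
            occ=1.0, b=0.0, el=str(system.element[i])))
    fh.write("TER\n")


def write_topology(path: str | Path, system: MolecularSystem, coordinates: np.ndarray,
                   enzyme_chain: str = "A", polymer_chain: str = "P") -> None:
    """Write a single-model PDB of the system at the given coordinates."""
    chains = {"enzyme": enzyme_chain, "polymer": polymer_chain}
    with open(path, "w") as fh:
        _write_pdb_frame(fh, system, np.asarray(coordinates, float), chains)
        fh.write("END\n")


# --------------------------------------------------------------------------
# trajectory I/O
# --------------------------------------------------------------------------

def read_trajectory(path: str | Path, system: MolecularSystem,
                    dialect: str = "frame-table") -> Trajectory:
    """Read a trajectory in either supported dialect.

    ``dialect`` is ``"multi-model-pdb"`` or ``"frame-table"`` (the internal
    plain-text format; see :func:`write_trajectory`).
    """
    if dialect == "multi-model-pdb":
        traj = _read_multimodel_pdb(path, system)
    elif dialect == "frame-table":
        traj = _read_frame_table(path, system)
    else:
        raise ValueError(f"unknown trajectory dialect: {dialect!r}")
    traj.check_system(system)
    return traj


def _read_multimodel_pdb(path: str | Path, system: MolecularSystem) -> Trajectory:
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames = []
    for f, model in enumerate(structure.get_models()):
        coords = np.array([atom.coord for atom in model.get_atoms()], dtype=float)
        if coords.shape[0] != system.n_atoms:
            raise ValueError(
                f"frame {f}: atom count {coords.shape[0]} does not match "
                f"system ({system.n_atoms})")
        frames.append(coords)
    coords = np.stack(frames)
    return Trajectory(coordinates=coords, time=np.arange(len(frames), dtype=float))


_FRAME_TABLE_COLUMNS = ["frame", "time", "atom", "x", "y", "z",
                        "box_x", "box_y", "box_z", "replica", "weight"]


def _read_frame_table(path: str | Path, system: MolecularSystem) -> Trajectory:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("frame-table must start with a '#'-prefixed header line")
        cols = header[1:].split()
        unknown = set(cols) - set(_FRAME_TABLE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown frame-table columns: {sorted(unknown)}")
        df = pd.read_csv(fh, sep=r"\s+", names=cols, header=None)

    n_atoms = system.n_atoms
    frame_ids = df["frame"].to_numpy()
    unique_frames = pd.unique(frame_ids)
    n_frames = len(unique_frames)
    if len(df) != n_frames * n_atoms:
        counts = df.groupby("frame").size()
        bad = counts[counts != n_atoms]
        f = int(bad.index[0]) if len(bad) else -1
        raise ValueError(
            f"frame {f}: atom count {int(bad.iloc[0]) if len(bad) else len(df)} "
            f"does not match system ({n_atoms})")

    coords = df[["x", "y", "z"]].to_numpy().reshape(n_frames, n_atoms, 3)
    per_frame = df.iloc[::n_atoms]
    time = per_frame["time"].to_numpy(dtype=float)
    if n_frames > 1 and not np.all(np.diff(time) > 0):
        raise ValueError("non-increasing time in frame-table")
    box = None
    if "box_x" in df.columns:
        box = per_frame[["box_x", "box_y", "box_z"]].to_numpy(dtype=float)
    replica = per_frame["replica"].to_numpy(dtype=int) if "replica" in df.columns else None
    weight = per_frame["weight"].to_numpy(dtype=float) if "weight" in df.columns else None
    return Trajectory(coordinates=coords, time=time, box=box,
                      replica_index=replica, frame_weight=weight)


def write_trajectory(path: str | Path, traj: Trajectory, system: MolecularSystem,
                     dialect: str = "frame-table",
                     enzyme_chain: str = "A", polymer_chain: str = "P") -> None:
    """Write a trajectory (frame-table with 4-decimal coordinates, or
    multi-model PDB)."""
    traj.check_system(system)
    if dialect == "multi-model-pdb":
        chains = {"enzyme": enzyme_chain, "polymer": polymer_chain}
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"MODEL     {f + 1:>4d}\n")
                _write_pdb_frame(fh, system, traj.coordinates[f], chains)
                fh.write("ENDMDL\n")
            fh.write("END\n")
        return
    if dialect != "frame-table":
        raise ValueError(f"unknown trajectory dialect: {dialect!r}")

    cols = ["frame", "time", "atom", "x", "y", "z"]
    if traj.box is not None:
        cols += ["box_x", "box_y", "box_z"]
    if traj.replica_index is not None:
        cols.append("replica")
    cols.append("weight")
    with open(path, "w") as fh:
        fh.write("#" + " ".join(cols) + "\n")
        for f in range(traj.n_frames):
            for i in range(traj.n_atoms):
                parts = [str(f), f"{traj.time[f]:.6g}", str(int(system.atom_id[i]))]
                parts += [f"{traj.coordinates[f, i, k]:.4f}" for k in range(3)]
                if traj.box is not None:
                    parts += [f"{traj.box[f, k]:.4f}" for k in range(3)]
                if traj.replica_index is not None:
                    parts.append(str(int(traj.replica_index[f])))
                parts.append(f"{traj.frame_weight[f]:.6g}")
                fh.write(" ".join(parts) + "\n")


def concatenate(trajs: Sequence[Trajectory]) -> Trajectory:
    """Concatenate trajectories, re-basing times to stay strictly increasing."""
    coords = np.concatenate([t.coordinates for t in trajs])
    times, offset = [], 0.0
    for t in trajs:
        times.append(t.time + offset)
        dt = t.time[-1] - t.time[0] if t.n_frames > 1 else 1.0
        offset = times[-1][-1] + (dt / max(t.n_frames - 1, 1) if t.n_frames > 1 else 1.0)
    box = None
    if all(t.box is not None for t in trajs):
        box = np.concatenate([t.box for t in trajs])
    replica = None
    if all(t.replica_index is not None for t in trajs):
        replica = np.concatenate([t.replica_index for t in trajs])
    weight = np.concatenate([t.frame_weight for t in trajs])
    return Trajectory(coordinates=coords, time=np.concatenate(times), box=box,
                      replica_index=replica, frame_weight=weight)
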