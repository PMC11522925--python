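"""Pairwise nonbonded interaction energies and their aggregation.

The interaction energy between two atom groups is the truncated Coulomb
plus Lennard-Jones 12-6 sum over inter-group pairs within the nonbonded
cutoff:

    E = sum_{i in A, j in B, r_ij <= r_c} [ k q_i q_j / r_ij
        + 4 eps_ij ((sig_ij/r_ij)^12 - (sig_ij/r_ij)^6) ]

with Lorentz-Berthelot combination (arithmetic sigma, geometric epsilon),
minimum-image distances, dielectric 1 and no switching or long-range
correction.  Absolute values are therefore model energies; the pipeline
only consumes orderings and differences, which are robust to the
truncation scheme.  Units: kcal/mol throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._geom import minimum_image
from .model_io import AnalysisConfig, MolecularSystem, Trajectory

__all__ = ["EnergySeries", "pair_energy", "residue_energy_series", "class_profile",
           "ClassProfile", "pet_internal_energy", "binding_onset", "site_delta_eint",
           "DEFAULT_CLASS_MAP"]


# Physicochemical classes over the 20 amino acids; histidine counted as
# charged by default (overridable via the class_map argument).
DEFAULT_CLASS_MAP: dict[str, str] = {
    **{aa: "apolar" for aa in ("ALA", "VAL", "LEU", "ILE", "MET", "GLY", "PRO", "CYS")},
    **{aa: "polar" for aa in ("SER", "THR", "ASN", "GLN")},
    **{aa: "charged" for aa in ("ASP", "GLU", "LYS", "ARG", "HIS")},
    **{aa: "aromatic" for aa in ("PHE", "TYR", "TRP")},
}


@dataclass
class EnergySeries:
    """Per-frame Coulomb/LJ energy between two groups, with frame weights."""

    coulomb: np.ndarray        # (F,) kcal/mol
    lj: np.ndarray             # (F,) kcal/mol
    weights: np.ndarray        # (F,)
    group_a: str = ""
    group_b: str = ""

    @property
    def total(self) -> np.ndarray:
        return self.coulomb + self.lj

    def weighted_mean(self) -> float:
        w = self.weights / self.weights.sum()
        return float(self.total @ w)


def pair_energy(coords: np.ndarray, group_a: np.ndarray, group_b: np.ndarray,
                system: MolecularSystem, config: AnalysisConfig,
                box: np.ndarray | None = None) -> tuple[float, float]:
    """Coulomb and LJ energy between two disjoint atom-index groups in one
    frame.

    Returns ``(coulomb, lj)`` in kcal/mol.  Raises on overlapping groups
    and on zero inter-atomic distances (clashing coordinates).
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("atom groups overlap")
    diff = coords[group_a][:, None, :] - coords[group_b][None, :, :]
    diff = minimum_image(diff, box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(r == 0):
        raise ValueError("zero inter-atomic distance (clashing coordinates)")
    within = r <= config.nonbonded_cutoff
    if not within.any():
        return 0.0, 0.0
    ia, ib = np.where(within)
    r = r[within]
    q = system.charge[group_a][ia] * system.charge[group_b][ib]
    coulomb = float(np.sum(config.coulomb_constant * q / r))
    sig = 0.5 * (system.lj_sigma[group_a][ia] + system.lj_sigma[group_b][ib])
    eps = np.sqrt(system.lj_epsilon[group_a][ia] * system.lj_epsilon[group_b][ib])
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(sig > 0, (sig / r) ** 6, 0.0)
    lj = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
    return coulomb, lj


def _series_over_frames(traj: Trajectory, system: MolecularSystem,
                        group_a: np.ndarray, group_b: np.ndarray,
                        config: AnalysisConfig, name_a: str, name_b: str) -> EnergySeries:
    coul = np.zeros(traj.n_frames)
    lj = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        coul[f], lj[f] = pair_energy(traj.coordinates[f], group_a, group_b,
                                     system, config, traj.frame_box(f))
    return EnergySeries(coulomb=coul, lj=lj, weights=traj.frame_weight.copy(),
                        group_a=name_a, group_b=name_b)


def residue_energy_series(traj: Trajectory, system: MolecularSystem,
                          config: AnalysisConfig) -> dict[int, EnergySeries]:
    """Interaction-energy series between each enzyme residue and the whole
    polymer."""
    traj.check_system(system)
    if not system.params_present:
        raise ValueError("system carries no nonbonded parameters; supply a parameter table")
    poly = np.where(system.polymer_mask)[0]
    out: dict[int, EnergySeries] = {}
    for r in system.enzyme_residues():
        idx = system.residue_atom_indices(int(r))
        out[int(r)] = _series_over_frames(traj, system, idx, poly, config,
                                          name_a=f"residue {r}", name_b="polymer")
    return out


@dataclass
class ClassProfile:
    """Scaled class-level interaction-energy profile.

    ``class_energy[c]`` = (sum of per-residue weighted-mean energies of
    contacting residues in class c) / (number of contacting residues in
    class c) -- i.e. energies scaled by the number of contacting residues
    of each class.
    """

    class_energy: dict[str, float]
    class_counts: dict[str, int]
    residue_means: dict[int, float]


def class_profile(series: Mapping[int, EnergySeries], contacts: Iterable[int],
                  system: MolecularSystem,
                  class_map: Mapping[str, str] | None = None) -> ClassProfile:
    """Aggregate per-residue mean energies into physicochemical classes,
    scaled by the number of contacting residues per class."""
    class_map = dict(class_map or DEFAULT_CLASS_MAP)
    contacts = set(int(c) for c in contacts)
    if not contacts:
        raise ValueError("empty contact set")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    means: dict[int, float] = {}
    for r in sorted(contacts):
        if r not in series:
            continue
        resn = system.residue_name_of(r)
        cls = class_map.get(resn)
        if cls is None:
            raise KeyError(f"residue name {resn} missing from class map")
        m = series[r].weighted_mean()
        means[r] = m
        sums[cls] = sums.get(cls, 0.0) + m
        counts[cls] = counts.get(cls, 0) + 1
    return ClassProfile(
        class_energy={c: sums[c] / counts[c] for c in sums},
        class_counts=counts, residue_means=means)


def pet_internal_energy(traj: Trajectory, system: MolecularSystem,
                        config: AnalysisConfig, pair: tuple[int, int]) -> EnergySeries:
    """Nonbonded energy between two non-adjacent polymer units (0-based
    indices into ``system.polymer_units``).

    Adjacent units share an ester bond, so their nonbonded energy is
    dominated by bonded neighbors and is excluded by precondition
    (|i - j| >= 2).
    """
    i, j = pair
    n = len(system.polymer_units)
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"unit index out of range (have {n} units)")
    if abs(i - j) < 2:
        raise ValueError("units must be non-adjacent (|i - j| >= 2)")
    a = system.indices_of(system.polymer_units[i])
    b = system.indices_of(system.polymer_units[j])
    return _series_over_frames(traj, system, a, b, config,
                               name_a=f"unit {i}", name_b=f"unit {j}")


def binding_onset(series: EnergySeries, time: np.ndarray,
                  threshold: float = -10.0) -> float | None:
    """Time of the first frame with total energy below ``threshold``
    (kcal/mol); None if never reached."""
    if threshold >= 0:
        raise ValueError("threshold must be negative")
    below = np.where(series.total < threshold)[0]
    return float(time[below[0]]) if len(below) else None


def site_delta_eint(parent: Mapping[int, EnergySeries],
                    variant: Mapping[int, EnergySeries],
                    sites: Sequence[int]) -> dict[int, dict[str, float]]:
    """Per-site weighted mean energies for parent and variant and their
    difference (variant - parent; positive = weakened binding)."""
    out: dict[int, dict[str, float]] = {}
    for s in sites:
        s = int(s)
        if s not in parent:
            raise KeyError(f"site {s} missing from parent system")
        if s not in variant:
            raise KeyError(f"site {s} missing from variant system")
        p = parent[s].weighted_mean()
        v = variant[s].weighted_mean()
        out[s] = {"parent": p, "variant": v, "delta": v - p}
    return out
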