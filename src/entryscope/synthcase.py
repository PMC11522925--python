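"""Synthetic fixtures with known ground truth.

Real microsecond enzyme-polymer trajectories cannot ship with a test
suite, so every analysis stage is exercised on generated data whose true
answer is known by construction:

- a *toy system*: a pseudo-enzyme Calpha shell with a serine site
  (gamma-oxygen bead flanked by two oxyanion-hole hydrogen beads) and a
  polymer bead chain carrying ester triplets between repeat units;
- *entry trajectories* that move the polymer rigidly along one of three
  planted spatial corridors into the active site, with Gaussian
  positional noise, recording the noiseless 6 A / 4 A phase boundaries;
- *Boltzmann samples* from analytic 2D potentials via a Metropolis chain,
  validating free-energy-surface recovery against the generating
  potential;
- *noisy Michaelis-Menten datasets* at stated K_m, V_max, noise and seed.

Every generator is a pure function of its arguments and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .entry import EntryEvent
from .kinetics import KineticDataset
from .model_io import MolecularSystem, Trajectory

__all__ = ["FixtureSpec", "make_toy_system", "simulate_entry",
           "simulate_contacts", "planted_corridor_residues",
           "sample_boltzmann2d", "make_kinetic_data", "POTENTIALS",
           "harmonic_potential", "double_well_potential"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study case."""

    seed: int = 0
    n_residues: int = 20
    n_polymer_units: int = 5
    n_frames: int = 120
    noise: float = 0.3            # A, positional noise on the polymer
    persistent_residues: tuple[int, ...] = ()   # planted >=75% contact subset

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("need at least 10 residues")
        if self.n_polymer_units < 3:
            raise ValueError("need at least 3 polymer units")


# 19 non-serine names cycled over the shell; covers all four classes
_SHELL_NAMES = ["ALA", "VAL", "LEU", "ILE", "MET", "GLY", "PRO", "CYS",
                "THR", "ASN", "GLN", "ASP", "GLU", "LYS", "ARG", "HIS",
                "PHE", "TYR", "TRP"]


def make_toy_system(spec: FixtureSpec) -> tuple[MolecularSystem, np.ndarray]:
    """Build the toy enzyme/polymer topology and its reference coordinates.

    The enzyme is a spherical Calpha shell of radius 15 A centred at the
    origin; residue 1 is the catalytic serine whose gamma-oxygen bead sits
    at (12, 0, 0), pointing into the cleft, with the two oxyanion
    hydrogen beads placed so that the final polymer pose of
    :func:`simulate_entry` satisfies the productive criteria.  The polymer
    is a straight bead chain of ``n_polymer_units`` repeat units, each a
    (C, O, Oester, C2) bead quartet; the ester triplet of unit u joins
    units u and u+1, giving ``n_polymer_units - 1`` triplets.  Toy charges
    and Lennard-Jones parameters are assigned so interaction energies are
    attractive at contact range.
    """
    rng = np.random.default_rng(spec.seed)
    n_res = spec.n_residues
    ids, names, elements, charges, sigmas, epsilons = [], [], [], [], [], []
    res_idx, res_names, segments, coords = [], [], [], []
    aid = 1

    def add(name, el, q, s, e, resi, resn, seg, xyz):
        nonlocal aid
        ids.append(aid)
        names.append(name)
        elements.append(el)
        charges.append(q)
        sigmas.append(s)
        epsilons.append(e)
        res_idx.append(resi)
        res_names.append(resn)
        segments.append(seg)
        coords.append(xyz)
        aid += 1

    # residue 1: catalytic serine with gamma-oxygen at the cleft mouth
    og = np.array([12.0, 0.0, 0.0])
    add("CA", "C", 0.10, 3.5, 0.08, 1, "SER", "enzyme", og - np.array([1.5, 0, 0]))
    add("OG", "O", -0.40, 3.0, 0.15, 1, "SER", "enzyme", og)
    # oxyanion-hole hydrogens near where the carbonyl oxygen will land
    # (carbonyl O sits ~1.8 A above the final ester-carbon position)
    final_c = og + np.array([3.0, 0.0, 0.0])
    final_o = final_c + np.array([0.0, 1.8, 0.0])
    add("HN1", "H", 0.30, 1.0, 0.02, 2, "GLY", "enzyme",
        final_o + np.array([1.6, 1.0, 0.0]))
    add("CA", "C", 0.0, 3.5, 0.08, 2, "GLY", "enzyme",
        final_o + np.array([2.6, 3.2, 0.0]))
    add("HN2", "H", 0.30, 1.0, 0.02, 3, "GLY", "enzyme",
        final_o + np.array([-1.6, 1.0, 0.0]))
    add("CA", "C", 0.0, 3.5, 0.08, 3, "GLY", "enzyme",
        final_o + np.array([-2.6, 3.2, 0.0]))

    # remaining shell residues on a sphere, avoiding the cleft mouth (+x)
    shell_r = 15.0
    for r in range(4, n_res + 1):
        while True:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            if v[0] < 0.85:       # keep the approach corridor open
                break
        resn = _SHELL_NAMES[(r - 4) % len(_SHELL_NAMES)]
        add("CA", "C", rng.uniform(-0.1, 0.1), 3.5, 0.08, r, resn, "enzyme",
            v * shell_r)

    # polymer chain along +x beyond the cleft, one residue per repeat unit
    unit_len = 4.0
    start = og + np.array([20.0, 0.0, 0.0])
    for u in range(spec.n_polymer_units):
        base = start + np.array([u * unit_len, 0.0, 0.0])
        resi = 100 + u
        # the terminal unit carries no ester junction: acid-like atom names
        # keep it out of the ester template match
        terminal = u == spec.n_polymer_units - 1
        add("CT" if terminal else "C1", "C", 0.55, 3.6, 0.10, resi, "PET",
            "polymer", base)
        add("OT" if terminal else "O1", "O", -0.45, 3.0, 0.17, resi, "PET",
            "polymer", base + np.array([0.0, 1.8, 0.0]))
        # O2 offset in -z puts the serine's approach on the si face
        add("OXT" if terminal else "O2", "O", -0.35, 3.0, 0.17, resi, "PET",
            "polymer", base + np.array([1.3, -0.6, -0.8]))
        add("C2", "C", 0.25, 3.6, 0.10, resi, "PET", "polymer",
            base + np.array([2.6, 0.0, 0.0]))

    coords = np.asarray(coords)
    ids_arr = np.asarray(ids, int)
    seg_arr = np.asarray(segments)
    resi_arr = np.asarray(res_idx, int)
    poly_mask = seg_arr == "polymer"
    units = [ids_arr[poly_mask & (resi_arr == 100 + u)]
             for u in range(spec.n_polymer_units)]
    names_arr = np.asarray(names)
    esters = []
    for u in range(spec.n_polymer_units - 1):
        m = poly_mask & (resi_arr == 100 + u)
        c = int(ids_arr[m & (names_arr == "C1")][0])
        o = int(ids_arr[m & (names_arr == "O1")][0])
        oe = int(ids_arr[m & (names_arr == "O2")][0])
        esters.append((c, o, oe))

    system = MolecularSystem(
        atom_id=ids_arr, name=names_arr, element=np.asarray(elements),
        charge=np.asarray(charges), lj_sigma=np.asarray(sigmas),
        lj_epsilon=np.asarray(epsilons), residue_index=resi_arr,
        residue_name=np.asarray(res_names), segment=seg_arr,
        serine_ogamma=2, histidine_residue=2, aspartate_residue=3,
        oxyanion_donors=(3, 5), polymer_units=units, ester_bonds=esters,
        params_present=True)
    return system, coords


# --------------------------------------------------------------------------
# entry trajectories along planted corridors
# --------------------------------------------------------------------------

# corridor approach directions (unit vectors, in the +x hemisphere seen
# from the serine): 1 = swinging in from -y, 2 = head-on, 3 = from +y
_CORRIDOR_DIRS = {
    1: np.array([0.55, -0.80, 0.23]),
    2: np.array([1.0, 0.0, 0.0]),
    3: np.array([0.55, 0.80, -0.23]),
}


def simulate_entry(system: MolecularSystem, ref_coords: np.ndarray,
                   spec: FixtureSpec, corridor: int, seed: int,
                   ) -> tuple[Trajectory, EntryEvent, int]:
    """Generate one entry trajectory along a planted corridor.

    The tracked ester carbon (first triplet) follows a corridor-specific
    guide curve from >= 9 A down to ~3 A of the serine gamma-oxygen; the
    whole polymer translates rigidly (internal geometry fixed) and the
    final pose satisfies the productive-pose criteria by construction.
    Per-frame Gaussian noise of amplitude ``spec.noise`` is added as a
    rigid polymer displacement.  Ground-truth phase boundaries are taken
    from the *noiseless* distance profile's 6 A / 4 A crossings.

    Returns (trajectory, ground-truth event, corridor label).
    """
    if corridor not in _CORRIDOR_DIRS:
        raise ValueError("corridor must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    og = ref_coords[system.index_of(system.serine_ogamma)]
    c_ref = ref_coords[system.index_of(system.ester_bonds[0][0])]
    final_c = og + np.array([3.0, 0.0, 0.0])     # productive pose, ~3 A
    u = _CORRIDOR_DIRS[corridor] / np.linalg.norm(_CORRIDOR_DIRS[corridor])

    F = spec.n_frames
    # approach schedule mimicking a long outside dwell, a fast passage
    # through the boundary zone (steep crossings keep the noisy and the
    # noiseless 6/4 A crossings close) and a settled inside dwell
    t = np.linspace(0.0, 1.0, F)
    offset = np.where(
        t < 0.75, 12.0 - 6.0 * (t / 0.75),                    # dwell 12 -> 6
        np.where(t < 0.85, 6.0 * (0.85 - t) / 0.10, 0.0))     # fast 6 -> 0
    # lateral bow during the dwell distinguishes corridors spatially; it
    # vanishes before the boundary zone so it cannot soften the crossings
    perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(u, np.array([0.0, 1.0, 0.0]))
    perp /= np.linalg.norm(perp)
    bow = 3.0 * np.sin(np.pi * np.clip(t / 0.75, 0, 1)) * (corridor - 2)

    poly_idx = np.where(system.polymer_mask)[0]
    coords = np.repeat(ref_coords[None, :, :], F, axis=0)
    guide_c = final_c[None, :] + offset[:, None] * u[None, :] + \
        bow[:, None] * perp[None, :]
    noiseless_d = np.linalg.norm(guide_c - og[None, :], axis=1)
    for f in range(F):
        shift = guide_c[f] - c_ref
        if spec.noise > 0:
            shift = shift + rng.normal(scale=spec.noise, size=3)
        coords[f, poly_idx] = ref_coords[poly_idx] + shift

    traj = Trajectory(coordinates=coords, time=np.arange(F) * 0.01)

    # ground-truth phases from the noiseless profile (6 / 4 A boundaries)
    below_inner = np.where(noiseless_d < 4.0)[0]
    in_start = int(below_inner[0])
    above_outer = np.where(noiseless_d[:in_start] > 6.0)[0]
    last_above = int(above_outer[-1])
    truth = EntryEvent(outside=(0, last_above + 1),
                       entry=(last_above + 1, in_start),
                       inside=(in_start, F),
                       face="si", productive=True, ester_index=0)
    return traj, truth, corridor


def planted_corridor_residues(system: MolecularSystem, ref_coords: np.ndarray,
                              radius: float = 10.0) -> dict[int, list[int]]:
    """Enzyme residues whose Calpha lies closest to each corridor's guide
    path midpoint -- the planted pathway-discriminating positions."""
    og = ref_coords[system.index_of(system.serine_ogamma)]
    out: dict[int, list[int]] = {}
    ca = (system.name == "CA") & system.enzyme_mask
    ca_idx = np.where(ca)[0]
    for c, u in _CORRIDOR_DIRS.items():
        mid = og + np.array([3.0, 0.0, 0.0]) + 6.0 * (u / np.linalg.norm(u))
        d = np.linalg.norm(ref_coords[ca_idx] - mid, axis=1)
        near = ca_idx[d <= radius]
        out[c] = sorted(int(r) for r in np.unique(system.residue_index[near]))
    return out


# --------------------------------------------------------------------------
# contact-pattern fixtures with a planted persistent subset
# --------------------------------------------------------------------------

def simulate_contacts(system: MolecularSystem, ref_coords: np.ndarray,
                      n_frames: int, fractions: dict[int, float], seed: int,
                      background: float = 0.1,
                      sites: dict[int, str] | None = None,
                      ) -> tuple[Trajectory, dict[int, float]]:
    """Trajectory with exact, planted per-residue contact fractions.

    The polymer sits rigidly in its bound pose (tracked ester carbon
    3.2 A from the serine gamma-oxygen).  Each enzyme residue's Calpha bead is
    placed 2.5 A from a polymer atom in exactly ``round(f * n_frames)``
    frames (f from ``fractions``, ``background`` for unlisted residues)
    and at its shell position otherwise, so the ground-truth contact
    fraction of every residue is known to a frame.

    ``sites`` optionally maps a residue to ``"proximal"`` or ``"distal"``:
    its contact frames touch a polymer atom of the first (near-serine) or
    the last (remote) repeat unit respectively; default proximal.

    Returns the trajectory and the exact fraction per residue.  The
    serine and oxyanion-scaffold residues (1-3) are left in place and get
    no planted contacts.
    """
    rng = np.random.default_rng(seed)
    sites = sites or {}
    og = ref_coords[system.index_of(system.serine_ogamma)]
    c_ref = ref_coords[system.index_of(system.ester_bonds[0][0])]
    # 3.2 A pose: bound, but just outside the 3 A contact cutoff so the
    # catalytic serine itself stays out of the planted contact set
    shift = (og + np.array([3.2, 0.0, 0.0])) - c_ref
    coords0 = ref_coords.copy()
    poly_idx = np.where(system.polymer_mask)[0]
    coords0[poly_idx] += shift

    near_atom = system.index_of(int(system.polymer_units[0][-1]))
    far_atom = system.index_of(int(system.polymer_units[-1][-1]))
    coords = np.repeat(coords0[None, :, :], n_frames, axis=0)
    truth: dict[int, float] = {}
    for r in system.enzyme_residues():
        r = int(r)
        if r <= 3:
            continue
        f = fractions.get(r, background)
        n_on = int(round(f * n_frames))
        truth[r] = n_on / n_frames
        on = rng.permutation(n_frames)[:n_on]
        target = far_atom if sites.get(r) == "distal" else near_atom
        idx = system.residue_atom_indices(r)
        away = coords0[target] - og
        away /= np.linalg.norm(away)
        pos = coords0[target] + 2.5 * away
        for fr in on:
            coords[fr, idx] = pos
    return Trajectory(coordinates=coords, time=np.arange(n_frames) * 0.01), truth


# --------------------------------------------------------------------------
# Boltzmann sampling of analytic 2D potentials
# --------------------------------------------------------------------------

def harmonic_potential(k: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """U(x, y) = k/2 (x^2 + y^2), kJ/mol per A^2."""
    def U(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        return 0.5 * k * (p[:, 0] ** 2 + p[:, 1] ** 2)
    return U


def double_well_potential(a: float = 5.0, b: float = 2.0,
                          x0: float = 1.5) -> Callable[[np.ndarray], np.ndarray]:
    """U(x, y) = a ((x/x0)^2 - 1)^2 + b y^2: two wells at x = +-x0, barrier
    a at x = 0 (kJ/mol)."""
    def U(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        return a * ((p[:, 0] / x0) ** 2 - 1.0) ** 2 + b * p[:, 1] ** 2
    return U


POTENTIALS: dict[str, Callable[..., Callable]] = {
    "harmonic": harmonic_potential,
    "double_well": double_well_potential,
}

_KB_KJ = 0.0083145


def sample_boltzmann2d(potential: Callable[[np.ndarray], np.ndarray], n: int,
                       temperature: float = 303.0, seed: int = 0,
                       step: float = 0.8, thin: int = 5, burn_in: int = 500,
                       start: tuple[float, float] = (0.0, 0.0),
                       ) -> tuple[np.ndarray, float]:
    """Metropolis samples targeting exp(-U / k_B T).

    A Gaussian random-walk chain of ``burn_in + n * thin`` steps is run
    and thinned by ``thin``.  Returns ``(samples, ess)`` where ``ess`` is
    the effective sample size estimated from the PC-wise autocorrelation
    of the thinned chain.  Raises when a full pass accepts nothing
    (step-size misconfiguration).
    """
    rng = np.random.default_rng(seed)
    kbt = _KB_KJ * temperature
    total = burn_in + n * thin
    pos = np.asarray(start, float)
    u_cur = float(potential(pos[None, :])[0])
    out = np.empty((n, 2))
    kept = 0
    accepted_in_pass = 1
    for i in range(total):
        if i % 1000 == 0:
            if accepted_in_pass == 0:
                raise RuntimeError("Metropolis chain accepted no moves in a "
                                   "full pass; reduce the step size")
            accepted_in_pass = 0
        prop = pos + rng.normal(scale=step, size=2)
        u_prop = float(potential(prop[None, :])[0])
        if u_prop <= u_cur or rng.random() < np.exp(-(u_prop - u_cur) / kbt):
            pos, u_cur = prop, u_prop
            accepted_in_pass += 1
        if i >= burn_in and (i - burn_in) % thin == 0 and kept < n:
            out[kept] = pos
            kept += 1
    ess = _effective_sample_size(out)
    return out, ess


def _effective_sample_size(samples: np.ndarray) -> float:
    n = len(samples)
    ess = []
    for k in range(samples.shape[1]):
        x = samples[:, k] - samples[:, k].mean()
        var = float(x @ x) / n
        if var == 0:
            continue
        tau = 1.0
        for lag in range(1, min(200, n // 2)):
            rho = float(x[:-lag] @ x[lag:]) / ((n - lag) * var)
            if rho < 0.05:
                break
            tau += 2.0 * rho
        ess.append(n / tau)
    return float(min(ess)) if ess else float(n)


# --------------------------------------------------------------------------
# kinetic data
# --------------------------------------------------------------------------

def make_kinetic_data(K_m: float, V_max: float, mode: str = "conv", n: int = 8,
                      noise_fraction: float = 0.05, seed: int = 0,
                      fixed_value: float = float("nan"),
                      fixed_unit: str = "") -> KineticDataset:
    """Noisy saturation dataset at known truth.

    x is log-spaced from K_m/10 to 10 K_m; rates are the Michaelis-Menten
    model plus Gaussian noise with sigma = ``noise_fraction * V_max``,
    clipped at zero (rates are non-negative by definition).
    """
    if n < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng(seed)
    x = np.logspace(np.log10(K_m / 10.0), np.log10(10.0 * K_m), n)
    v = V_max * x / (K_m + x)
    if noise_fraction > 0:
        v = v + rng.normal(scale=noise_fraction * V_max, size=n)
    v = np.clip(v, 0.0, None)
    return KineticDataset(x=x, rate=v, mode=mode,
                          fixed_value=fixed_value, fixed_unit=fixed_unit)
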