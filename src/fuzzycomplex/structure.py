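"""Coarse-grained restrained annealing of peptide–domain complexes and
ensemble statistics.

The model builder produces backbone + Cβ chains (N, CA, C, O, CB except
glycine) with ideal bond geometry from φ/ψ torsions; D-amino-acid chains are
exact mirror images (flipped torsion signs, mirrored Cβ placement).  The
annealer replaces a full molecular force field with the logic of the
restrained protocol: a flat-bottom harmonic energy over distance restraints
(ambiguous groups collapse through r⁻⁶ summation), harmonic dihedral and
positional terms, and a soft-sphere steric repulsion, minimised by
torsion-space plus rigid-body Metropolis moves under a geometric cooling
schedule.  Ensemble statistics follow the standard repertoire: Kabsch
superposition RMSD, two-pass mean-structure RMSF, quality-threshold
clustering at a backbone RMSD cutoff, and Ramachandran basin populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .pdbio import CoordinateModel
from .pre import DistanceRestraint, ambiguous_effective_distance

# ---------------------------------------------------------------------------
# ideal backbone geometry (Å, degrees)

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521

ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 109.45
TORSION_N_C_CA_CB = 120.0  # improper dihedral N-C-CA-CB fixing L chirality

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

DEFAULT_PHI_PSI = {"extended": (-135.0, 135.0), "helix": (-60.0, -45.0)}


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement: position d with |cd|=bond, angle(b,c,d), dihedral(a,b,c,d)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(
    sequence: str,
    chirality: str = "L",
    conformation: str | Sequence[tuple[float, float]] = "extended",
    chain_id: str = "A",
    start_residue: int = 1,
) -> CoordinateModel:
    """Build a backbone+Cβ chain with ideal geometry from φ/ψ torsions.

    ``conformation`` is ``"extended"``, ``"helix"`` or an explicit list of
    (φ, ψ) pairs in degrees (L convention — D chains flip the signs
    internally, producing the exact mirror image).
    """
    sequence = sequence.upper()
    for ch in sequence:
        if ch not in AA3:
            raise ValueError(f"unknown residue letter {ch!r}")
    if chirality not in ("L", "D"):
        raise ValueError("chirality must be 'L' or 'D'")
    n_res = len(sequence)
    if isinstance(conformation, str):
        try:
            phi_psi = [DEFAULT_PHI_PSI[conformation]] * n_res
        except KeyError:
            raise ValueError(f"unknown conformation {conformation!r}") from None
    else:
        phi_psi = [tuple(pp) for pp in conformation]
        if len(phi_psi) != n_res:
            raise ValueError("need one (phi, psi) pair per residue")
    sign = 1.0 if chirality == "L" else -1.0
    phi_psi = [(sign * p, sign * s) for p, s in phi_psi]
    cb_torsion = sign * TORSION_N_C_CA_CB

    chains, residues, names, coords = [], [], [], []

    def emit(res_i, name, xyz):
        chains.append(chain_id)
        residues.append(start_residue + res_i)
        names.append(name)
        coords.append(np.asarray(xyz, dtype=float))

    # seed first residue in the xy-plane
    n_xyz = np.zeros(3)
    ca_xyz = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    c_xyz = ca_xyz + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    prev = {}
    for i, aa in enumerate(sequence):
        if i > 0:
            phi_prev, psi_prev = phi_psi[i - 1]
            n_xyz = _place_atom(prev["N"], prev["CA"], prev["C"],
                                BOND_C_N, ANGLE_CA_C_N, psi_prev)
            ca_xyz = _place_atom(prev["CA"], prev["C"], n_xyz,
                                 BOND_N_CA, ANGLE_C_N_CA, 180.0)  # omega trans
            c_xyz = _place_atom(prev["C"], n_xyz, ca_xyz,
                                BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        psi = phi_psi[i][1]
        o_xyz = _place_atom(n_xyz, ca_xyz, c_xyz, BOND_C_O, ANGLE_CA_C_O,
                            psi + 180.0)
        emit(i, "N", n_xyz)
        emit(i, "CA", ca_xyz)
        emit(i, "C", c_xyz)
        emit(i, "O", o_xyz)
        if aa != "G":
            cb_xyz = _place_atom(n_xyz, c_xyz, ca_xyz, BOND_CA_CB,
                                 ANGLE_C_CA_CB, cb_torsion)
            emit(i, "CB", cb_xyz)
        prev = {"N": n_xyz, "CA": ca_xyz, "C": c_xyz}

    return CoordinateModel(
        chain_id=np.array(chains), residue_index=np.array(residues),
        residue_name=np.array([AA3[sequence[r - start_residue]] for r in residues]),
        atom_name=np.array(names), coords=np.stack(coords),
    )


def compute_phi_psi(model: CoordinateModel, chain: str) -> dict[int, tuple[float, float]]:
    """Backbone (φ, ψ) in degrees per residue of one chain (NaN at termini)."""
    mask = model.chain_id == chain
    res_ids = np.unique(model.residue_index[mask])
    pos = {}
    for r in res_ids:
        for a in ("N", "CA", "C"):
            try:
                pos[(r, a)] = model.coords[model.atom_index(chain, int(r), a)]
            except KeyError:
                pass
    out = {}
    for r in res_ids:
        r = int(r)
        phi = psi = np.nan
        if (r - 1, "C") in pos and all((r, a) in pos for a in ("N", "CA", "C")):
            phi = dihedral(pos[(r - 1, "C")], pos[(r, "N")], pos[(r, "CA")],
                           pos[(r, "C")])
        if (r + 1, "N") in pos and all((r, a) in pos for a in ("N", "CA", "C")):
            psi = dihedral(pos[(r, "N")], pos[(r, "CA")], pos[(r, "C")],
                           pos[(r + 1, "N")])
        out[r] = (phi, psi)
    return out


def merge_models(*models: CoordinateModel, model_id: int = 0) -> CoordinateModel:
    """Concatenate chains into one complex model."""
    return CoordinateModel(
        chain_id=np.concatenate([m.chain_id for m in models]),
        residue_index=np.concatenate([m.residue_index for m in models]),
        residue_name=np.concatenate([m.residue_name for m in models]),
        atom_name=np.concatenate([m.atom_name for m in models]),
        coords=np.concatenate([m.coords for m in models]),
        model_id=model_id,
    )


def spin_label_copies(model: CoordinateModel, chain: str, residue: int,
                      arm: float = 8.0, n_copies: int = 4) -> np.ndarray:
    """Geometric spin-label copy positions around the labelled residue.

    Copies sit at ``arm`` Å from CA along a tetrahedral spread about the
    CA→CB direction, absorbing unknown label orientation.
    """
    ca = model.coords[model.atom_index(chain, residue, "CA")]
    try:
        cb = model.coords[model.atom_index(chain, residue, "CB")]
        axis = cb - ca
    except KeyError:  # glycine: use outward normal from backbone plane
        n = model.coords[model.atom_index(chain, residue, "N")]
        c = model.coords[model.atom_index(chain, residue, "C")]
        axis = np.cross(n - ca, c - ca)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    half = np.radians(54.75)  # tetrahedral half-angle
    out = []
    for k in range(n_copies):
        az = 2 * np.pi * k / n_copies
        direction = (np.cos(half) * axis
                     + np.sin(half) * (np.cos(az) * u + np.sin(az) * v))
        out.append(ca + arm * direction)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# restraints


@dataclass(frozen=True)
class DihedralRestraint:
    chain: str
    residue: int
    angle: str          # phi | psi
    target: float       # degrees
    width: float = 10.0  # flat-bottom half-width, degrees
    weight: float = 1.0


@dataclass(frozen=True)
class PositionalRestraint:
    """Harmonic tether of template atoms to reference coordinates."""

    chain: str
    atom_names: tuple[str, ...] = BACKBONE_ATOMS
    force_constant: float = 100.0  # reduced units per Å²; mirrors the
    # 10,000 kcal mol⁻¹ Å⁻² template restraint scaled by 1/100
    residues: tuple[int, ...] | None = None


@dataclass
class RestraintSet:
    distance: list[DistanceRestraint] = field(default_factory=list)
    dihedral: list[DihedralRestraint] = field(default_factory=list)
    positional: list[PositionalRestraint] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (self.distance or self.dihedral or self.positional)


def _parse_selection(model: CoordinateModel, sel: str) -> tuple[int, float]:
    """Resolve 'chain/residue/atom' → (atom index, upper-bound padding Å).

    Side-chain atom names beyond the coarse representation map to Cβ with a
    +3 Å pseudo-atom padding.
    """
    parts = sel.split("/")
    if len(parts) != 3:
        raise KeyError(f"selection {sel!r} must be chain/residue/atom")
    chain, res, atom = parts[0], int(parts[1]), parts[2]
    try:
        return model.atom_index(chain, res, atom), 0.0
    except KeyError:
        if atom not in ("N", "CA", "C", "O", "CB"):
            # side-chain pseudo-atom: fall back to CB, pad the bound
            return model.atom_index(chain, res, "CB"), 3.0
        raise


class ResolvedRestraints:
    """Restraint set with atom selections resolved to index arrays."""

    def __init__(self, model: CoordinateModel, rset: RestraintSet,
                 k_distance: float = 1.0, k_dihedral: float = 0.01,
                 k_steric: float = 1.0, steric_d0: float = 2.8):
        self.rset = rset
        self.k_distance = k_distance
        self.k_dihedral = k_dihedral
        self.k_steric = k_steric
        self.steric_d0 = steric_d0
        self.n_atoms = len(model)

        self.dist_entries = []  # (idx_a, idx_array_b, lower, upper, weight, mode)
        for r in rset.distance:
            try:
                ia, pad_a = _parse_selection(model, r.selection_a)
                sels_b = (r.selection_b if isinstance(r.selection_b, tuple)
                          else (r.selection_b,))
                ib, pad_b = zip(*(_parse_selection(model, s) for s in sels_b))
            except KeyError as err:
                raise KeyError(f"unresolvable restraint {r.selection_a} - "
                               f"{r.selection_b}: {err}") from None
            pad = pad_a + max(pad_b)
            self.dist_entries.append(
                (ia, np.array(ib, dtype=int), r.lower, r.upper + pad,
                 r.weight, r.ambiguity_mode)
            )

        self.dih_entries = []  # (4 atom indices, target, width, weight)
        for d in rset.dihedral:
            quad = _dihedral_atoms(model, d.chain, d.residue, d.angle)
            self.dih_entries.append((quad, d.target, d.width, d.weight))

        self.pos_entries = []  # (indices, reference coords, k)
        for p in rset.positional:
            mask = model.select(chain=p.chain, atom_names=p.atom_names,
                                residues=p.residues)
            idx = np.flatnonzero(mask)
            self.pos_entries.append((idx, model.coords[idx].copy(),
                                     p.force_constant))

        # steric exclusion: same or adjacent residue within a chain
        chain_codes = np.unique(model.chain_id, return_inverse=True)[1]
        ids = chain_codes * 100000 + model.residue_index
        diff = np.abs(ids[:, None] - ids[None, :])
        same_chain = chain_codes[:, None] == chain_codes[None, :]
        excluded = same_chain & (diff <= 1)
        self.steric_mask = np.triu(~excluded, k=1)

    def energy(self, coords: np.ndarray) -> tuple[float, list[float]]:
        """Total reduced-unit energy and per-restraint violations.

        Violations are Å for distance, degrees for dihedral restraints;
        positional and steric terms contribute energy only.
        """
        e = 0.0
        violations: list[float] = []
        for ia, ib, lower, upper, weight, mode in self.dist_entries:
            if len(ib) == 1:
                d = float(np.linalg.norm(coords[ia] - coords[ib[0]]))
            else:
                dists = np.linalg.norm(coords[ib] - coords[ia], axis=1)
                d = ambiguous_effective_distance(dists, mode)
            viol = max(0.0, lower - d, d - upper)
            violations.append(viol)
            e += weight * self.k_distance * viol**2
        for quad, target, width, weight in self.dih_entries:
            ang = dihedral(*coords[list(quad)])
            delta = (ang - target + 180.0) % 360.0 - 180.0
            viol = max(0.0, abs(delta) - width)
            violations.append(viol)
            e += weight * self.k_dihedral * viol**2
        for idx, ref, k in self.pos_entries:
            e += k * float(np.sum((coords[idx] - ref) ** 2))
        # soft-sphere sterics
        dm = cdist(coords, coords)
        clash = (dm < self.steric_d0) & self.steric_mask
        if clash.any():
            e += self.k_steric * float(np.sum((self.steric_d0 - dm[clash]) ** 2))
        return e, violations


def _dihedral_atoms(model: CoordinateModel, chain: str, residue: int,
                    angle: str) -> tuple[int, int, int, int]:
    if angle == "phi":
        return (model.atom_index(chain, residue - 1, "C"),
                model.atom_index(chain, residue, "N"),
                model.atom_index(chain, residue, "CA"),
                model.atom_index(chain, residue, "C"))
    if angle == "psi":
        return (model.atom_index(chain, residue, "N"),
                model.atom_index(chain, residue, "CA"),
                model.atom_index(chain, residue, "C"),
                model.atom_index(chain, residue + 1, "N"))
    raise ValueError(f"unknown torsion {angle!r}")


def restraint_energy(model: CoordinateModel, rset: RestraintSet,
                     **kwargs) -> tuple[float, list[float]]:
    """Energy of one model under a restraint set (see ResolvedRestraints)."""
    return ResolvedRestraints(model, rset, **kwargs).energy(model.coords)


def make_helix_hbond_restraints(model: CoordinateModel, chain: str,
                                residues: Iterable[int],
                                lower: float = 2.8, upper: float = 3.3,
                                ) -> list[DistanceRestraint]:
    """O(i)–N(i+4) hydrogen-bond restraints over a helical stretch."""
    out = []
    res = sorted(residues)
    present = set(model.residue_index[model.chain_id == chain].tolist())
    for r in res:
        if r in present and r + 4 in present:
            out.append(DistanceRestraint(
                f"{chain}/{r}/O", f"{chain}/{r + 4}/N",
                target=(lower + upper) / 2, lower=lower, upper=upper,
                kind="range", provenance="hbond"))
    return out


def csp_ambiguous_restraint(selection_a: str, group_b: Sequence[str],
                            upper: float = 8.0) -> DistanceRestraint:
    """Ambiguous interface restraint for a residue showing binding CSPs:
    r⁻⁶-summed effective distance to the partner selection under an upper
    bound (default 8 Å)."""
    return DistanceRestraint(selection_a, tuple(group_b), target=upper,
                             lower=0.0, upper=upper, kind="upper_only",
                             provenance="csp_ambiguous")


# ---------------------------------------------------------------------------
# annealing


@dataclass(frozen=True)
class AnnealSchedule:
    t_start: float = 50.0
    t_end: float = 0.02
    n_cycles: int = 200
    moves_per_cycle: int = 50
    quench_moves: int = 2000

    def temperatures(self) -> np.ndarray:
        if self.n_cycles <= 0:
            return np.array([])
        if self.n_cycles == 1:
            return np.array([self.t_end])
        ratio = (self.t_end / self.t_start) ** (1.0 / (self.n_cycles - 1))
        return self.t_start * ratio ** np.arange(self.n_cycles)


@dataclass
class ConformationEnsemble:
    """Ordered models with per-model restraint energy and violations."""

    models: list[CoordinateModel]
    energies: list[float]
    violations: list[list[float]]

    def __len__(self) -> int:
        return len(self.models)

    def sorted_by_energy(self) -> "ConformationEnsemble":
        order = sorted(range(len(self.models)),
                       key=lambda i: (self.energies[i], self.models[i].model_id))
        return ConformationEnsemble(
            [self.models[i] for i in order],
            [self.energies[i] for i in order],
            [self.violations[i] for i in order],
        )


class _TorsionMover:
    """Applies φ/ψ rotations and rigid-body moves to a complex model."""

    def __init__(self, model: CoordinateModel,
                 flexible: Mapping[str, Sequence[int]]):
        self.model = model
        self.torsions = []  # (axis_i, axis_j, affected atom indices)
        order = np.arange(len(model))
        for chain, residues in flexible.items():
            cmask = model.chain_id == chain
            for r in residues:
                r = int(r)
                try:
                    i_n = model.atom_index(chain, r, "N")
                    i_ca = model.atom_index(chain, r, "CA")
                    i_c = model.atom_index(chain, r, "C")
                except KeyError:
                    continue
                downstream = cmask & (model.residue_index > r)
                # phi: rotate about N-CA; moves C, O, CB of r + downstream
                aff = downstream.copy()
                rmask = cmask & (model.residue_index == r)
                aff |= rmask & np.isin(model.atom_name, ["C", "O", "CB"])
                if model.residue_index[cmask].min() < r:  # phi defined
                    self.torsions.append((i_n, i_ca, np.flatnonzero(aff)))
                # psi: rotate about CA-C; moves O of r + downstream
                aff2 = downstream.copy()
                aff2 |= rmask & (model.atom_name == "O")
                if model.residue_index[cmask].max() > r:
                    self.torsions.append((i_ca, i_c, np.flatnonzero(aff2)))
        # chains that are entirely flexible get rigid-body moves
        self.rigid_chains = []
        for chain, residues in flexible.items():
            cres = set(model.residue_index[model.chain_id == chain].tolist())
            if cres and cres <= set(int(r) for r in residues):
                self.rigid_chains.append(np.flatnonzero(model.chain_id == chain))

    @staticmethod
    def _rotate(coords, i, j, idx, angle_rad):
        axis = coords[j] - coords[i]
        axis = axis / np.linalg.norm(axis)
        pts = coords[idx] - coords[j]
        k = axis
        cos, sin = np.cos(angle_rad), np.sin(angle_rad)
        rotated = (pts * cos + np.cross(k, pts) * sin
                   + np.outer(pts @ k, k) * (1 - cos))
        coords[idx] = rotated + coords[j]

    def propose(self, coords: np.ndarray, rng: np.random.Generator,
                scale: float) -> np.ndarray:
        new = coords.copy()
        n_tor = len(self.torsions)
        n_rigid = len(self.rigid_chains)
        pick = rng.integers(n_tor + 2 * n_rigid)
        if pick < n_tor:
            i, j, idx = self.torsions[pick]
            self._rotate(new, i, j, idx, rng.normal(0.0, np.radians(1 + 29 * scale)))
        elif pick < n_tor + n_rigid:
            idx = self.rigid_chains[pick - n_tor]
            new[idx] += rng.normal(0.0, 0.05 + 1.45 * scale, size=3)
        else:
            idx = self.rigid_chains[pick - n_tor - n_rigid]
            centroid = new[idx].mean(axis=0)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.normal(0.0, np.radians(1 + 29 * scale))
            pts = new[idx] - centroid
            cos, sin = np.cos(ang), np.sin(ang)
            new[idx] = (pts * cos + np.cross(axis, pts) * sin
                        + np.outer(pts @ axis, axis) * (1 - cos)) + centroid
        return new

    def randomize(self, coords: np.ndarray, rng: np.random.Generator,
                  n_kicks: int = 60) -> np.ndarray:
        out = coords.copy()
        for _ in range(n_kicks):
            out = self.propose(out, rng, scale=1.0)
        return out


def anneal(
    start: CoordinateModel,
    restraints: RestraintSet,
    flexible: Mapping[str, Sequence[int]],
    schedule: AnnealSchedule = AnnealSchedule(),
    n_models: int = 20,
    seed: int = 0,
    randomize: bool = True,
    **energy_kwargs,
) -> ConformationEnsemble:
    """Restrained simulated annealing; returns all models with energies.

    Each model starts from ``start`` with flexible torsions randomised, then
    runs Metropolis annealing over torsion and rigid-body moves at the
    geometric cooling schedule, finishing with a zero-temperature quench.
    Deterministic for a given seed.  An empty restraint set returns the
    start geometry unchanged (there is nothing to anneal against).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not flexible or all(len(v) == 0 for v in flexible.values()):
        raise ValueError("empty flexible selection: nothing to anneal")
    temps = schedule.temperatures()
    resolved = ResolvedRestraints(start, restraints, **energy_kwargs)
    if restraints.is_empty or temps.size == 0:
        models, energies, viols = [], [], []
        for m in range(n_models):
            mdl = start.copy()
            mdl.model_id = m
            e, v = resolved.energy(mdl.coords)
            models.append(mdl)
            energies.append(e)
            viols.append(v)
        return ConformationEnsemble(models, energies, viols)

    mover = _TorsionMover(start, flexible)
    master = np.random.default_rng(seed)
    models, energies, violations = [], [], []
    for m in range(n_models):
        rng = np.random.default_rng(master.integers(2**31))
        coords = start.coords.copy()
        if randomize:
            coords = mover.randomize(coords, rng)
        e, _ = resolved.energy(coords)
        t0 = temps[0]
        for t in temps:
            scale = t / t0
            for _ in range(schedule.moves_per_cycle):
                cand = mover.propose(coords, rng, scale)
                e_new, _ = resolved.energy(cand)
                if e_new <= e or rng.random() < np.exp(-(e_new - e) / t):
                    coords, e = cand, e_new
        for _ in range(schedule.quench_moves):
            cand = mover.propose(coords, rng, scale=0.02)
            e_new, _ = resolved.energy(cand)
            if e_new <= e:
                coords, e = cand, e_new
        mdl = start.copy()
        mdl.coords = coords
        mdl.model_id = m
        e, v = resolved.energy(coords)
        models.append(mdl)
        energies.append(e)
        violations.append(v)
    return ConformationEnsemble(models, energies, violations)


def select_lowest(ensemble: ConformationEnsemble, n: int) -> ConformationEnsemble:
    """The n lowest-energy models, ties broken by model id; sorted ascending."""
    if n > len(ensemble):
        raise ValueError(f"cannot select {n} of {len(ensemble)} models")
    s = ensemble.sorted_by_energy()
    return ConformationEnsemble(s.models[:n], s.energies[:n], s.violations[:n])


# ---------------------------------------------------------------------------
# ensemble statistics


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping P onto Q."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def superpose_rmsd(a: CoordinateModel | np.ndarray,
                   b: CoordinateModel | np.ndarray,
                   selection: np.ndarray | None = None) -> float:
    """RMSD (Å) after optimal rigid (Kabsch) superposition.

    ``selection`` is a boolean mask or index array applied to both models'
    atoms (which must correspond 1:1).  Degenerate selections (< 3
    non-collinear points) fall back to translation-only with a warning.
    """
    P = a.coords if isinstance(a, CoordinateModel) else np.asarray(a)
    Q = b.coords if isinstance(b, CoordinateModel) else np.asarray(b)
    if selection is not None:
        P, Q = P[selection], Q[selection]
    if P.shape != Q.shape:
        raise ValueError("selections must map 1:1")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    rank = np.linalg.matrix_rank(Pc, tol=1e-8)
    if len(P) < 3 or rank < 2:
        warnings.warn("degenerate selection: translation-only superposition",
                      stacklevel=2)
        return float(np.sqrt(np.mean(np.sum((Pc - Qc) ** 2, axis=1))))
    R, t = _kabsch(P, Q)
    moved = P @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))


def _superpose_onto(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    R, t = _kabsch(P, Q)
    return P @ R.T + t


def ensemble_rmsf(models: Sequence[CoordinateModel],
                  selection: np.ndarray | None = None) -> np.ndarray:
    """Per-atom RMSF (Å) after two-pass superposition on the mean structure."""
    if len(models) < 2:
        raise ValueError("RMSF needs at least 2 models")
    coords = np.stack([m.coords for m in models])
    if selection is not None:
        coords = coords[:, selection]
    ref = coords[0]
    for _ in range(2):
        aligned = np.stack([_superpose_onto(c, ref) for c in coords])
        ref = aligned.mean(axis=0)
    dev = aligned - ref
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def cluster_ensemble(models: Sequence[CoordinateModel], cutoff: float = 2.0,
                     atom_names: Sequence[str] = BACKBONE_ATOMS
                     ) -> list[list[int]]:
    """Quality-threshold clustering on pairwise superposed backbone RMSD.

    Repeatedly the model with the most neighbours within ``cutoff`` seeds a
    cluster (ties broken by lowest model index); clusters are returned as
    index lists ordered by decreasing size.
    """
    n = len(models)
    if n == 0:
        return []
    sel = models[0].select(atom_names=atom_names)
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = superpose_rmsd(models[i], models[j], sel)
    remaining = list(range(n))
    clusters = []
    while remaining:
        counts = {i: sum(rmsd[i, j] <= cutoff for j in remaining)
                  for i in remaining}
        maxc = max(counts.values())
        # deterministic tie-break: smallest index among max-count models
        best = min(i for i, c in counts.items() if c == maxc)
        members = [j for j in remaining if rmsd[best, j] <= cutoff]
        clusters.append(members)
        remaining = [j for j in remaining if j not in members]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


#: default Ramachandran basins (φ, ψ windows in degrees)
RAMA_BASINS = {
    "alpha": ((-100.0, -30.0), (-67.0, -7.0)),
    "beta": ((-180.0, -90.0), (90.0, 180.0)),
}


def ramachandran_populations(
    phi: np.ndarray, psi: np.ndarray,
    basins: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = RAMA_BASINS,
) -> dict[str, float]:
    """Fractional occupancy of (φ, ψ) basins; remainder reported as 'other'."""
    phi = np.asarray(phi, dtype=float).ravel()
    psi = np.asarray(psi, dtype=float).ravel()
    ok = np.isfinite(phi) & np.isfinite(psi)
    phi, psi = phi[ok], psi[ok]
    if phi.size == 0:
        raise ValueError("empty dihedral series")
    assigned = np.zeros(phi.size, dtype=bool)
    out = {}
    for name, ((plo, phi_hi), (slo, shi)) in basins.items():
        mask = (~assigned & (phi >= plo) & (phi <= phi_hi)
                & (psi >= slo) & (psi <= shi))
        out[name] = float(mask.mean())
        assigned |= mask
    out["other"] = float((~assigned).mean())
    return out
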