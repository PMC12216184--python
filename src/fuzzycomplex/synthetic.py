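"""Forward-model generators for every measurement the pipeline analyses.

Each generator is the exact forward model of one analysis stage — fast
two-state-exchange titration shifts, mono-exponential relaxation decays,
Battiste–Wagner PRE attenuation from a planted structure, discrete-state
Markov torsion dynamics with wrapped-Gaussian emissions, and the Wiseman
one-site ITC isotherm — so that each stage's recovery behaviour can be
quantified with planted ground truth and no external data.  All randomness
flows through an integer-seeded NumPy generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .io import PeakEntry, PeakTable
from .csp import TitrationSeries, single_site_bound_fraction
from .relaxation import DecayCurve
from .pre import PREMeasurement, distance_to_gamma2, _bw_forward
from .itc import ITCTitration, default_scheme, one_site_heats
from .msm import DihedralTrajectory
from .pdbio import CoordinateModel
from .structure import (
    AA3, RestraintSet, DihedralRestraint, PositionalRestraint,
    build_chain, compute_phi_psi, merge_models, spin_label_copies,
    BACKBONE_ATOMS,
)
from .pre import DistanceRestraint

#: recovery-delay lists (s) of the R1 and R1ρ experiments; replicates are
#: genuine repeat points and are kept as such
R1_DELAYS = (0.010000, 2.000000, 0.030778, 1.272627, 0.063183, 0.806249,
             0.113724, 0.507217, 0.192548, 0.507217, 0.315484)
R1RHO_DELAYS = (0.010000, 0.200000, 0.011984, 0.130552, 0.015078, 0.086024,
                0.019903, 0.057473, 0.027429, 0.057473, 0.039167)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic data set."""

    kind: str                      # titration | decay | pre | torsion | itc | toy_complex
    params: dict = field(default_factory=dict)
    seed: int = 0

    def generate(self):
        try:
            fn = _DISPATCH[self.kind]
        except KeyError:
            raise ValueError(f"unknown generator kind {self.kind!r}") from None
        return fn(seed=self.seed, **self.params)


def gen_titration(
    n_residues: int = 30,
    binding_residues: Mapping[int, tuple[float, float]] | None = None,
    kd: float = 20e-6,
    protein_conc: float = 100e-6,
    ratios: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 3.0),
    noise_ppm: float = 0.0,
    broaden_above: float | None = None,
    seed: int = 0,
) -> TitrationSeries:
    """Fast-exchange two-state titration series.

    Observed shifts are free + bound_fraction·Δδ_max + Gaussian ppm noise
    (¹⁵N noise scaled ×5 for realism), with the bound fraction from the
    exact single-site quadratic.  ``binding_residues`` maps residue →
    (Δδ_H^max, Δδ_N^max) in ppm; default plants a 6-residue interface.
    If ``broaden_above`` is set, interface peaks whose bound fraction
    exceeds it are flagged broadened in that spectrum (exchange-broadening
    emulation).
    """
    rng = np.random.default_rng(seed)
    codes = rng.choice(list(_AA), size=n_residues)
    free_h = rng.uniform(7.5, 9.5, size=n_residues)
    free_n = rng.uniform(105.0, 130.0, size=n_residues)
    if binding_residues is None:
        start = n_residues // 3
        binding_residues = {start + i: (0.12 + 0.03 * i, 0.5 + 0.1 * i)
                            for i in range(6)}
    points = []
    for ratio in ratios:
        fb = float(single_site_bound_fraction(protein_conc,
                                              ratio * protein_conc, kd))
        entries = []
        for i in range(n_residues):
            res = i + 1
            dmax_h, dmax_n = binding_residues.get(res, (0.0, 0.0))
            flag = "ok"
            if (broaden_above is not None and res in binding_residues
                    and fb > broaden_above):
                entries.append(PeakEntry(res, str(codes[i]), np.nan, np.nan,
                                         np.nan, "broadened"))
                continue
            h = free_h[i] + fb * dmax_h + rng.normal(0.0, noise_ppm)
            n15 = free_n[i] + fb * dmax_n + rng.normal(0.0, 5.0 * noise_ppm)
            entries.append(PeakEntry(res, str(codes[i]), float(h), float(n15),
                                     1e6, flag))
        points.append((float(ratio), PeakTable(tuple(entries))))
    return TitrationSeries(tuple(points))


def gen_decay(
    rate: float = 2.0,
    amplitude: float = 1e6,
    offset: float = 0.0,
    delays: Sequence[float] = R1_DELAYS,
    noise: float = 0.0,
    residue_index: int = 1,
    seed: int = 0,
) -> DecayCurve:
    """Mono-exponential decay with Gaussian noise of SD ``noise·amplitude``."""
    rng = np.random.default_rng(seed)
    t = np.asarray(delays, dtype=float)
    y = amplitude * np.exp(-rate * t) + offset
    if noise > 0:
        y = y + rng.normal(0.0, noise * amplitude, size=t.shape)
    return DecayCurve(residue_index, t, y)


class PREDataset(NamedTuple):
    measurements: list[PREMeasurement]
    true_distances: dict[tuple[str, int], float]  # (label site, residue) -> Å


def gen_pre(
    model: CoordinateModel,
    label_sites: Sequence[tuple[str, int]],
    measured_chain: str,
    tau_c: float = 4e-9,
    field_mhz: float = 700.0,
    r2_dia: float = 10.0,
    t_evol: float = 0.010,
    noise: float = 0.0,
    i_dia: float = 1e6,
    seed: int = 0,
) -> PREDataset:
    """PRE intensity-ratio table from a planted complex structure.

    For each spin-label site, four label copies are generated geometrically
    and the r⁻⁶-summed effective distance to each measured amide nitrogen is
    converted to Γ2 and then to a paramagnetic/diamagnetic ratio through the
    Battiste–Wagner attenuation, plus optional Gaussian ratio noise.
    """
    rng = np.random.default_rng(seed)
    measurements, truth = [], {}
    res_ids = np.unique(model.residue_index[model.chain_id == measured_chain])
    for chain, site in label_sites:
        copies = spin_label_copies(model, chain, int(site))
        site_id = f"{chain}{site}"
        for r in res_ids:
            r = int(r)
            try:
                n_xyz = model.coords[model.atom_index(measured_chain, r, "N")]
            except KeyError:
                continue
            dists = np.linalg.norm(copies - n_xyz, axis=1)
            r_eff = float(np.sum(dists ** -6.0) ** (-1.0 / 6.0))
            gamma2 = distance_to_gamma2(r_eff, tau_c, field_mhz)
            ratio = _bw_forward(gamma2, r2_dia, t_evol)
            if noise > 0:
                ratio = ratio + rng.normal(0.0, noise)
            ratio = float(np.clip(ratio, 0.0, 1.2))
            measurements.append(PREMeasurement(
                residue_index=r, atom_name="H", i_para=ratio * i_dia,
                i_dia=i_dia, label_site=site_id, field_mhz=field_mhz,
                tau_c=tau_c))
            truth[(site_id, r)] = r_eff
    return PREDataset(measurements, truth)


def gen_torsion_traj(
    n_states: int = 3,
    basins: Sequence[tuple[float, float]] = ((-60.0, -45.0), (-135.0, 135.0),
                                             (60.0, 45.0)),
    widths: float | Sequence[float] = 12.0,
    transition_matrix: np.ndarray | None = None,
    n_frames: int = 1500,
    n_residues: int = 2,
    stride: float = 1.0,
    seed: int = 0,
    return_states: bool = False,
):
    """Discrete-state Markov torsion dynamics with wrapped-Gaussian emissions.

    A hidden Markov chain over ``n_states`` basins emits (φ, ψ) per residue
    from truncated (±3σ) Gaussians around the basin centre, wrapped into
    (−180, 180].  Default frame count matches the per-system trajectory
    subsampling used throughout (1500 frames).
    """
    rng = np.random.default_rng(seed)
    if transition_matrix is None:
        transition_matrix = np.full((n_states, n_states),
                                    0.05 / max(n_states - 1, 1))
        np.fill_diagonal(transition_matrix, 0.95)
    T = np.asarray(transition_matrix, dtype=float)
    if T.shape != (n_states, n_states):
        raise ValueError("transition matrix shape mismatch")
    T = T / T.sum(axis=1, keepdims=True)
    sig = np.broadcast_to(np.asarray(widths, dtype=float), (n_states,))
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.integers(n_states)
    for t in range(1, n_frames):
        states[t] = rng.choice(n_states, p=T[states[t - 1]])
    centers = np.asarray(basins, dtype=float)[:n_states]

    def emit(which):
        c = centers[states, which][:, None]
        s = sig[states][:, None]
        raw = rng.normal(0.0, 1.0, size=(n_frames, n_residues))
        raw = np.clip(raw, -3.0, 3.0) * s + c
        wrapped = raw % 360.0            # [0, 360)
        wrapped[wrapped > 180.0] -= 360.0  # -> (-180, 180]
        return wrapped

    traj = DihedralTrajectory(emit(0), emit(1), stride=stride, label="synthetic")
    if return_states:
        return traj, states
    return traj


def gen_itc(
    n: float = 0.9,
    kd: float = 18.5e-6,
    dh: float = 0.2,
    scheme: ITCTitration | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> ITCTitration:
    """One-site Wiseman thermogram; ``noise`` is the per-injection Gaussian
    SD as a fraction of that injection's heat.  The default scheme is
    18 × 15 µL injections at 25 °C."""
    rng = np.random.default_rng(seed)
    scheme = scheme if scheme is not None else default_scheme()
    q = one_site_heats(n, 1.0 / kd, dh, scheme)
    if noise > 0:
        q = q + rng.normal(0.0, 1.0, size=q.shape) * noise * np.abs(q)
    return ITCTitration(scheme.cell_volume, scheme.cell_conc,
                        scheme.syringe_conc, scheme.injection_volumes.copy(),
                        q, scheme.temperature)


class ToyComplex(NamedTuple):
    model: CoordinateModel          # planted host+guest pose
    restraints: RestraintSet        # generated from the planted pose
    flexible: dict                  # flexible selection for the annealer


def gen_toy_complex(
    host_length: int = 20,
    guest_sequence: str = "AEALAKLA",
    n_distance: int = 12,
    seed: int = 0,
    distance_margin: float = 0.5,
    dihedral_width: float = 10.0,
) -> ToyComplex:
    """Planted-truth fixture: a helical guest peptide docked against a fixed
    helical host, plus the restraint set derived from the planted pose
    (intermolecular CA–CA distances, guest helical hydrogen bonds, guest
    dihedrals, host positional tethers).

    Every generated restraint is satisfied at zero violation by the planted
    pose, by construction.
    """
    rng = np.random.default_rng(seed)
    host = build_chain("A" * host_length, conformation="helix", chain_id="A")
    guest = build_chain(guest_sequence, conformation="helix", chain_id="B")

    host_ca = host.coords[host.atom_name == "CA"]
    axis = np.linalg.svd(host_ca - host_ca.mean(axis=0))[2][0]
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    guest_ca = guest.coords[guest.atom_name == "CA"]
    offset = (host_ca.mean(axis=0) + 10.0 * perp + 1.0 * axis
              - guest_ca.mean(axis=0))
    guest.coords = guest.coords + offset

    complex_model = merge_models(host, guest)

    # intermolecular CA-CA distance restraints from the planted pose
    g_res = np.unique(guest.residue_index)
    h_res = np.unique(host.residue_index)
    pairs = []
    for gr in g_res:
        gi = complex_model.atom_index("B", int(gr), "CA")
        for hr in h_res:
            hi = complex_model.atom_index("A", int(hr), "CA")
            d = float(np.linalg.norm(complex_model.coords[gi]
                                     - complex_model.coords[hi]))
            if d < 16.0:
                pairs.append((int(gr), int(hr), d))
    if len(pairs) < n_distance:
        raise RuntimeError("planted pose yields too few contact pairs")
    chosen = rng.choice(len(pairs), size=n_distance, replace=False)
    distance = []
    for idx in sorted(chosen):
        gr, hr, d = pairs[idx]
        distance.append(DistanceRestraint(
            f"B/{gr}/CA", f"A/{hr}/CA", target=d,
            lower=d - distance_margin, upper=d + distance_margin,
            kind="range", provenance="NOE"))

    # guest helical hydrogen bonds, bounds around the measured distances
    for gr in g_res:
        gr = int(gr)
        if gr + 4 in g_res:
            i_o = complex_model.atom_index("B", gr, "O")
            i_n = complex_model.atom_index("B", gr + 4, "N")
            d = float(np.linalg.norm(complex_model.coords[i_o]
                                     - complex_model.coords[i_n]))
            distance.append(DistanceRestraint(
                f"B/{gr}/O", f"B/{gr + 4}/N", target=d, lower=d - 0.25,
                upper=d + 0.25, kind="range", provenance="hbond"))

    # guest dihedral restraints at the planted values
    dihedrals = []
    planted = compute_phi_psi(complex_model, "B")
    for gr, (phi, psi) in planted.items():
        if np.isfinite(phi):
            dihedrals.append(DihedralRestraint("B", gr, "phi", phi,
                                               dihedral_width))
        if np.isfinite(psi):
            dihedrals.append(DihedralRestraint("B", gr, "psi", psi,
                                               dihedral_width))

    restraints = RestraintSet(
        distance=distance,
        dihedral=dihedrals,
        positional=[PositionalRestraint("A", BACKBONE_ATOMS + ("CB",))],
    )
    flexible = {"B": [int(r) for r in g_res]}
    return ToyComplex(complex_model, restraints, flexible)


_DISPATCH = {
    "titration": gen_titration,
    "decay": gen_decay,
    "pre": gen_pre,
    "torsion": gen_torsion_traj,
    "itc": gen_itc,
    "toy_complex": gen_toy_complex,
}
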