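"""Backbone ¹⁵N spin-relaxation analysis.

Longitudinal (R1) and rotating-frame (R1ρ) decays are fitted per residue with
the three-parameter mono-exponential

    M_z(t) = M0 · exp(−R_i · t) + C

R1ρ is converted to the transverse rate R2 through the tilt angle θ between
the static field and the effective field in the rotating frame,

    R1ρ = R1 cos²θ + R2 sin²θ,    θ = arctan(ω1 / Ω),

with ω1 the spin-lock field strength and Ω the resonance offset (both
rad s⁻¹).  The steady-state ¹⁵N{¹H} NOE is the saturated/reference intensity
ratio with its error propagated from the spectral noise standard deviations.
Secondary ¹³C chemical shifts (ΔδCα − ΔδCβ) against a packaged random-coil
reference report residual helical propensity of disordered regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import lmfit

from .csp import InsufficientDataError


@dataclass(frozen=True)
class DecayCurve:
    """Per-residue relaxation decay: (delay s, intensity) points.

    Duplicate delays are legitimate replicates and kept as independent
    points.
    """

    residue_index: int
    delays: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "delays", np.asarray(self.delays, dtype=float))
        object.__setattr__(self, "intensities",
                           np.asarray(self.intensities, dtype=float))
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must align")
        if np.any(self.delays < 0):
            raise ValueError("delays must be >= 0")

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.delays))


@dataclass
class RelaxationResult:
    residue_index: int
    rate: float              # s^-1
    amplitude: float
    offset: float
    rate_stderr: float | None
    amplitude_stderr: float | None
    offset_stderr: float | None
    kind: str                # R1 | R1rho | R2_derived
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class HetNOEResult:
    residue_index: int
    noe: float
    sigma_noe: float


def _loglinear_start(t: np.ndarray, y: np.ndarray, c0: float) -> tuple[float, float]:
    """Initial (M0, R) from log-linear regression on offset-subtracted data."""
    z = y - c0
    mask = z > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(t[mask], np.log(z[mask]), 1)
        return float(np.exp(intercept)), float(max(-slope, 1e-6))
    return float(max(z.max(), 1e-12)), 1.0


def fit_monoexponential(curve: DecayCurve, fix_offset: bool = False,
                        kind: str = "R1") -> RelaxationResult:
    """Nonlinear least-squares fit of M_z(t) = M0·exp(−R·t) + C.

    The offset C is free by default; ``fix_offset`` pins it at 0.  Data that
    do not decay (fitted R ≤ 0 or unidentifiable) are flagged
    ``converged=False`` rather than silently returned.
    """
    need = 3 if fix_offset else 4
    if curve.n_distinct < need:
        raise InsufficientDataError(
            f"need >= {need} distinct delays, got {curve.n_distinct}"
        )
    t, y = curve.delays, curve.intensities
    c0 = 0.0 if fix_offset else float(min(y.min(), 0.0))
    m0, r0 = _loglinear_start(t, y, c0)

    params = lmfit.Parameters()
    params.add("M0", value=m0)
    params.add("R", value=r0)
    params.add("C", value=c0, vary=not fix_offset)

    def residual(p):
        return p["M0"].value * np.exp(-p["R"].value * t) + p["C"].value - y

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = lmfit.minimize(residual, params, method="leastsq")
    rate = float(out.params["R"].value)
    stderr = lambda n: (float(out.params[n].stderr)
                        if out.params[n].stderr is not None else None)
    converged = bool(out.success) and rate > 0 and stderr("R") is not None
    msg = "" if converged else "non-decaying or unidentifiable data"
    return RelaxationResult(
        residue_index=curve.residue_index,
        rate=rate,
        amplitude=float(out.params["M0"].value),
        offset=float(out.params["C"].value),
        rate_stderr=stderr("R"),
        amplitude_stderr=stderr("M0"),
        offset_stderr=stderr("C") if not fix_offset else 0.0,
        kind=kind, converged=converged, message=msg,
    )


class ExponentialDecayModel:
    """Model/fit wrapper around :func:`fit_monoexponential`."""

    def __init__(self, curve: DecayCurve, fix_offset: bool = False, kind: str = "R1"):
        self.curve = curve
        self.fix_offset = fix_offset
        self.kind = kind

    def fit(self) -> RelaxationResult:
        return fit_monoexponential(self.curve, self.fix_offset, self.kind)


def tilt_angle(omega_offset: float, omega1: float,
               legacy_form: bool = False) -> float:
    """Tilt angle θ of the effective field, radians in (0, π/2].

    ``θ = arctan(ω1/Ω)``; zero offset gives π/2 (on-resonance spin lock).
    ``legacy_form=True`` evaluates the literal arctan(1/Ω) variant for
    comparison with legacy analyses; it is dimensionally inconsistent and
    not recommended.
    """
    if legacy_form:
        if omega_offset == 0:
            return np.pi / 2
        return float(np.arctan(1.0 / abs(omega_offset)))
    if omega1 <= 0:
        raise ValueError("spin-lock field strength omega1 must be positive")
    return float(np.arctan2(omega1, abs(omega_offset)))


def r1rho_to_r2(r1rho: float, r1: float, theta: float) -> float:
    """Transverse rate from the rotating-frame rate:
    R2 = (R1ρ − R1·cos²θ) / sin²θ.

    A negative result signals inconsistent inputs and is returned with a
    warning rather than raised.
    """
    if not 0 < theta <= np.pi / 2:
        raise ZeroDivisionError("tilt angle must lie in (0, pi/2]")
    s2 = np.sin(theta) ** 2
    r2 = (r1rho - r1 * np.cos(theta) ** 2) / s2
    if r2 < 0:
        warnings.warn(
            f"derived R2 = {r2:.3f} s^-1 is negative: inconsistent R1/R1rho/theta",
            stacklevel=2,
        )
    return float(r2)


def het_noe(i_sat: float, i_ref: float,
            sigma_sat: float, sigma_ref: float,
            residue_index: int = 0) -> HetNOEResult:
    """¹⁵N{¹H} NOE = I_sat/I_ref with first-order error propagation:

    σ_NOE = sqrt( (σ_sat/I_ref)² + (I_sat·σ_ref/I_ref²)² )
    """
    if i_ref == 0:
        raise ValueError("reference intensity must be nonzero")
    noe = i_sat / i_ref
    sigma = np.hypot(sigma_sat / i_ref, i_sat * sigma_ref / i_ref**2)
    return HetNOEResult(residue_index, float(noe), float(abs(sigma)))


#: Random-coil ¹³Cα/¹³Cβ chemical shifts (ppm), neighbor-uncorrected
#: reference values for the 20 standard residues (Cys reduced); Gly has no
#: Cβ and contributes through Cα only.
RANDOM_COIL_CACB: dict[str, tuple[float, float | None]] = {
    "A": (52.5, 19.1), "R": (56.0, 30.9), "N": (53.1, 38.9), "D": (54.2, 41.1),
    "C": (58.2, 28.0), "Q": (55.7, 29.4), "E": (56.6, 29.9), "G": (45.1, None),
    "H": (55.0, 29.0), "I": (61.1, 38.8), "L": (55.1, 42.4), "K": (56.2, 33.1),
    "M": (55.4, 32.9), "F": (57.7, 39.6), "P": (63.3, 31.7), "S": (58.3, 63.8),
    "T": (61.8, 69.8), "W": (57.5, 29.6), "Y": (57.9, 38.8), "V": (62.2, 32.9),
}


def secondary_shifts(
    observed: Sequence[tuple[int, str, float, float | None]],
    random_coil: Mapping[str, tuple[float, float | None]] | None = None,
) -> dict[int, float]:
    """ΔδCα − ΔδCβ secondary shifts (ppm) per residue.

    ``observed`` rows are (residue_index, one-letter code, δCα, δCβ or None).
    Positive runs indicate α-helical propensity.  The reference table is the
    packaged neighbor-uncorrected set unless a replacement mapping is given.
    """
    rc = RANDOM_COIL_CACB if random_coil is None else random_coil
    out: dict[int, float] = {}
    for res, code, ca_obs, cb_obs in observed:
        if code not in rc:
            raise ValueError(f"no random-coil reference for residue {code!r} ({res})")
        ca_rc, cb_rc = rc[code]
        scs = ca_obs - ca_rc
        if cb_obs is not None and cb_rc is not None:
            scs -= cb_obs - cb_rc
        out[int(res)] = float(scs)
    return out
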