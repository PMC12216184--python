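"""One-site isothermal titration calorimetry analysis.

The forward model is the Wiseman isotherm for a single class of binding
sites: after each injection the total macromolecule and ligand
concentrations in the cell are updated with the displaced-volume perfusion
correction (per-injection scaling by 1 − v/2V₀), the bound-complex
concentration follows from the exact root of the single-site quadratic, and
the measured heat is the binding enthalpy times the change in complex
*moles* (macromolecule moles are conserved — displaced material has already
reacted), plus a constant per-injection baseline offset.

Thermodynamic algebra (R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, 1 M standard state):

    ΔG = RT ln K_D,   −TΔS = ΔG − ΔH,   K_D = exp(ΔG/RT)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import lmfit
import pandas as pd

#: gas constant in kcal mol⁻¹ K⁻¹
R_KCAL = 1.987e-3


class UnidentifiableError(ValueError):
    """The thermogram carries no binding signal."""


@dataclass(frozen=True)
class ITCTitration:
    """One titration: instrument geometry, concentrations, and per-injection
    (volume L, measured heat cal) pairs."""

    cell_volume: float                 # L
    cell_conc: float                   # M (macromolecule)
    syringe_conc: float                # M (ligand)
    injection_volumes: np.ndarray      # (n,) L
    heats: np.ndarray                  # (n,) cal
    temperature: float = 298.15        # K

    def __post_init__(self):
        v = np.asarray(self.injection_volumes, dtype=float)
        q = np.asarray(self.heats, dtype=float)
        object.__setattr__(self, "injection_volumes", v)
        object.__setattr__(self, "heats", q)
        if self.cell_volume <= 0 or np.any(v <= 0):
            raise ValueError("volumes must be positive")
        if self.cell_conc < 0 or self.syringe_conc < 0:
            raise ValueError("concentrations must be >= 0")
        if v.shape != q.shape:
            raise ValueError("injection volumes and heats must align")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def molar_ratios(self) -> np.ndarray:
        """Cumulative syringe:cell molar ratio after each injection."""
        m, x, _ = _evolve_concentrations(self)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(m > 0, x / m, np.inf)


def default_scheme(cell_volume: float = 1.4e-3, cell_conc: float = 50e-6,
                   syringe_conc: float = 500e-6, n_injections: int = 18,
                   injection_volume: float = 15e-6,
                   temperature: float = 298.15) -> ITCTitration:
    """The measurement scheme used throughout: 18 × 15 µL injections at
    25 °C into a 1.4 mL cell."""
    v = np.full(n_injections, injection_volume)
    return ITCTitration(cell_volume, cell_conc, syringe_conc, v,
                        np.zeros(n_injections), temperature)


def _evolve_concentrations(t: ITCTitration):
    """Per-injection cell concentrations under the perfusion approximation.

    Each injection of volume v scales existing concentrations by
    (1 − v/2V₀) and adds ligand at (v/V₀)·syringe_conc scaled the same way.
    Returns (M, X, dilution factors), each (n,)."""
    v0 = t.cell_volume
    m = np.empty(t.n_injections)
    x = np.empty(t.n_injections)
    f = np.empty(t.n_injections)
    mc, xc = t.cell_conc, 0.0
    for i, v in enumerate(t.injection_volumes):
        d = 1.0 - v / (2.0 * v0)
        mc = mc * d
        xc = (xc + t.syringe_conc * v / v0) * d
        m[i], x[i], f[i] = mc, xc, d
    return m, x, f


def _complex_conc(m, x, ka):
    """Exact single-site quadratic root for [PL] given totals and K_a."""
    kd = 1.0 / ka
    b = m + x + kd
    return 0.5 * (b - np.sqrt(b * b - 4.0 * m * x))


def one_site_heats(n: float, ka: float, dh: float, titration: ITCTitration,
                   offset: float = 0.0) -> np.ndarray:
    """Predicted per-injection heats (cal) of the one-site model.

    ``n`` is the stoichiometry (binding-competent fraction of the
    macromolecule), ``ka`` the association constant (M⁻¹), ``dh`` the molar
    binding enthalpy (kcal/mol; heats come out in cal via ×1000).
    Macromolecule moles are conserved at cell_conc·V₀; the effective volume
    implied by the perfusion dilution tracks complex moles so that the
    cumulative heat at saturation equals n·ΔH·[cell]₀·V₀.
    """
    if ka <= 0:
        raise ValueError("K_a must be positive")
    m, x, _ = _evolve_concentrations(titration)
    v0 = titration.cell_volume
    # effective volume conserving macromolecule moles under dilution
    with np.errstate(divide="ignore", invalid="ignore"):
        v_eff = np.where(m > 0, titration.cell_conc * v0 / m, v0)
    pl = _complex_conc(n * m, x, ka)
    moles = pl * v_eff
    dmoles = np.diff(moles, prepend=0.0)
    return dh * 1000.0 * dmoles + offset


@dataclass
class ITCFitResults:
    """One-site fit with derived thermodynamics.

    Invariants: K_a > 0; ΔG = ΔH + (−TΔS); K_D = exp(ΔG/RT).
    """

    n: float
    ka: float                       # M^-1
    dh: float                       # kcal/mol
    offset: float                   # cal per injection
    n_stderr: float | None
    ka_stderr: float | None
    dh_stderr: float | None
    offset_stderr: float | None
    temperature: float
    c_value: float
    residuals: np.ndarray
    low_confidence: bool

    @property
    def kd(self) -> float:
        return 1.0 / self.ka

    @property
    def kd_stderr(self) -> float | None:
        return self.ka_stderr / self.ka**2 if self.ka_stderr else None

    @property
    def dg(self) -> float:
        return R_KCAL * self.temperature * np.log(self.kd)

    @property
    def minus_tds(self) -> float:
        return self.dg - self.dh

    def summary(self) -> str:
        def fmt(v, s, unit=""):
            out = f"{v:10.4g}"
            if s is not None:
                out += f" +/- {s:.2g}"
            return out + f" {unit}"

        lines = [
            "One-site ITC fit",
            "=" * 46,
            f"n (stoichiometry)  {fmt(self.n, self.n_stderr)}",
            f"K_D                {fmt(self.kd * 1e6, (self.kd_stderr or 0) * 1e6 or None, 'uM')}",
            f"dH                 {fmt(self.dh, self.dh_stderr, 'kcal/mol')}",
            f"dG                 {self.dg:10.4g} kcal/mol",
            f"-TdS               {self.minus_tds:10.4g} kcal/mol",
            f"baseline offset    {fmt(self.offset * 1e6, None, 'ucal/inj')}",
            f"c-value            {self.c_value:10.3g}"
            + ("   [low confidence: c outside 1..1000]" if self.low_confidence else ""),
            f"T                  {self.temperature:10.2f} K",
        ]
        return "\n".join(lines)


class OneSiteBindingModel:
    """Wiseman one-site isotherm model for an ITC titration."""

    def __init__(self, titration: ITCTitration, discard_first: bool = False):
        if titration.n_injections < 6:
            raise ValueError("need at least 6 injections")
        self.titration = titration
        self.discard_first = discard_first

    def _initial_guess(self) -> tuple[float, float, float]:
        t = self.titration
        q = t.heats
        ratios = t.molar_ratios()
        # inflection: steepest change of heat vs molar ratio
        dq = np.abs(np.diff(q))
        n0 = float(np.clip(ratios[1:][np.argmax(dq)], 0.2, 5.0))
        moles_1 = t.syringe_conc * t.injection_volumes[0]
        dh0 = float(q[0] / 1000.0 / max(moles_1, 1e-15))
        ka0 = 10.0 / max(t.cell_conc, 1e-12)  # start at c = 10·n
        return n0, ka0, dh0

    def fit(self) -> ITCFitResults:
        t = self.titration
        q = t.heats.copy()
        use = np.ones(t.n_injections, dtype=bool)
        if self.discard_first:
            use[0] = False
        if np.allclose(q[use] - q[use].mean(), 0.0, atol=1e-15) or \
                t.syringe_conc == 0 or t.cell_conc == 0:
            raise UnidentifiableError("flat thermogram: no binding signal")
        n0, ka0, dh0 = self._initial_guess()
        params = lmfit.Parameters()
        params.add("n", value=n0, min=1e-3, max=20)
        params.add("log_ka", value=np.log(ka0), min=np.log(1e-2), max=np.log(1e15))
        params.add("dh", value=dh0 if abs(dh0) > 1e-12 else 1e-3)
        params.add("offset", value=0.0)

        def residual(p):
            pred = one_site_heats(p["n"].value, np.exp(p["log_ka"].value),
                                  p["dh"].value, t, p["offset"].value)
            return (pred - q)[use]

        out = lmfit.minimize(residual, params, method="leastsq")
        if not np.all(np.isfinite(out.residual)):
            raise UnidentifiableError(f"fit failed: {out.message}")
        pn = out.params
        ka = float(np.exp(pn["log_ka"].value))
        ka_stderr = (ka * float(pn["log_ka"].stderr)
                     if pn["log_ka"].stderr is not None else None)
        c = pn["n"].value * ka * t.cell_conc
        return ITCFitResults(
            n=float(pn["n"].value), ka=ka, dh=float(pn["dh"].value),
            offset=float(pn["offset"].value),
            n_stderr=(float(pn["n"].stderr) if pn["n"].stderr is not None else None),
            ka_stderr=ka_stderr,
            dh_stderr=(float(pn["dh"].stderr) if pn["dh"].stderr is not None else None),
            offset_stderr=(float(pn["offset"].stderr)
                           if pn["offset"].stderr is not None else None),
            temperature=t.temperature, c_value=float(c),
            residuals=np.asarray(out.residual),
            low_confidence=not (1.0 <= c <= 1000.0),
        )


def fit_one_site(titration: ITCTitration, **kwargs) -> ITCFitResults:
    """Convenience wrapper: build the one-site model and fit."""
    return OneSiteBindingModel(titration, **kwargs).fit()


def thermo_complete(kd: float, dh: float, temperature: float = 298.15
                    ) -> tuple[float, float]:
    """(ΔG, −TΔS) in kcal/mol from K_D (M) and ΔH (kcal/mol)."""
    if kd <= 0:
        raise ValueError("K_D must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dg = R_KCAL * temperature * np.log(kd)
    return float(dg), float(dg - dh)


def kd_from_enthalpy_entropy(dh: float, minus_tds: float,
                             temperature: float = 298.15) -> float:
    """K_D (M) implied by ΔH and −TΔS (kcal/mol): exp((ΔH + (−TΔS))/RT)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dg = dh + minus_tds
    return float(np.exp(dg / (R_KCAL * temperature)))


@dataclass(frozen=True)
class ThermoRow:
    """One published thermodynamic record for consistency auditing."""

    label: str
    kd_um: float
    kd_sd_um: float | None
    dh: float
    minus_tds: float


def audit_thermo_table(rows: Sequence[ThermoRow], temperature: float = 298.15,
                       rel_tol: float = 0.15) -> pd.DataFrame:
    """Internal-consistency audit of (K_D, ΔH, −TΔS) triplets.

    Recomputes K_D from ΔH and −TΔS; a row is consistent when the recomputed
    value falls within the stated SD of the printed K_D, or within
    ``rel_tol`` relative where the SD is tighter than rounding permits.
    Inconsistent rows are reported as such — never adjusted.
    """
    records = []
    for r in rows:
        kd_calc = kd_from_enthalpy_entropy(r.dh, r.minus_tds, temperature) * 1e6
        dev = abs(kd_calc - r.kd_um)
        tol = max(r.kd_sd_um or 0.0, rel_tol * r.kd_um)
        records.append({
            "label": r.label, "kd_printed_um": r.kd_um,
            "kd_recomputed_um": kd_calc, "abs_dev_um": dev,
            "tolerance_um": tol, "consistent": dev <= tol,
        })
    return pd.DataFrame(records)


def plot_isotherm(results: ITCFitResults, titration: ITCTitration, ax=None):
    """Measured and fitted normalized heats versus molar ratio."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ratios = titration.molar_ratios()
    per_mole = titration.syringe_conc * titration.injection_volumes * 1000.0
    pred = one_site_heats(results.n, results.ka, results.dh, titration,
                          results.offset)
    ax.plot(ratios, titration.heats / per_mole, "o", label="measured")
    ax.plot(ratios, pred / per_mole, "-", label="one-site fit")
    ax.set_xlabel("molar ratio")
    ax.set_ylabel("kcal per mol of injectant")
    ax.legend()
    return ax
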