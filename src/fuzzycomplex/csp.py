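"""Chemical shift perturbation (CSP) mapping and fast-exchange titration fits.

The CSP statistic for an amide cross-peak is the weighted Euclidean shift
distance

    CSP = sqrt(ΔδH² + ΔδN²/7)

with the ¹⁵N change down-weighted by the conventional factor accounting for
the wider nitrogen shift range.  Under fast exchange the observed peak
position is the population-weighted average of the free and bound states, so
per-residue trajectories across a titration series trace straight lines whose
extent follows the single-site binding isotherm; a global dissociation
constant is obtained by least squares over selected residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import PeakTable

#: nitrogen scaling divisor inside the square root
NITROGEN_WEIGHT = 7.0


class AlignmentError(ValueError):
    """Peak tables share no scoreable residues."""


class InsufficientDataError(ValueError):
    pass


class UnidentifiableError(ValueError):
    """The data carry no information on the requested parameter."""


def compute_csp(delta_delta_H: float, delta_delta_N: float) -> float:
    """Scalar CSP (ppm) from amide ¹H and ¹⁵N shift changes (ppm)."""
    dH = np.asarray(delta_delta_H, dtype=float)
    dN = np.asarray(delta_delta_N, dtype=float)
    if not (np.all(np.isfinite(dH)) and np.all(np.isfinite(dN))):
        raise ValueError("shift changes must be finite")
    out = np.sqrt(dH**2 + dN**2 / NITROGEN_WEIGHT)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CSPRecord:
    residue_index: int
    delta_delta_H: float
    delta_delta_N: float
    csp: float
    flag: str = "ok"


@dataclass(frozen=True)
class CSPProfile:
    """Per-residue shift changes between a free and a ligand-added spectrum.

    ``records`` holds scored residues (flag ``ok``); residues that vanish or
    broaden beyond detection in the bound spectrum are listed separately in
    ``broadened`` — they mark the interface but carry no CSP value.
    """

    records: tuple[CSPRecord, ...]
    broadened: tuple[int, ...] = ()

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    @property
    def residues(self) -> np.ndarray:
        return np.array([r.residue_index for r in self.records], dtype=int)

    @property
    def values(self) -> np.ndarray:
        return np.array([r.csp for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "residue": self.residues,
                "ddH": [r.delta_delta_H for r in self.records],
                "ddN": [r.delta_delta_N for r in self.records],
                "csp": self.values,
                "flag": [r.flag for r in self.records],
            }
        )
        for res in self.broadened:
            df = pd.concat(
                [df, pd.DataFrame([{"residue": res, "ddH": np.nan, "ddN": np.nan,
                                    "csp": np.nan, "flag": "broadened"}])],
                ignore_index=True,
            )
        return df.sort_values("residue", ignore_index=True)


def csp_profile(free: PeakTable, bound: PeakTable) -> CSPProfile:
    """CSPs between a free-state and a ligand-added peak table.

    Residues scored in the free spectrum but absent/broadened/missing in the
    bound one are reported in ``broadened`` (exchange broadening at the
    interface), not as CSP values.
    """
    free_by = {e.residue_index: e for e in free if e.flag == "ok"}
    bound_by = bound.by_residue()
    if not set(free_by) & set(bound_by):
        raise AlignmentError("peak tables share no residues")
    records, broadened = [], []
    for res, fe in sorted(free_by.items()):
        be = bound_by.get(res)
        if be is None or be.flag in ("broadened", "missing"):
            broadened.append(res)
            continue
        if be.flag != "ok":
            continue
        ddH = be.delta_H - fe.delta_H
        ddN = be.delta_N - fe.delta_N
        records.append(CSPRecord(res, ddH, ddN, compute_csp(ddH, ddN)))
    if not records and not broadened:
        raise AlignmentError("peak tables share no scoreable residues")
    return CSPProfile(tuple(records), tuple(broadened))


def classify_binding_site(
    profile: CSPProfile,
    rule: str = "mean+sd",
    k: float = 1.0,
    cutoff_ppm: float | None = None,
) -> set[int]:
    """Flag putative binding-site residues from a CSP profile.

    ``rule="mean+sd"`` flags residues with CSP above mean + k·SD over all
    scored residues (default k=1); ``rule="absolute"`` uses ``cutoff_ppm``.
    """
    if len(profile) < 5:
        raise InsufficientDataError("need at least 5 scored residues")
    vals = profile.values
    if rule == "mean+sd":
        threshold = float(vals.mean() + k * vals.std(ddof=0))
    elif rule == "absolute":
        if cutoff_ppm is None:
            raise ValueError("absolute rule requires cutoff_ppm")
        threshold = float(cutoff_ppm)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return {int(r) for r, v in zip(profile.residues, vals) if v > threshold}


def single_site_bound_fraction(p_tot, l_tot, kd):
    """Fraction of labelled protein P bound, exact root of the single-site
    quadratic in total concentrations (all in the same molar units)."""
    p = np.asarray(p_tot, dtype=float)
    l = np.asarray(l_tot, dtype=float)
    if np.any(p < 0) or np.any(l < 0) or kd < 0:
        raise ValueError("concentrations and K_D must be non-negative")
    b = p + l + kd
    pl = 0.5 * (b - np.sqrt(b * b - 4.0 * p * l))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(p > 0, pl / p, 0.0)
    return np.clip(frac, 0.0, 1.0)


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered titration points: (ligand:protein ratio, PeakTable).

    The first point must be ratio 0 (free state); ratios strictly increase.
    """

    points: tuple[tuple[float, PeakTable], ...]
    labeled_species: str = "protein"
    ligand: str = "ligand"

    def __post_init__(self):
        ratios = [r for r, _ in self.points]
        if not ratios or ratios[0] != 0:
            raise ValueError("first titration point must be ratio 0")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("ratios must be strictly increasing")
        if any(r < 0 for r in ratios):
            raise ValueError("ratios must be non-negative")

    @property
    def ratios(self) -> np.ndarray:
        return np.array([r for r, _ in self.points], dtype=float)


@dataclass
class FastExchangeResults:
    """Global-K_D fit of a fast-exchange titration."""

    kd: float                      # molar
    kd_stderr: float | None
    ddmax: dict[int, float]        # per-residue CSP extrapolated to saturation (ppm)
    residues: tuple[int, ...]
    protein_conc: float
    cost: float
    n_points: int

    def summary(self) -> str:
        lines = [
            "Fast-exchange single-site titration fit",
            "=" * 42,
            f"K_D            {self.kd * 1e6:10.3f} uM"
            + (f"  +/- {self.kd_stderr * 1e6:.3f}" if self.kd_stderr else ""),
            f"[P] total      {self.protein_conc * 1e6:10.1f} uM",
            f"residues used  {len(self.residues):6d}",
            f"points         {self.n_points:6d}",
            "per-residue CSP at saturation (ppm):",
        ]
        for res in self.residues:
            lines.append(f"  {res:5d}  {self.ddmax[res]:8.4f}")
        return "\n".join(lines)


class FastExchangeTitration:
    """Fast-exchange single-site binding model for a titration series.

    Observed per-residue CSP at each point is modelled as
    ``ddmax_r * f_bound(ratio)`` with the bound fraction the exact root of
    the single-site quadratic at total concentrations ``P`` and
    ``ratio * P``.  ``fit`` estimates one global K_D and per-residue ddmax.
    """

    def __init__(self, series: TitrationSeries, residues: Iterable[int] | None,
                 protein_conc: float):
        if protein_conc <= 0:
            raise ValueError("protein concentration must be positive")
        if len(series.points) < 3:
            raise InsufficientDataError("need at least 3 titration points")
        self.series = series
        self.protein_conc = float(protein_conc)
        ref = series.points[0][1]
        profiles = [csp_profile(ref, tab) for _, tab in series.points[1:]]
        common = set(profiles[0].residues)
        for p in profiles[1:]:
            common &= set(p.residues)
        if residues is not None:
            common &= set(int(r) for r in residues)
        if not common:
            raise AlignmentError("no residue scored at every titration point")
        self.residues = tuple(sorted(common))
        # csp matrix: (n_points-1, n_residues)
        self._csp = np.array(
            [[dict(zip(p.residues, p.values))[r] for r in self.residues]
             for p in profiles]
        )
        self._ratios = series.ratios[1:]

    def fit(self) -> FastExchangeResults:
        if np.allclose(self._csp, 0.0):
            raise UnidentifiableError("no shift change across the series")
        p = self.protein_conc
        ratios = self._ratios

        def model(log_kd):
            fb = single_site_bound_fraction(p, ratios * p, np.exp(log_kd))
            # optimal ddmax per residue given kd is linear least squares
            denom = float(fb @ fb)
            ddmax = (fb @ self._csp) / denom
            return fb[:, None] * ddmax[None, :], ddmax

        def resid(theta):
            pred, _ = model(theta[0])
            return (pred - self._csp).ravel()

        res = least_squares(resid, x0=[np.log(p)], method="lm")
        kd = float(np.exp(res.x[0]))
        _, ddmax = model(res.x[0])
        # delta-method stderr on kd from the 1-parameter profile
        dof = self._csp.size - 1 - len(self.residues)
        kd_stderr = None
        if dof > 0 and res.jac is not None:
            jtj = float(np.sum(res.jac**2))
            if jtj > 0:
                s2 = 2 * res.cost / dof
                kd_stderr = float(np.sqrt(s2 / jtj) * kd)
        return FastExchangeResults(
            kd=kd, kd_stderr=kd_stderr,
            ddmax={r: float(d) for r, d in zip(self.residues, ddmax)},
            residues=self.residues, protein_conc=p,
            cost=float(res.cost), n_points=len(ratios),
        )


def fit_fast_exchange_kd(series: TitrationSeries, residues=None,
                         protein_conc: float = 100e-6) -> FastExchangeResults:
    """Convenience wrapper: build the model and fit."""
    return FastExchangeTitration(series, residues, protein_conc).fit()


def competition_score(
    free: PeakTable, complexed: PeakTable, competed: PeakTable,
    residues: Iterable[int] | None = None, noise_floor: float = 0.005,
) -> float:
    """Mean fractional reversion toward the free state upon competitor addition.

    Per residue: 1 − CSP(free→competed)/CSP(free→complexed), clipped to [0, 1];
    averaged over residues whose free→complexed CSP exceeds ``noise_floor``
    (ppm).  1 means full displacement, 0 means no competition.
    """
    prof_complex = csp_profile(free, complexed)
    prof_compete = csp_profile(free, competed)
    cx = dict(zip(prof_complex.residues, prof_complex.values))
    cp = dict(zip(prof_compete.residues, prof_compete.values))
    shared = set(cx) & set(cp)
    if residues is not None:
        shared &= set(int(r) for r in residues)
    scores = [
        float(np.clip(1.0 - cp[r] / cx[r], 0.0, 1.0))
        for r in sorted(shared) if cx[r] > noise_floor
    ]
    if not scores:
        raise InsufficientDataError(
            "no residue with free->complexed CSP above the noise floor"
        )
    return float(np.mean(scores))


def plot_csp_profile(profile: CSPProfile, ax=None, threshold: float | None = None):
    """Bar plot of per-residue CSPs; broadened residues marked at the top."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(profile.residues, profile.values, color="0.4")
    if threshold is not None:
        ax.axhline(threshold, ls="--", color="tab:red", lw=1)
    top = max(profile.values, default=0.1) * 1.05
    for res in profile.broadened:
        ax.plot(res, top, marker="v", color="tab:orange")
    ax.set_xlabel("residue")
    ax.set_ylabel("CSP (ppm)")
    return ax
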