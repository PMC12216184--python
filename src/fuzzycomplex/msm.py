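"""Markov state modelling of backbone-torsion dynamics.

The pipeline mirrors the standard conformational-dynamics workflow: backbone
(φ, ψ) torsions are made periodicity-safe by (sin, cos) featurisation,
reduced with time-lagged independent component analysis (tICA), discretised
into microstates with k-means, and summarised as a Markov state model at a
fixed lag time.  The reversible transition-matrix estimator is the usual
maximum-likelihood fixed-point iteration on the symmetrised count matrix,
which guarantees detailed balance with respect to the stationary
distribution.  Validation is by the Chapman–Kolmogorov test (model
propagated to multiples of the lag versus models re-estimated there, with
block-bootstrap uncertainty bands), metastable coarse-graining by PCCA+
(inner-simplex algorithm on the dominant eigenvectors), and free-energy
surfaces as −kT·ln of the stationary-weighted histogram over the leading
tICA coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans


class DisconnectedWarning(UserWarning):
    pass


@dataclass(frozen=True)
class DihedralTrajectory:
    """Frames × residues table of backbone torsions in degrees (−180, 180]."""

    phi: np.ndarray     # (n_frames, n_residues)
    psi: np.ndarray
    stride: float = 1.0  # physical time per frame
    label: str = ""

    def __post_init__(self):
        phi = np.asarray(self.phi, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        object.__setattr__(self, "phi", np.atleast_2d(phi))
        object.__setattr__(self, "psi", np.atleast_2d(psi))
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must have identical shape")
        if self.phi.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        for name, a in (("phi", self.phi), ("psi", self.psi)):
            if np.any(a <= -180.0) or np.any(a > 180.0):
                raise ValueError(f"{name} angles must lie in (-180, 180]")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]


def featurize(traj: DihedralTrajectory) -> np.ndarray:
    """(sin, cos) features per torsion — continuous across the ±180° wrap.

    Returns (n_frames, 4·n_residues): for each residue the columns
    (sin φ, cos φ, sin ψ, cos ψ)."""
    rad_phi = np.radians(traj.phi)
    rad_psi = np.radians(traj.psi)
    feats = np.empty((traj.n_frames, 4 * traj.phi.shape[1]))
    feats[:, 0::4] = np.sin(rad_phi)
    feats[:, 1::4] = np.cos(rad_phi)
    feats[:, 2::4] = np.sin(rad_psi)
    feats[:, 3::4] = np.cos(rad_psi)
    return feats


@dataclass
class TICAResult:
    components: np.ndarray   # (n_features, k) eigenvectors, columns
    eigenvalues: np.ndarray  # (k,) autocorrelations at the lag, descending
    projection: np.ndarray   # (n_frames, k) mean-free projected coordinates
    lag: int


def tica(features: np.ndarray, lag: int, n_components: int | None = None,
         epsilon: float = 1e-10) -> TICAResult:
    """Time-lagged independent component analysis.

    Solves the generalised eigenproblem of the symmetrised lag-τ covariance
    against the instantaneous covariance (regularised by ``epsilon·trace`` on
    the diagonal).  Eigenvalues are clipped to [−1, 1] and sorted
    descending; projections are mean-free.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if lag >= n / 2:
        raise ValueError("lag must be < n_frames/2")
    X = X - X.mean(axis=0)
    A, B = X[:-lag], X[lag:]
    m = n - lag
    c0 = 0.5 * (A.T @ A + B.T @ B) / m
    ct = 0.5 * (A.T @ B + B.T @ A) / m
    reg = epsilon * np.trace(c0)
    rank = np.linalg.matrix_rank(c0)
    if rank < c0.shape[0]:
        warnings.warn("rank-deficient covariance: regularised", stacklevel=2)
    c0 = c0 + reg * np.eye(c0.shape[0])
    vals, vecs = scipy.linalg.eigh(ct, c0)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], -1.0, 1.0), vecs[:, order]
    if n_components is not None:
        vals, vecs = vals[:n_components], vecs[:, :n_components]
    proj = X @ vecs
    proj = proj - proj.mean(axis=0)
    return TICAResult(vecs, vals, proj, lag)


def kmeans_discretize(projection: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means++ microstate assignment, deterministic for a fixed seed."""
    X = np.asarray(projection, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k > X.shape[0]:
        raise ValueError("k must not exceed the number of frames")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(X)


def count_matrix(dtrajs: Sequence[np.ndarray] | np.ndarray, lag: int,
                 n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the lag."""
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    C = np.zeros((n_states, n_states))
    for d in dtrajs:
        d = np.asarray(d, dtype=int)
        if len(d) > lag:
            np.add.at(C, (d[:-lag], d[lag:]), 1.0)
    return C


def _largest_connected_set(C: np.ndarray) -> np.ndarray:
    adj = C > 0
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    if n_comp == 1:
        return np.arange(C.shape[0])
    sizes = np.bincount(labels, weights=C.sum(axis=1) + C.sum(axis=0))
    keep = np.flatnonzero(labels == np.argmax(sizes))
    dropped = sorted(set(range(C.shape[0])) - set(keep.tolist()))
    warnings.warn(
        f"count matrix disconnected; restricting to largest set, dropping "
        f"states {dropped}", DisconnectedWarning, stacklevel=3)
    return keep


def _reversible_mle(C: np.ndarray, tol: float = 1e-12,
                    max_iter: int = 100000) -> np.ndarray:
    """Maximum-likelihood reversible transition matrix (fixed-point)."""
    Csym = C + C.T
    c_i = C.sum(axis=1)
    x = Csym / Csym.sum()
    x_i = x.sum(axis=1)
    for _ in range(max_iter):
        denom = c_i[:, None] / x_i[:, None] + c_i[None, :] / x_i[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = Csym / denom
        x_new[Csym == 0] = 0.0
        x_new /= x_new.sum()
        xi_new = x_new.sum(axis=1)
        if np.max(np.abs(xi_new - x_i)) < tol:
            x, x_i = x_new, xi_new
            break
        x, x_i = x_new, xi_new
    return x / x.sum(axis=1)[:, None]


@dataclass
class MSMModel:
    """Estimated Markov state model.

    Invariants (asserted on construction): rows of T sum to 1, entries are
    non-negative, πT = π, and — for reversible estimation — detailed
    balance π_i T_ij = π_j T_ji.
    """

    transition_matrix: np.ndarray
    lag: int
    stationary: np.ndarray
    active_set: np.ndarray          # microstate labels kept
    reversible: bool
    stride: float = 1.0
    memberships: np.ndarray | None = None  # PCCA+ result, filled by pcca()

    def __post_init__(self):
        T = self.transition_matrix
        assert np.all(T >= -1e-15), "negative transition probability"
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10), "rows must sum to 1"
        pi = self.stationary
        assert np.allclose(pi @ T, pi, atol=1e-8), "pi is not stationary"
        if self.reversible:
            flux = pi[:, None] * T
            assert np.allclose(flux, flux.T, atol=1e-8), "detailed balance violated"

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def lag_time(self) -> float:
        return self.lag * self.stride

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        vals = np.linalg.eigvals(self.transition_matrix)
        vals = vals[np.argsort(-np.abs(vals))]
        vals = np.real_if_close(vals, tol=1e6)
        return vals[:k] if k is not None else vals

    def implied_timescales(self, k: int = 5) -> np.ndarray:
        """t_i = −lag / ln λ_i for the leading non-unit eigenvalues (in
        physical time units)."""
        vals = np.real(self.eigenvalues(k + 1))[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = -self.lag_time / np.log(np.abs(vals))
        return ts

    def summary(self) -> str:
        ts = self.implied_timescales(min(4, self.n_states - 1))
        lines = [
            "Markov state model",
            "=" * 40,
            f"microstates       {self.n_states}",
            f"lag               {self.lag} frames ({self.lag_time:g} time units)",
            f"estimator         {'reversible MLE' if self.reversible else 'nonreversible'}",
            "implied timescales: " + ", ".join(f"{t:.3g}" for t in ts),
        ]
        return "\n".join(lines)


def estimate_msm(dtrajs, lag: int, mode: str = "reversible",
                 stride: float = 1.0) -> MSMModel:
    """Estimate an MSM at the given lag (frames).

    Sliding-window counts; restriction to the largest strongly connected
    set; reversible maximum-likelihood or simple row-normalised estimation;
    stationary distribution from the leading left eigenvector.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("reversible", "nonreversible"):
        raise ValueError("mode must be 'reversible' or 'nonreversible'")
    C = count_matrix(dtrajs, lag)
    if C.sum() == 0:
        raise ValueError("no transition observed at this lag")
    keep = _largest_connected_set(C)
    C = C[np.ix_(keep, keep)]
    if mode == "reversible":
        T = _reversible_mle(C)
    else:
        T = C / C.sum(axis=1, keepdims=True)
    vals, vecs = scipy.linalg.eig(T, left=True, right=False)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    # polish stationarity to the asserted tolerance
    for _ in range(100):
        pi_new = pi @ T
        pi_new /= pi_new.sum()
        if np.max(np.abs(pi_new - pi)) < 1e-14:
            pi = pi_new
            break
        pi = pi_new
    return MSMModel(T, lag, pi, keep, mode == "reversible", stride)


class MarkovStateModel:
    """statsmodels-style front end: configure, then ``fit`` discrete
    trajectories."""

    def __init__(self, lag: int, mode: str = "reversible", stride: float = 1.0):
        self.lag = lag
        self.mode = mode
        self.stride = stride

    def fit(self, dtrajs) -> MSMModel:
        return estimate_msm(dtrajs, self.lag, self.mode, self.stride)


# ---------------------------------------------------------------------------
# PCCA+


def _index_search(evecs: np.ndarray) -> np.ndarray:
    """Inner-simplex vertex search of PCCA+."""
    n, m = evecs.shape
    index = np.zeros(m, dtype=int)
    ortho = evecs.copy()
    index[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = ortho - ortho[index[0]]
    for j in range(1, m):
        norms = np.linalg.norm(ortho, axis=1)
        index[j] = int(np.argmax(norms))
        v = ortho[index[j]] / norms[index[j]]
        ortho = ortho - np.outer(ortho @ v, v)
    return index


def pcca(model: MSMModel, n_metastable: int) -> np.ndarray:
    """PCCA+ fuzzy memberships (n_states × n_metastable), rows in [0, 1]
    summing to 1; also stored on the model.  Requires a reversible model."""
    if not model.reversible:
        raise ValueError("PCCA+ requires a reversible transition matrix")
    if not 1 <= n_metastable <= model.n_states:
        raise ValueError("n_metastable out of range")
    pi = model.stationary
    T = model.transition_matrix
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    vals, phis = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1][:n_metastable]
    psi = phis[:, order] / sqrt_pi[:, None]   # right eigenvectors of T
    if n_metastable == model.n_states:
        chi = np.eye(model.n_states)
    else:
        vertices = _index_search(psi)
        A = np.linalg.inv(psi[vertices])
        chi = psi @ A
        chi = np.clip(chi, 0.0, None)
        chi = chi / chi.sum(axis=1, keepdims=True)
    model.memberships = chi
    return chi


def crisp_assignment(memberships: np.ndarray) -> np.ndarray:
    return np.argmax(memberships, axis=1)


# ---------------------------------------------------------------------------
# Chapman–Kolmogorov test


@dataclass
class CKTestResult:
    factors: tuple[int, ...]
    predicted: dict[int, np.ndarray]   # set-level P(kτ) from T(τ)^k
    estimated: dict[int, np.ndarray]   # set-level P from re-estimation at kτ
    lower: dict[int, np.ndarray]
    upper: dict[int, np.ndarray]
    passed: bool
    confidence: float


def _set_transition(T: np.ndarray, pi: np.ndarray, sets: np.ndarray,
                    n_sets: int) -> np.ndarray:
    """Stationary-weighted coarse-graining of T onto crisp metastable sets."""
    P = np.zeros((n_sets, n_sets))
    for a in range(n_sets):
        ia = sets == a
        wa = pi[ia]
        if wa.sum() == 0:
            P[a, a] = 1.0
            continue
        for b in range(n_sets):
            ib = sets == b
            P[a, b] = float(wa @ T[np.ix_(ia, ib)].sum(axis=1) / wa.sum())
    return P


def ck_test(model: MSMModel, dtrajs, factors: Sequence[int] = (2, 3, 4),
            n_metastable: int | None = None, confidence: float = 0.95,
            n_bootstrap: int = 100, seed: int = 0) -> CKTestResult:
    """Chapman–Kolmogorov test on metastable-set transition probabilities.

    Compares T(τ)^k coarse-grained onto the PCCA+ crisp sets against models
    re-estimated at k·τ; uncertainty bands on the re-estimates come from a
    trajectory block bootstrap.  The test passes iff every predicted
    set-to-set probability lies inside its band at the stated confidence.
    """
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    n_frames = sum(len(d) for d in dtrajs)
    if max(factors) * model.lag >= n_frames / 2:
        raise ValueError("trajectories too short for the requested factors")
    if n_metastable is None:
        n_metastable = 2 if model.memberships is None else model.memberships.shape[1]
    if model.memberships is None or model.memberships.shape[1] != n_metastable:
        pcca(model, n_metastable)
    sets = crisp_assignment(model.memberships)
    rng = np.random.default_rng(seed)
    alpha = 1.0 - confidence

    predicted, estimated, lower, upper = {}, {}, {}, {}
    passed = True
    # blocks long enough to carry many transitions at the largest test lag
    block = 10 * model.lag * max(factors)
    for k in factors:
        Tk = np.linalg.matrix_power(model.transition_matrix, k)
        predicted[k] = _set_transition(Tk, model.stationary, sets, n_metastable)
        mk = estimate_msm(
            [_restrict(d, model.active_set) for d in dtrajs], model.lag * k,
            mode="reversible" if model.reversible else "nonreversible")
        est = _embed_sets(mk, sets, n_metastable, model.n_states)
        estimated[k] = est
        boots = []
        for _ in range(n_bootstrap):
            bd = _block_resample(dtrajs, block, rng)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", DisconnectedWarning)
                    mb = estimate_msm(
                        [_restrict(d, model.active_set) for d in bd],
                        model.lag * k,
                        mode="reversible" if model.reversible else "nonreversible")
                boots.append(_embed_sets(mb, sets, n_metastable, model.n_states))
            except (ValueError, ZeroDivisionError):
                continue
        if boots:
            stack = np.stack(boots)
            lower[k] = np.quantile(stack, alpha / 2, axis=0)
            upper[k] = np.quantile(stack, 1 - alpha / 2, axis=0)
            if np.any(predicted[k] < lower[k] - 1e-12) or \
               np.any(predicted[k] > upper[k] + 1e-12):
                passed = False
        else:  # pragma: no cover
            lower[k] = upper[k] = estimated[k]
            passed = False
    return CKTestResult(tuple(factors), predicted, estimated, lower, upper,
                        passed, confidence)


def _restrict(d: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Relabel a discrete trajectory onto the active set (drop others)."""
    mapping = -np.ones(int(max(d.max(), active.max())) + 1, dtype=int)
    mapping[active] = np.arange(len(active))
    mapped = mapping[d]
    return mapped[mapped >= 0]


def _embed_sets(m: MSMModel, sets: np.ndarray, n_sets: int,
                n_full: int) -> np.ndarray:
    """Coarse-grain a (possibly restricted) model onto the reference sets."""
    full_sets = sets[m.active_set] if m.n_states != n_full else sets
    return _set_transition(m.transition_matrix, m.stationary, full_sets, n_sets)


def _block_resample(dtrajs: list[np.ndarray], block: int,
                    rng: np.random.Generator) -> list[np.ndarray]:
    # each resampled block is kept as its own trajectory so that no
    # spurious transitions are counted across block seams
    out = []
    for d in dtrajs:
        n = len(d)
        nblocks = max(1, n // block)
        starts = rng.integers(0, max(1, n - block), size=nblocks)
        out.extend(d[s:s + block] for s in starts)
    return out


# ---------------------------------------------------------------------------
# free-energy surfaces


@dataclass
class FreeEnergySurface:
    free_energy: np.ndarray   # (nx, ny), kT units, NaN where unobserved
    x_edges: np.ndarray
    y_edges: np.ndarray
    observed: np.ndarray      # boolean mask of populated bins

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        pc = ax.pcolormesh(xc, yc, self.free_energy.T, shading="auto", **kwargs)
        ax.figure.colorbar(pc, ax=ax, label="free energy (kT)")
        ax.set_xlabel("IC1")
        ax.set_ylabel("IC2")
        return ax


def free_energy_surface(ic1: np.ndarray, ic2: np.ndarray,
                        weights: np.ndarray | None = None,
                        bins: int | Sequence = 40,
                        kT: float = 1.0) -> FreeEnergySurface:
    """F = −kT·ln(p / p_max) over a 2-D histogram of the leading tICA
    coordinates; unobserved bins are NaN-masked rather than infinite."""
    H, xe, ye = np.histogram2d(np.asarray(ic1).ravel(), np.asarray(ic2).ravel(),
                               bins=bins, weights=weights, density=False)
    if H.sum() == 0:
        raise ValueError("no populated bin")
    observed = H > 0
    F = np.full_like(H, np.nan)
    F[observed] = -kT * np.log(H[observed] / H.max())
    return FreeEnergySurface(F, xe, ye, observed)
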