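"""WHAM free-energy surfaces from umbrella-sampling data.

The estimator is the standard binned weighted-histogram self-consistency
iteration.  ``WHAM`` is a model object built from an
:class:`UmbrellaDataset`; ``fit()`` returns a :class:`FreeEnergyResult`
carrying the surface, window free energies, block-bootstrap uncertainties
and a ``summary()`` table.  Downstream helpers extract binding free
energies, their differences, and plateau "shoulders" from 1D profiles.

Energies are in kcal/mol, distances in Angstrom, temperatures in Kelvin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

KB = 0.0019872  # kcal/mol/K


class FreeEnergyError(ValueError):
    pass


class OverlapError(FreeEnergyError):
    """Umbrella windows do not overlap enough to be combined."""


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias on the reaction coordinate.

    ``samples`` holds the biased coordinate; ``extra`` optionally carries
    co-recorded order parameters (e.g. pc0, q_f) aligned with samples.
    """

    center: float
    spring_constant: float  # kcal/mol/A^2 (full k in (k/2)(x-c)^2)
    samples: np.ndarray
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) < 1:
            raise FreeEnergyError("window needs a 1D non-empty sample series")
        if self.spring_constant < 0:
            raise FreeEnergyError("spring constant must be >= 0")
        for k, v in self.extra.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.samples.shape:
                raise FreeEnergyError(f"extra series {k!r} length mismatch")
            self.extra[k] = v

    def bias_energy(self, x):
        return 0.5 * self.spring_constant * (np.asarray(x) - self.center) ** 2


@dataclass
class UmbrellaDataset:
    """A series of umbrella windows at one temperature.

    ``coordinate`` names the biased order parameter.  ``metadata`` may
    carry analytic ground truth for synthetic datasets (consumed only by
    tests, never by the estimator).
    """

    windows: list
    temperature: float = 300.0
    coordinate: str = "r"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.windows) < 1:
            raise FreeEnergyError("dataset needs at least one window")
        if self.temperature <= 0:
            raise FreeEnergyError("temperature must be positive")

    @property
    def kt(self):
        return KB * self.temperature

    def sample_range(self):
        lo = min(w.samples.min() for w in self.windows)
        hi = max(w.samples.max() for w in self.windows)
        return lo, hi


@dataclass
class FreeEnergySurface:
    """Gridded free energy over one or two order parameters (kcal/mol).

    ``f`` is min-normalized to 0 on sampled bins and NaN on unsampled
    bins (never interpolated).  ``uncertainty`` is the block-bootstrap
    standard deviation per bin.
    """

    axes: list            # axis names
    edges: list           # list of bin-edge arrays
    f: np.ndarray
    uncertainty: np.ndarray = None
    basin_labels: dict = field(default_factory=dict)

    @property
    def centers(self):
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    def sampled_mask(self):
        return np.isfinite(self.f)


def _normalize(f):
    finite = np.isfinite(f)
    if not finite.any():
        raise FreeEnergyError("no sampled bins")
    return f - np.nanmin(f)


def _overlap_components(windows, edges):
    """Connected components of windows linked by shared occupied bins."""
    occ = [np.histogram(w.samples, bins=edges)[0] > 0 for w in windows]
    n = len(windows)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.any(occ[i] & occ[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


class WHAM:
    """Weighted-histogram estimator for an umbrella series.

    Parameters
    ----------
    dataset : UmbrellaDataset
    bins : int or array
        Bin count or explicit edges over the biased coordinate.
    tol : float
        Relative convergence tolerance on window free energies.
    max_iter : int
    n_bootstrap : int
        Block-bootstrap replicates for uncertainties (0 disables).
    """

    def __init__(self, dataset, bins=50, tol=1e-7, max_iter=100_000,
                 n_bootstrap=50, seed=0):
        self.dataset = dataset
        self.tol = tol
        self.max_iter = max_iter
        self.n_bootstrap = n_bootstrap
        self.seed = seed
        lo, hi = dataset.sample_range()
        if np.isscalar(bins):
            self.edges = np.linspace(lo, hi, int(bins) + 1)
        else:
            self.edges = np.asarray(bins, dtype=float)

    # -- core solver -------------------------------------------------------

    def _solve(self, windows, f_init=None):
        kt = self.dataset.kt
        centers = 0.5 * (self.edges[1:] + self.edges[:-1])
        n_win = len(windows)
        hist = np.array([
            np.histogram(w.samples, bins=self.edges)[0] for w in windows
        ], dtype=float)
        n_i = hist.sum(axis=1)
        if np.any(n_i == 0):
            raise FreeEnergyError("window with no samples in range")
        # bias energy of each window evaluated at bin centers
        u = np.array([w.bias_energy(centers) for w in windows])
        boltz = np.exp(-u / kt)
        f = np.zeros(n_win) if f_init is None else np.array(f_init)
        num = hist.sum(axis=0)
        for it in range(self.max_iter):
            denom = (n_i * np.exp(f / kt)) @ boltz
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(denom > 0, num / denom, 0.0)
            norm = boltz @ p
            f_new = -kt * np.log(norm)
            f_new -= f_new[0]
            if np.max(np.abs(f_new - f)) <= self.tol * max(
                    1.0, np.max(np.abs(f_new))):
                f = f_new
                break
            f = f_new
        else:
            raise FreeEnergyError(
                f"WHAM failed to converge in {self.max_iter} iterations"
            )
        with np.errstate(divide="ignore"):
            big_f = np.where(p > 0, -kt * np.log(p), np.nan)
        return _normalize(big_f), f, p

    def _check_overlap(self):
        groups = _overlap_components(self.dataset.windows, self.edges)
        if len(groups) > 1:
            raise OverlapError(
                "umbrella windows form disconnected groups "
                f"(no shared occupied bins): {groups}"
            )

    def fit(self):
        """Solve the self-consistency equations; returns FreeEnergyResult."""
        self._check_overlap()
        windows = self.dataset.windows
        f_surface, f_win, _ = self._solve(windows)
        boot = self._bootstrap(f_win)
        unc = (np.nanstd(boot, axis=0) if boot is not None
               else np.full_like(f_surface, np.nan))
        surface = FreeEnergySurface(
            axes=[self.dataset.coordinate], edges=[self.edges],
            f=f_surface, uncertainty=unc,
        )
        return FreeEnergyResult(self, surface, f_win, boot)

    def _bootstrap(self, f_win):
        if not self.n_bootstrap:
            return None
        rng = np.random.default_rng(self.seed)
        reps = []
        for _ in range(self.n_bootstrap):
            windows = []
            for w in self.dataset.windows:
                n = len(w.samples)
                # block bootstrap: resample contiguous blocks to respect
                # autocorrelation in the time series
                n_blocks = max(1, min(20, n // 50))
                block = n // n_blocks
                starts = rng.integers(0, max(1, n - block + 1), n_blocks)
                idx = np.concatenate(
                    [np.arange(s, s + block) for s in starts])[:n]
                windows.append(UmbrellaWindow(
                    w.center, w.spring_constant, w.samples[idx]))
            try:
                rep, _, _ = self._solve(windows, f_init=f_win)
            except FreeEnergyError:
                rep = np.full(len(self.edges) - 1, np.nan)
            reps.append(rep)
        return np.array(reps)


class FreeEnergyResult:
    """Result of a WHAM fit: surface, window offsets, uncertainties."""

    def __init__(self, model, surface, window_free_energies, bootstrap):
        self.model = model
        self.surface = surface
        self.window_free_energies = window_free_energies
        self.bootstrap_surfaces = bootstrap
        self.dataset = model.dataset

    def summary(self):
        import pandas as pd

        c = self.surface.centers[0]
        return pd.DataFrame({
            self.surface.axes[0]: c,
            "free_energy": self.surface.f,
            "uncertainty": self.surface.uncertainty,
        })

    # -- 2D reweighting ----------------------------------------------------

    def surface_2d(self, axis_pair, bins=(40, 40)):
        """Reweight samples onto two order parameters.

        The bias acts on the primary coordinate alone, so the converged
        window free energies of the 1D solve reweight every sample; the
        second coordinate must be present in each window's ``extra``.
        """
        ds = self.dataset
        kt = ds.kt
        name_x, name_y = axis_pair
        xs, ys, ws = [], [], []
        n_i = np.array([len(w.samples) for w in ds.windows])
        f = self.window_free_energies
        for w in ds.windows:
            x = (w.samples if name_x == ds.coordinate
                 else _extra(w, name_x))
            y = (w.samples if name_y == ds.coordinate
                 else _extra(w, name_y))
            r = w.samples
            u = np.array([wi.bias_energy(r) for wi in ds.windows])
            denom = (n_i[:, None] * np.exp((f[:, None] - u) / kt)).sum(axis=0)
            xs.append(x)
            ys.append(y)
            ws.append(1.0 / denom)
        xs, ys, ws = map(np.concatenate, (xs, ys, ws))
        bx = np.linspace(xs.min(), xs.max(), bins[0] + 1)
        by = np.linspace(ys.min(), ys.max(), bins[1] + 1)
        h, _, _ = np.histogram2d(xs, ys, bins=[bx, by], weights=ws)
        with np.errstate(divide="ignore"):
            f2 = np.where(h > 0, -kt * np.log(h), np.nan)
        return FreeEnergySurface(
            axes=[name_x, name_y], edges=[bx, by], f=_normalize(f2),
        )


def _extra(window, name):
    if name not in window.extra:
        raise FreeEnergyError(
            f"order parameter {name!r} not recorded in window"
        )
    return window.extra[name]


def wham(dataset, bins=50, tol=1e-7, max_iter=100_000, n_bootstrap=50,
         seed=0):
    """Functional front-end: fit WHAM and return the 1D FreeEnergyResult."""
    return WHAM(dataset, bins=bins, tol=tol, max_iter=max_iter,
                n_bootstrap=n_bootstrap, seed=seed).fit()


def wham_2d(dataset, axis_pair, bins=(40, 40), **kwargs):
    """2D surface over ``axis_pair`` reweighted from a 1D WHAM solve."""
    return wham(dataset, **kwargs).surface_2d(axis_pair, bins=bins)


# ---------------------------------------------------------------------------
# Binding free energy and comparisons
# ---------------------------------------------------------------------------

def split_by_sweep(dataset):
    """Split an umbrella dataset into one dataset per sampling sweep.

    Requires a ``sweep`` series in every window's extras (recorded by
    bidirectional umbrella runs).  The forward/backward discrepancy of
    any derived estimate is an honest scale for pulling hysteresis that
    within-window bootstraps cannot see.
    """
    n_sweeps = int(max(
        w.extra["sweep"].max() for w in dataset.windows)) + 1
    out = []
    for s in range(n_sweeps):
        windows = []
        for w in dataset.windows:
            mask = w.extra["sweep"] == s
            if not mask.any():
                continue
            windows.append(UmbrellaWindow(
                w.center, w.spring_constant, w.samples[mask],
                {k: v[mask] for k, v in w.extra.items() if k != "sweep"},
            ))
        out.append(UmbrellaDataset(
            windows=windows, temperature=dataset.temperature,
            coordinate=dataset.coordinate,
            metadata=dict(dataset.metadata, sweep=s),
        ))
    return out


def binding_free_energy(result, bound_region=None, unbound_region=None,
                        plateau_fraction=0.2):
    """Binding free energy from a 1D profile over the separation coordinate.

    dG = mean F over the unbound plateau - min F over the bound region.
    Defaults: bound region = whole sampled range (its minimum), unbound
    plateau = last ``plateau_fraction`` of the sampled range.  The error
    is the standard deviation of the same estimate over the bootstrap
    replicate surfaces.

    Returns (dG, error) in kcal/mol.
    """
    surface = result.surface if hasattr(result, "surface") else result
    c = surface.centers[0]
    f = surface.f
    lo, hi = c[np.isfinite(f)][[0, -1]]
    if unbound_region is None:
        unbound_region = (hi - plateau_fraction * (hi - lo), hi)
    if bound_region is None:
        bound_region = (lo, hi)

    def estimate(fv):
        inb = (c >= bound_region[0]) & (c <= bound_region[1]) & np.isfinite(fv)
        unb = (c >= unbound_region[0]) & (c <= unbound_region[1]) \
            & np.isfinite(fv)
        if not unb.any():
            raise FreeEnergyError("unbound region unsampled")
        if not inb.any():
            raise FreeEnergyError("bound region unsampled")
        return float(np.mean(fv[unb]) - np.min(fv[inb]))

    dg = estimate(f)
    err = np.nan
    boot = getattr(result, "bootstrap_surfaces", None)
    if boot is not None:
        vals = []
        for rep in boot:
            try:
                vals.append(estimate(rep))
            except FreeEnergyError:
                continue
        if len(vals) > 1:
            err = float(np.std(vals))
    return dg, err


def delta_delta_g(affinity_a, affinity_b):
    """Difference of two (value, error) affinities, errors in quadrature."""
    (ga, ea), (gb, eb) = affinity_a, affinity_b
    return ga - gb, float(np.hypot(ea, eb))


def detect_shoulder(surface, window=3.0, slope_tol=None):
    """Locate plateau 'shoulders' in a 1D free-energy profile.

    A shoulder is a local minimum of dF/dx where the derivative dips
    toward zero *without* changing sign (an inflection plateau); a true
    barrier, where dF/dx crosses zero, is reported as an extremum by the
    sign change and excluded here.

    Returns a list of shoulder locations (same units as the axis).
    """
    c = surface.centers[0]
    f = surface.f
    ok = np.isfinite(f)
    c, f = c[ok], f[ok]
    if len(c) < 8:
        raise FreeEnergyError("surface too coarse for derivative estimate")
    # smoothing scaled to the noise level (bin uncertainty), not to the
    # signal variance, so genuine plateaus survive the fit
    unc = getattr(surface, "uncertainty", None)
    sigma = 0.05
    if unc is not None and np.isfinite(unc).any():
        sigma = max(sigma, float(np.nanmedian(unc)))
    spl = UnivariateSpline(c, f, k=4, s=len(c) * sigma ** 2)
    d1 = spl.derivative(1)
    dx = np.median(np.diff(c))
    grid = np.arange(c[0] + dx, c[-1] - dx, dx / 4)
    g = d1(grid)
    if slope_tol is None:
        slope_tol = 0.5 * np.ptp(np.abs(g))
    shoulders = []
    half = max(2, int(round(window / 2 / (dx / 4))))
    for i in range(half, len(grid) - half):
        seg = g[i - half:i + half + 1]
        if g[i] != seg.min():
            continue
        if not (g[i - half] > g[i] < g[i + half]):
            continue
        # no sign change across the dip -> plateau, not a barrier
        if np.sign(g[i - half]) == np.sign(g[i + half]) != 0 \
                and abs(g[i]) < slope_tol and g[i] > -slope_tol:
            if not shoulders or grid[i] - shoulders[-1] > window:
                shoulders.append(float(grid[i]))
    return shoulders
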