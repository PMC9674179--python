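import numpy as np
import pytest

from cglandscape import free_energy as fe
from cglandscape import synthetic as syn
from cglandscape.free_energy import KB


def oracle(n_samples=5000, k_bias=2.0, seed=3, T=300.0, k_true=1.0):
    return syn.make_umbrella_oracle(
        k_true, np.linspace(-5, 5, 11), k_bias, n_samples, T=T, seed=seed)


def well_sampled_mask(ds, edges, min_count=400):
    """Bins with enough counts that the statistical error of -kT log(n)
    is well below the 0.1 kcal/mol comparison band (kT/sqrt(400) ~ 0.03
    kcal/mol)."""
    hist = sum(np.histogram(w.samples, bins=edges)[0] for w in ds.windows)
    return hist >= min_count


class TestWHAM:
    def test_recovers_analytic_harmonic_profile(self):
        ds = oracle()
        res = fe.wham(ds, bins=50)
        s = res.surface
        c = s.centers[0]
        mask = well_sampled_mask(ds, s.edges[0]) & np.isfinite(s.f)
        truth = 0.5 * c ** 2
        truth = truth - truth[mask].min()
        f = s.f - s.f[mask].min()
        assert np.abs(f[mask] - truth[mask]).max() < 0.1

    def test_single_unbiased_window_matches_histogram(self):
        rng = np.random.default_rng(1)
        kt = KB * 300.0
        samples = rng.normal(0.0, np.sqrt(kt), 50000)
        ds = fe.UmbrellaDataset(
            [fe.UmbrellaWindow(0.0, 0.0, samples)], temperature=300.0)
        res = fe.wham(ds, bins=30, n_bootstrap=0)
        s = res.surface
        hist, _ = np.histogram(samples, bins=s.edges[0])
        with np.errstate(divide="ignore"):
            direct = -kt * np.log(hist.astype(float))
        direct -= np.nanmin(direct[hist > 0])
        ok = hist > 50
        assert np.allclose(s.f[ok], direct[ok], atol=1e-9)

    def test_more_samples_reduce_bootstrap_uncertainty(self):
        u1 = fe.wham(oracle(n_samples=500, seed=5), bins=30).surface
        u2 = fe.wham(oracle(n_samples=8000, seed=5), bins=30).surface
        assert np.nanmean(u2.uncertainty) < np.nanmean(u1.uncertainty)

    def test_error_shrinks_with_samples(self):
        """Estimator consistency on the analytic oracle: error roughly
        halves when samples grow 4x (n^-1/2 rate)."""
        errs = []
        for n in (500, 8000):
            ds = oracle(n_samples=n, seed=7)
            s = fe.wham(ds, bins=30, n_bootstrap=0).surface
            c = s.centers[0]
            mask = well_sampled_mask(ds, s.edges[0], 50) & np.isfinite(s.f)
            truth = 0.5 * c ** 2
            truth = truth - truth[mask].min()
            errs.append(
                np.sqrt(np.mean((s.f[mask] - s.f[mask].min()
                                 - truth[mask]) ** 2)))
        assert errs[1] < errs[0] * 0.6

    def test_temperature_energy_rescaling_leaves_f_over_kt(self):
        """Scaling T and all energies jointly leaves F/kT invariant: the
        oracle at (k_true, T) and (2 k_true, 2T) give the same F/kT."""
        s1 = fe.wham(oracle(seed=9, k_true=1.0, T=300.0),
                     bins=np.linspace(-4, 4, 30), n_bootstrap=0).surface
        s2 = fe.wham(oracle(seed=9, k_true=2.0, T=600.0, k_bias=10.0),
                     bins=np.linspace(-4, 4, 30), n_bootstrap=0).surface
        kt1, kt2 = KB * 300, KB * 600
        ok = np.isfinite(s1.f) & np.isfinite(s2.f) \
            & (np.abs(s1.centers[0]) < 3)
        d = s1.f[ok] / kt1 - s2.f[ok] / kt2
        assert np.abs(d - d.mean()).max() < 0.4

    def test_disconnected_windows_error(self):
        ds = syn.make_umbrella_oracle(
            1.0, [-5.0, 0.0, 5.0], 400.0, 50, seed=2)
        with pytest.raises(fe.OverlapError, match="disconnected"):
            fe.wham(ds, bins=60)


class TestWHAM2D:
    def test_marginalization_matches_1d(self):
        rng = np.random.default_rng(4)
        ds = oracle(n_samples=4000)
        for w in ds.windows:
            w.extra["pc0"] = rng.normal(0, 1, len(w.samples))
        res = fe.wham(ds, bins=40, n_bootstrap=0)
        s2 = res.surface_2d(("x", "pc0"), bins=(40, 15))
        kt = ds.kt
        with np.errstate(over="ignore"):
            p2 = np.where(np.isfinite(s2.f), np.exp(-s2.f / kt), 0.0)
        marg = -kt * np.log(p2.sum(axis=1))
        marg -= np.nanmin(marg)
        f1 = np.interp(s2.centers[0], res.surface.centers[0],
                       res.surface.f)
        ok = np.isfinite(marg) & (np.abs(s2.centers[0]) < 3.0)
        dev = marg[ok] - f1[ok]
        assert np.abs(dev - dev.mean()).max() < 0.1

    def test_independent_coordinates_separable(self):
        rng = np.random.default_rng(8)
        ds = oracle(n_samples=4000)
        kt = ds.kt
        # decoupled second coordinate with its own harmonic free energy
        for w in ds.windows:
            w.extra["pc0"] = rng.normal(0, np.sqrt(kt / 2.0),
                                        len(w.samples))
        s2 = fe.wham(ds, bins=30, n_bootstrap=0).surface_2d(
            ("x", "pc0"), bins=(20, 12))
        f = s2.f
        # check additivity F(x,y) = F(x) + F(y) + c on well-sampled core
        ok = np.isfinite(f)
        core = np.ix_(
            np.nonzero(ok.sum(axis=1) > 8)[0][1:-1],
            np.nonzero(ok.sum(axis=0) > 12)[0][1:-1])
        sub = f[core]
        if np.isnan(sub).any():
            sub = np.where(np.isnan(sub), np.nanmean(sub), sub)
        fx = np.nanmean(sub, axis=1, keepdims=True)
        fy = np.nanmean(sub, axis=0, keepdims=True)
        resid = sub - fx - fy + np.nanmean(sub)
        assert np.nanstd(resid) < 0.25

    def test_unsampled_bins_flagged_not_interpolated(self):
        ds = oracle(n_samples=300)
        s2 = fe.wham(ds, bins=30, n_bootstrap=0).surface_2d(
            ("x", "x"), bins=(25, 25))
        # off-diagonal bins of (x, x) are never sampled
        assert np.isnan(s2.f[0, -1])
        assert np.isnan(s2.f[-1, 0])


def flat_plateau_surface(depth=8.0):
    edges = np.linspace(0.0, 30.0, 61)
    c = 0.5 * (edges[1:] + edges[:-1])
    f = np.full_like(c, depth)
    f[c < 6.0] = depth * (1 - np.exp(-((c[c < 6.0] - 4.0) ** 2)))
    f[np.argmin(np.abs(c - 4.0))] = 0.0
    return fe.FreeEnergySurface(axes=["r"], edges=[edges], f=f)


class TestBindingFreeEnergy:
    def test_constructed_plateau_depth(self):
        s = flat_plateau_surface(8.0)
        dg, _ = fe.binding_free_energy(s)
        assert dg == pytest.approx(8.0, abs=1e-9)

    def test_gauge_invariance(self):
        s = flat_plateau_surface(5.0)
        shifted = fe.FreeEnergySurface(axes=s.axes, edges=s.edges,
                                       f=s.f + 3.3)
        dg1, _ = fe.binding_free_energy(s)
        dg2, _ = fe.binding_free_energy(shifted)
        assert dg1 == pytest.approx(dg2, abs=1e-12)

    def test_two_well_toy_recovered_within_error(self):
        """Analytic double well sampled through the umbrella oracle
        machinery: depth difference recovered within bootstrap error."""
        rng = np.random.default_rng(11)
        kt = KB * 300.0
        delta = 1.5

        # explicit Boltzmann sampling of a piecewise double well by
        # rejection, windows along x
        def u(x):
            return np.where(x < 2.5, 0.0, delta) \
                + 4.0 * np.exp(-((x - 2.5) ** 2) / 0.08)

        windows = []
        for c in np.linspace(0, 5, 11):
            k_b = 2.0
            xs = []
            while len(xs) < 3000:
                prop = rng.normal(c, np.sqrt(kt / k_b), 6000)
                acc = rng.random(6000) < np.exp(-u(prop) / kt)
                xs.extend(prop[acc].tolist())
            windows.append(fe.UmbrellaWindow(c, k_b,
                                             np.array(xs[:3000])))
        ds = fe.UmbrellaDataset(windows, temperature=300.0,
                                coordinate="x")
        res = fe.wham(ds, bins=40)
        dg, err = fe.binding_free_energy(
            res, bound_region=(0.0, 2.0), unbound_region=(3.5, 4.5))
        assert dg == pytest.approx(delta, abs=max(3 * err, 0.15))


class TestDeltaDeltaG:
    def test_quadrature(self):
        ddg, err = fe.delta_delta_g((8.0, 0.3), (6.0, 0.4))
        assert ddg == pytest.approx(2.0)
        assert err == pytest.approx(0.5)

    def test_identical_inputs_zero(self):
        ddg, err = fe.delta_delta_g((7.0, 0.2), (7.0, 0.2))
        assert ddg == 0.0
        assert err == pytest.approx(np.sqrt(0.08))

    def test_antisymmetry(self):
        a, b = (8.1, 0.25), (6.3, 0.45)
        assert fe.delta_delta_g(a, b)[0] == -fe.delta_delta_g(b, a)[0]


class TestShoulder:
    @staticmethod
    def surface_from(fvals, edges):
        return fe.FreeEnergySurface(axes=["r"], edges=[edges],
                                    f=fvals - fvals.min())

    def test_plateau_detected_near_13(self):
        edges = np.linspace(4, 26, 90)
        c = 0.5 * (edges[1:] + edges[:-1])
        # rising profile with a flat shelf at 12-14 A
        f = 0.6 * (c - 4.0)
        shelf = (c > 12) & (c < 14)
        f = np.where(c >= 14, f - 0.6 * 2.0, np.where(shelf, 0.6 * 8.0, f))
        s = self.surface_from(f, edges)
        shoulders = fe.detect_shoulder(s, window=3.0)
        assert any(abs(x - 13.0) < 1.5 for x in shoulders)

    def test_convex_profile_has_none(self):
        edges = np.linspace(-3, 3, 60)
        c = 0.5 * (edges[1:] + edges[:-1])
        s = self.surface_from(0.7 * c ** 2, edges)
        assert fe.detect_shoulder(s) == []

    def test_true_barrier_not_reported_as_shoulder(self):
        edges = np.linspace(0, 20, 90)
        c = 0.5 * (edges[1:] + edges[:-1])
        f = 2.0 * np.exp(-((c - 10) ** 2) / 4.0) + 0.02 * (c - 10) ** 2
        s = self.surface_from(f, edges)
        shoulders = fe.detect_shoulder(s, window=3.0)
        assert all(abs(x - 10.0) > 1.0 for x in shoulders)

    def test_coarse_surface_rejected(self):
        edges = np.linspace(0, 10, 6)
        c = 0.5 * (edges[1:] + edges[:-1])
        s = self.surface_from(c * 0.1, edges)
        with pytest.raises(fe.FreeEnergyError, match="coarse"):
            fe.detect_shoulder(s)
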