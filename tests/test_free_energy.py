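"""Nonequilibrium switching, free-energy estimators, cycle and uncertainty."""

import numpy as np
import pytest

from hiqem.constants import KB_KJ_MOL_K
from hiqem.free_energy import (
    SwitchingProtocol,
    bar_variance,
    combine_cycle,
    estimate_free_energy,
    neq_switch,
    propagate_uncertainty,
    resample_to_target,
)

# temperature at which R T = 1 kJ/mol (the "kT = 1" toy regime)
T_UNIT = 1.0 / KB_KJ_MOL_K
LN4_HALF = 0.5 * np.log(4.0)


class Harmonic:
    """1-D harmonic well 0.5 k x^2 (kJ/mol with x in angstrom)."""

    def __init__(self, k):
        self.k = k

    def energy_forces(self, x):
        x = np.atleast_1d(np.asarray(x, float))
        return 0.5 * self.k * float(x @ x), -self.k * x


def harmonic_instantaneous_works(n, rng, k0=1.0, k1=4.0):
    """Bidirectional FEP works for the analytic k0 -> k1 switch at kT = 1."""
    x0 = rng.standard_normal(n) / np.sqrt(k0)
    x1 = rng.standard_normal(n) / np.sqrt(k1)
    return 0.5 * (k1 - k0) * x0**2, 0.5 * (k0 - k1) * x1**2


# ---------------------------------------------------------------------------
# Switching protocol and work accumulation
# ---------------------------------------------------------------------------


def test_schedule_endpoints_and_monotonicity():
    proto = SwitchingProtocol(n_steps=10)
    lam = proto.schedule()
    assert lam[0] == 0.0 and lam[-1] == 1.0
    assert np.all(np.diff(lam) >= 0)
    with pytest.raises(ValueError):
        SwitchingProtocol(lambda_schedule=np.array([0.0, 0.7, 0.4, 1.0])).schedule()


def test_identical_potentials_give_zero_work(rng):
    starts = rng.standard_normal((20, 1))
    proto = SwitchingProtocol(
        n_start_structures=8, n_steps=10, relaxation_steps=5, n_repeats=2,
        temperature=T_UNIT, seed=1,
    )
    ws = neq_switch(starts, Harmonic(2.0), Harmonic(2.0), proto)
    assert np.max(np.abs(ws.all_forward())) == 0.0
    assert np.max(np.abs(ws.all_backward())) == 0.0


def test_zero_step_protocol_is_exact_fep(rng):
    """Instantaneous switching: W = U_end - U_start at each start point."""
    starts = rng.standard_normal((12, 1))
    proto = SwitchingProtocol(
        n_start_structures=12, n_steps=0, relaxation_steps=0, n_repeats=1,
        temperature=T_UNIT, seed=2,
    )
    u0, u1 = Harmonic(1.0), Harmonic(4.0)
    ws = neq_switch(starts, u0, u1, proto)
    drawn = np.random.default_rng(2).integers(0, 12, size=12)
    expected = np.sort(
        [u1.energy_forces(starts[i])[0] - u0.energy_forces(starts[i])[0] for i in drawn]
    )
    assert np.allclose(np.sort(ws.w_forward[0]), expected, atol=1e-12)


def test_mean_forward_work_bounds_free_energy(rng):
    """Second law on the harmonic toy: <W_f> >= dF and <W_b> >= -dF (3 SE)."""
    proto = SwitchingProtocol(
        n_start_structures=500, n_steps=20, relaxation_steps=20, n_repeats=1,
        temperature=T_UNIT, seed=3, timestep=0.05,
    )
    starts = rng.standard_normal((500, 1))
    ws = neq_switch(starts, Harmonic(1.0), Harmonic(4.0), proto)
    wf, wb = ws.all_forward(), ws.all_backward()
    assert wf.mean() + 3 * wf.std() / np.sqrt(len(wf)) >= LN4_HALF
    assert wb.mean() + 3 * wb.std() / np.sqrt(len(wb)) >= -LN4_HALF


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def test_bar_deterministic_limit():
    wf = np.full(50, 3.7)
    wb = np.full(50, -3.7)
    df, se = estimate_free_energy(wf, wb, "bar", T_UNIT)
    assert df == pytest.approx(3.7, abs=1e-9)


def test_bar_recovers_analytic_harmonic_free_energy():
    rng = np.random.default_rng(11)
    wf, wb = harmonic_instantaneous_works(2000, rng)
    df, se = estimate_free_energy(wf, wb, "bar", T_UNIT)
    assert abs(df - LN4_HALF) < 3 * se


def test_jarzynski_zero_variance_gives_mean_work():
    wf = np.full(100, 1.25)
    df, _ = estimate_free_energy(wf, method="jarzynski_forward", temperature=T_UNIT)
    assert df == pytest.approx(1.25, abs=1e-12)


def test_crooks_fit_on_gaussian_works():
    """Crooks-consistent Gaussian work distributions: the fitted-Gaussian
    intersection recovers dF (mean +/- diss with variance 2 kT diss)."""
    rng = np.random.default_rng(7)
    df_true, diss = 0.9, 1.6
    wf = rng.normal(df_true + diss, np.sqrt(2 * diss), 4000)
    wb = rng.normal(-df_true + diss, np.sqrt(2 * diss), 4000)
    df, se = estimate_free_energy(wf, wb, "crooks_fit", T_UNIT)
    assert df == pytest.approx(df_true, abs=0.1)


def test_crooks_crossing_consistent_with_bar():
    """The empirical crossing of forward and reversed-backward work
    histograms sits within 3 SE of the BAR estimate (near-Gaussian works)."""
    rng = np.random.default_rng(19)
    df_true, diss = 0.5, 1.0
    wf = rng.normal(df_true + diss, np.sqrt(2 * diss), 3000)
    wb = rng.normal(-df_true + diss, np.sqrt(2 * diss), 3000)
    df_bar, se = estimate_free_energy(wf, wb, "bar", T_UNIT)
    # empirical crossing: histogram densities on a shared grid
    grid = np.linspace(-4, 6, 60)
    h_f, _ = np.histogram(wf, bins=grid, density=True)
    h_r, _ = np.histogram(-wb, bins=grid, density=True)
    centers = 0.5 * (grid[:-1] + grid[1:])
    diff = h_f - h_r
    sign_change = np.where(np.diff(np.sign(diff)) != 0)[0]
    mid = centers[(np.abs(centers - df_bar)).argmin()]
    crossings = centers[sign_change] if len(sign_change) else np.array([mid])
    nearest = crossings[np.argmin(np.abs(crossings - df_bar))]
    assert abs(nearest - df_bar) < max(3 * se, np.diff(centers)[0] * 2)


def test_bar_error_decreases_with_slower_switching(rng):
    """Dissipation, and with it the BAR uncertainty, shrinks as the harmonic
    switch is driven more slowly (10 -> 100 -> 1000 steps)."""
    ses = []
    for steps in (10, 100, 1000):
        proto = SwitchingProtocol(
            n_start_structures=150, n_steps=steps, relaxation_steps=50,
            n_repeats=1, temperature=T_UNIT, seed=5, timestep=0.05,
        )
        starts = rng.standard_normal((300, 1))
        ws = neq_switch(starts, Harmonic(1.0), Harmonic(4.0), proto)
        _, se = estimate_free_energy(ws.all_forward(), ws.all_backward(), "bar", T_UNIT)
        ses.append(se)
    assert ses[2] < ses[0]


def test_empty_work_sets_rejected():
    with pytest.raises(ValueError):
        estimate_free_energy(np.array([]), np.array([1.0]), "bar", T_UNIT)
    with pytest.raises(ValueError):
        estimate_free_energy(np.array([1.0]), np.array([]), "bar", T_UNIT)


# ---------------------------------------------------------------------------
# BAR variance
# ---------------------------------------------------------------------------


def test_bar_variance_scales_inversely_with_samples():
    rng = np.random.default_rng(13)
    wf, wb = harmonic_instantaneous_works(400, rng)
    se1 = bar_variance(wf, wb, T_UNIT)
    se4 = bar_variance(np.tile(wf, 4), np.tile(wb, 4), T_UNIT)
    assert se4 == pytest.approx(se1 / 2.0, rel=0.05)


def test_bar_variance_identical_distributions_small():
    rng = np.random.default_rng(17)
    wf = rng.normal(0, 0.1, 500)
    wb = rng.normal(0, 0.1, 500)
    df, se = estimate_free_energy(wf, wb, "bar", T_UNIT)
    assert abs(df) < 0.05
    assert 0 < se < 0.1


def test_bar_variance_agrees_with_bootstrap():
    """Analytic acceptance-ratio SE within 30% of a bootstrap oracle."""
    rng = np.random.default_rng(23)
    wf, wb = harmonic_instantaneous_works(500, rng)
    se = bar_variance(wf, wb, T_UNIT)
    boot = []
    for _ in range(1000):
        i = rng.integers(0, 500, 500)
        j = rng.integers(0, 500, 500)
        boot.append(estimate_free_energy(wf[i], wb[j], "bar", T_UNIT)[0])
    assert se == pytest.approx(np.std(boot), rel=0.3)


def test_bar_variance_needs_two_samples():
    with pytest.raises(ValueError):
        bar_variance(np.array([1.0]), np.array([1.0, 2.0]), T_UNIT)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def test_resampling_weights_and_ess(rng):
    configs = rng.standard_normal((6, 2))
    works = np.full(6, 2.5)
    resampled, weights = resample_to_target(configs, works, T_UNIT)
    assert weights == pytest.approx(np.full(6, 1 / 6), abs=1e-12)
    assert 1.0 / np.sum(weights**2) == pytest.approx(6.0)
    # kT ln 2 work difference -> exact factor-2 weight ratio
    works2 = np.array([0.0, np.log(2.0), 0.0])
    _, w2 = resample_to_target(configs[:3], works2, T_UNIT)
    assert w2[0] / w2[1] == pytest.approx(2.0, rel=1e-12)
    assert w2.sum() == pytest.approx(1.0, abs=1e-12)


def test_resampling_collapse_warns(rng):
    configs = rng.standard_normal((5, 2))
    works = np.array([0.0, 50.0, 50.0, 50.0, 50.0])
    with pytest.warns(UserWarning, match="effective sample size"):
        resample_to_target(configs, works, T_UNIT)


# ---------------------------------------------------------------------------
# Cycle assembly and uncertainty propagation
# ---------------------------------------------------------------------------


def test_cycle_zero_corrections():
    est = combine_cycle(-35.3, np.zeros(6), np.zeros(6))
    assert est.grid.shape == (6, 6)
    assert np.all(est.grid == -35.3)
    assert est.sigma_bind < 1e-12
    assert est.dg_bind == pytest.approx(-35.3, abs=1e-12)


def test_cycle_grid_counting_and_antisymmetry(rng):
    cp = rng.normal(size=2)
    cs = rng.normal(size=2)
    est = combine_cycle(-10.0, cp, cs)
    assert est.grid.size == 4
    swapped = combine_cycle(-10.0, cs, cp)
    assert est.dg_bind - (-10.0) == pytest.approx(-(swapped.dg_bind - (-10.0)))


def test_cycle_missing_end_state_rejected():
    with pytest.raises(ValueError):
        combine_cycle(0.0, [], [1.0])


def test_uncertainty_propagation_arithmetic():
    assert propagate_uncertainty(0.0, 0.0, 0.0) == 0.0
    assert propagate_uncertainty(0.3, 0.4, 0.45) == pytest.approx(
        np.sqrt(1.06), abs=1e-12
    )
    with pytest.raises(ValueError):
        propagate_uncertainty(-0.1, 0.0, 0.0)


def test_uncertainty_monotone_in_each_argument(rng):
    grid = rng.uniform(0, 2, size=(20, 3))
    for row in grid:
        base = propagate_uncertainty(*row)
        for k in range(3):
            bumped = row.copy()
            bumped[k] += 0.3
            assert propagate_uncertainty(*bumped) >= base


# ---------------------------------------------------------------------------
# Phenomenology and determinism
# ---------------------------------------------------------------------------


class DoubleWell:
    """1-D double well with minima near +/- a; paired with a tilted partner."""

    def __init__(self, a=1.5, height=8.0, tilt=0.0):
        self.a, self.h, self.tilt = a, height, tilt

    def energy_forces(self, x):
        x = np.atleast_1d(np.asarray(x, float))
        u = self.h * ((x / self.a) ** 2 - 1.0) ** 2 + self.tilt * x
        du = 4.0 * self.h * x / self.a**2 * ((x / self.a) ** 2 - 1.0) + self.tilt
        return float(u.sum()), -du


def test_bimodal_start_ensemble_gives_bimodal_works():
    """Starts split between two wells produce a two-component work
    distribution, detected by a two- vs one-component mixture comparison."""
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(29)
    u0 = DoubleWell(tilt=0.0)
    u1 = DoubleWell(tilt=4.0)  # tilting makes the two wells inequivalent
    starts = np.concatenate(
        [rng.normal(-1.5, 0.25, 150), rng.normal(1.5, 0.25, 150)]
    )[:, None]
    works = np.array(
        [u1.energy_forces(x)[0] - u0.energy_forces(x)[0] for x in starts]
    )
    bics = []
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, random_state=0).fit(works[:, None])
        bics.append(gm.bic(works[:, None]))
    assert bics[1] < bics[0]  # two components clearly preferred


class _Treacherous:
    """Harmonic well that returns NaN energy outside a trust region."""

    def energy_forces(self, x):
        x = np.atleast_1d(np.asarray(x, float))
        if np.any(np.abs(x) > 1.5):
            return np.nan, np.zeros_like(x)
        return 0.5 * float(x @ x), -x


def test_nan_trajectories_flagged_and_excluded(rng):
    starts = np.concatenate([rng.standard_normal(10) * 0.1, [5.0, -6.0]])[:, None]
    proto = SwitchingProtocol(
        n_start_structures=12, n_steps=0, relaxation_steps=0, n_repeats=1,
        temperature=T_UNIT, seed=0,
    )
    with pytest.warns(UserWarning, match="discarded"):
        ws = neq_switch(starts, Harmonic(1.0), _Treacherous(), proto)
    assert ws.n_discarded > 0
    assert np.all(np.isfinite(ws.all_forward()))


def test_full_determinism_under_fixed_seed(rng):
    starts = rng.standard_normal((30, 1))
    proto = SwitchingProtocol(
        n_start_structures=10, n_steps=20, relaxation_steps=10, n_repeats=2,
        temperature=T_UNIT, seed=42,
    )
    ws1 = neq_switch(starts, Harmonic(1.0), Harmonic(3.0), proto)
    ws2 = neq_switch(starts, Harmonic(1.0), Harmonic(3.0), proto)
    for a, b in zip(ws1.w_forward, ws2.w_forward):
        assert np.array_equal(a, b)
    for a, b in zip(ws1.w_backward, ws2.w_backward):
        assert np.array_equal(a, b)
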