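"""FO moments and Fisher information, cross-checked against independent oracles."""

import numpy as np
import pytest

import mbaod
from mbaod import scenario
from mbaod.fim import PositiveDefiniteError
from mbaod.parameters import ETA_NAMES


# ---------------------------------------------------------------------------
# Independent oracle: separate response arithmetic, coarser FD step (1e-4 vs
# the engine's 1e-5), plain loops, explicit block assembly.
# ---------------------------------------------------------------------------

def oracle_response(fx, eta, dose, times):
    emax = fx.emax * np.exp(eta[0])
    ec50 = fx.ec50 * np.exp(eta[1])
    cl = fx.cl * np.exp(eta[2])
    v = fx.v * np.exp(eta[3])
    out = np.empty(len(times))
    for j, t in enumerate(times):
        conc = dose * fx.ka / (v * fx.ka - cl) * (
            np.exp(-(cl / v) * t) - np.exp(-fx.ka * t)
        )
        if conc > 0:
            frac = conc**fx.gamma / (conc**fx.gamma + ec50**fx.gamma)
        else:
            frac = 0.0
        out[j] = fx.base + emax * frac
    return out


def oracle_moments(theta, group, h=1e-6):
    times = np.asarray(group.times)
    f0 = oracle_response(theta.fixed, np.zeros(4), group.dose, times)
    L = np.zeros((len(times), 4))
    for k in range(4):
        e = np.zeros(4)
        e[k] = h
        L[:, k] = (
            oracle_response(theta.fixed, e, group.dose, times)
            - oracle_response(theta.fixed, -e, group.dose, times)
        ) / (2 * h)
    V = L @ theta.omega_matrix() @ L.T + np.diag(
        theta.random.sigma2_prop * f0**2 + theta.random.sigma2_add
    )
    return f0, V


def oracle_elementary_fim(theta, group, rel_step=1e-4):
    names = theta.estimated_beta + theta.estimated_lambda
    nb = len(theta.estimated_beta)
    P = len(names)
    _, V0 = oracle_moments(theta, group)
    Vinv = np.linalg.inv(V0)
    dE, dV = [], []
    for name in names:
        val = theta.value(name)
        h = max(rel_step * abs(val), 1e-8)
        Ep, Vp = oracle_moments(theta.with_value(name, val + h), group)
        Em, Vm = oracle_moments(theta.with_value(name, val - h), group)
        dE.append((Ep - Em) / (2 * h))
        dV.append((Vp - Vm) / (2 * h))
    F = np.zeros((P, P))
    for i in range(nb):
        for j in range(nb):
            F[i, j] = dE[i] @ Vinv @ dE[j]
    for i in range(nb, P):
        for j in range(nb, P):
            F[i, j] = 0.5 * np.trace(dV[i] @ Vinv @ dV[j] @ Vinv)
    return F


def oracle_population_fim(theta, design):
    return sum(g.n * oracle_elementary_fim(theta, g) for g in design.groups)


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

class TestFoMoments:
    def test_no_bsv_leaves_pure_residual_variance(self, theta_true):
        theta0 = theta_true.with_values(
            {f"omega2_{n}": 0.0 for n in ETA_NAMES}
        )
        g = mbaod.GroupDesign(160, 1, scenario.T_SPARSE)
        mom = mbaod.fo_moments(theta0, g)
        expected = np.diag(
            theta0.random.sigma2_prop * mom.mean**2 + theta0.random.sigma2_add
        )
        np.testing.assert_allclose(mom.variance, expected, rtol=1e-10)

    def test_placebo_group_mean_is_baseline(self, theta_true):
        g = mbaod.GroupDesign(0, 1, scenario.T_SPARSE)
        mom = mbaod.fo_moments(theta_true, g)
        np.testing.assert_allclose(mom.mean, theta_true.fixed.base)

    def test_eta_jacobian_against_independent_differentiation(self, theta_true):
        g = mbaod.GroupDesign(160, 1, scenario.T_SPARSE)
        mom = mbaod.fo_moments(theta_true, g)
        _, V_oracle = oracle_moments(theta_true, g)
        np.testing.assert_allclose(mom.variance, V_oracle, rtol=1e-6)


# ---------------------------------------------------------------------------
# information matrices
# ---------------------------------------------------------------------------

class TestElementaryFim:
    def test_linear_model_closed_form(self, theta_true):
        # y = slope*t + eps_add: information for the slope is sum(t^2)/sigma^2.
        sigma2 = 0.04
        theta = theta_true.with_values(
            {
                "omega2_emax": 0.0, "omega2_ec50": 0.0, "omega2_cl": 0.0,
                "omega2_v": 0.0, "sigma2_add": sigma2, "sigma2_prop": 0.0,
            }
        )
        theta = mbaod.PopulationParameters(theta.fixed, theta.random, ("emax",))
        times = (1.0, 2.0, 4.0)

        def linear_response(fx, eta, dose, times_):
            t = np.asarray(times_, dtype=float)
            lead = np.broadcast_shapes(np.shape(np.asarray(eta)[..., 0]), np.shape(dose))
            return np.broadcast_to(fx.emax * t, lead + t.shape).copy()

        g = mbaod.GroupDesign(1, 1, times)
        F = mbaod.elementary_fim(theta, g, form="block_diag", response=linear_response)
        assert F.names == ("emax",)
        assert F.values[0, 0] == pytest.approx(sum(t**2 for t in times) / sigma2, rel=1e-8)

    def test_block_diag_off_blocks_are_zero(self, theta_true):
        g = mbaod.GroupDesign(160, 1, scenario.T_SPARSE)
        F = mbaod.elementary_fim(theta_true, g, form="block_diag")
        nb = len(theta_true.estimated_beta)
        assert np.all(F.values[:nb, nb:] == 0.0)
        assert np.all(F.values[nb:, :nb] == 0.0)

    def test_dimension_and_names_for_scenario(self, theta_true):
        g = mbaod.GroupDesign(160, 1, scenario.T_SPARSE)
        F = mbaod.elementary_fim(theta_true, g)
        assert F.values.shape == (7, 7)
        assert F.names == (
            "base", "emax", "ec50", "gamma", "omega2_emax", "omega2_ec50", "sigma2_prop",
        )

    def test_full_form_matches_monte_carlo_expected_hessian(self, theta_true):
        # The full FIM must equal the expected negative Hessian of the FO
        # (Gaussian) log-likelihood. Oracle: simulate 1e5 response vectors
        # from the FO moments, average the log-likelihood over them with
        # common random numbers, differentiate that average numerically.
        g = mbaod.GroupDesign(160, 1, (1.0, 10.0))
        F = mbaod.elementary_fim(theta_true, g, form="full").values
        names = theta_true.estimated
        E0, V0 = oracle_moments(theta_true, g)
        rng = np.random.default_rng(2024)
        y = rng.multivariate_normal(E0, V0, size=100_000)

        def mean_nll(theta):
            E, V = oracle_moments(theta, g)
            Vinv = np.linalg.inv(V)
            _, ld = np.linalg.slogdet(V)
            R = y - E
            quad = np.einsum("nt,ts,ns->n", R, Vinv, R)
            return 0.5 * (ld + float(quad.mean()))

        H = np.zeros((7, 7))
        steps = [max(1e-3 * abs(theta_true.value(n)), 1e-5) for n in names]
        f0 = mean_nll(theta_true)
        for i, ni in enumerate(names):
            vi, hi = theta_true.value(ni), steps[i]
            H[i, i] = (
                mean_nll(theta_true.with_value(ni, vi + hi))
                - 2 * f0
                + mean_nll(theta_true.with_value(ni, vi - hi))
            ) / hi**2
            for j in range(i + 1, 7):
                nj = names[j]
                vj, hj = theta_true.value(nj), steps[j]
                pp = mean_nll(theta_true.with_values({ni: vi + hi, nj: vj + hj}))
                pm = mean_nll(theta_true.with_values({ni: vi + hi, nj: vj - hj}))
                mp = mean_nll(theta_true.with_values({ni: vi - hi, nj: vj + hj}))
                mm = mean_nll(theta_true.with_values({ni: vi - hi, nj: vj - hj}))
                H[i, j] = H[j, i] = (pp - pm - mp + mm) / (4 * hi * hj)

        scale = np.sqrt(np.outer(np.diag(F), np.diag(F)))
        np.testing.assert_allclose(H / scale, F / scale, atol=2e-2)

    def test_singular_variance_raises(self, theta_true):
        theta0 = theta_true.with_values(
            {
                "omega2_emax": 0.0, "omega2_ec50": 0.0, "omega2_cl": 0.0,
                "omega2_v": 0.0, "sigma2_add": 0.0, "sigma2_prop": 0.0,
            }
        )
        g = mbaod.GroupDesign(160, 1, scenario.T_SPARSE)
        with pytest.raises(PositiveDefiniteError):
            mbaod.fo_moments(theta0, g)


class TestPopulationFim:
    def test_matches_independent_oracle_both_schedules(self, theta_true):
        for schedule in ("sparse", "rich"):
            design = scenario.initial_design(schedule)
            F = mbaod.population_fim(theta_true, design).values
            F_oracle = oracle_population_fim(theta_true, design)
            np.testing.assert_allclose(F, F_oracle, rtol=1e-6, atol=1e-9)

    def test_linear_in_group_sizes(self, theta_true, sparse_design):
        F1 = mbaod.population_fim(theta_true, sparse_design).values
        doubled = mbaod.StudyDesign(
            tuple(
                mbaod.GroupDesign(g.dose, 2 * g.n, g.times) for g in sparse_design.groups
            )
        )
        F2 = mbaod.population_fim(theta_true, doubled).values
        np.testing.assert_allclose(F2, 2 * F1, rtol=1e-12)

    def test_single_group_equals_scaled_elementary(self, theta_true):
        g = mbaod.GroupDesign(160, 1, scenario.T_SPARSE)
        F_pop = mbaod.population_fim(theta_true, mbaod.StudyDesign((g,)))
        F_el = mbaod.elementary_fim(theta_true, g)
        np.testing.assert_allclose(F_pop.values, F_el.values, rtol=1e-12)

    def test_additive_over_groups_and_order_invariant(self, theta_true):
        g1 = mbaod.GroupDesign(40, 3, scenario.T_SPARSE)
        g2 = mbaod.GroupDesign(300, 5, scenario.T_SPARSE)
        F12 = mbaod.population_fim(theta_true, mbaod.StudyDesign((g1, g2))).values
        F21 = mbaod.population_fim(theta_true, mbaod.StudyDesign((g2, g1))).values
        Fsum = (
            mbaod.population_fim(theta_true, mbaod.StudyDesign((g1,))).values
            + mbaod.population_fim(theta_true, mbaod.StudyDesign((g2,))).values
        )
        np.testing.assert_allclose(F12, F21, rtol=1e-12)
        np.testing.assert_allclose(F12, Fsum, rtol=1e-12)

    def test_adding_a_group_never_loses_information(self, theta_true, sparse_design):
        base = mbaod.population_fim(theta_true, sparse_design)
        grown = sparse_design
        prev = base.logdet()
        for dose in (10, 80, 250, 500):
            grown = grown.add_group(mbaod.GroupDesign(dose, 2, scenario.T_SPARSE))
            cur = mbaod.population_fim(theta_true, grown).logdet()
            assert cur >= prev - 1e-9
            prev = cur

    def test_grid_batch_agrees_with_per_group_path(self, theta_true):
        doses = np.array([0, 40, 160, 500])
        batch = mbaod.elementary_fim_grid(theta_true, doses, scenario.T_SPARSE)
        for i, dose in enumerate(doses):
            single = mbaod.elementary_fim(
                theta_true, mbaod.GroupDesign(int(dose), 1, scenario.T_SPARSE)
            )
            np.testing.assert_allclose(batch[i], single.values, rtol=1e-12)

    def test_csv_round_trip(self, theta_true, sparse_design, tmp_path):
        F = mbaod.population_fim(theta_true, sparse_design)
        p = tmp_path / "fim.csv"
        F.to_csv(p)
        back = mbaod.FisherMatrix.from_csv(p)
        assert back.names == F.names
        np.testing.assert_allclose(back.values, F.values, rtol=1e-12)
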