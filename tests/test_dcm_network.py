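"""Network structure, bilinear neural dynamics, balloon observation,
inversion sanity, and PEB group inference."""

import numpy as np
import pandas as pd
import pytest

import oculostop as oc
from oculostop import dcm_network as dcm
from oculostop.errors import InvalidInputError, StabilityError


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

class TestStructure:
    def test_nineteen_edges_no_self_pairs(self, structure):
        assert len(structure.edges) == 19
        assert all(s != t for s, t in structure.edges)
        assert len(set(structure.edges)) == 19

    def test_directional_claims(self, structure):
        edges = set(structure.edges)
        assert ("FEF", "SC") in edges and ("SC", "FEF") not in edges
        assert ("rIFC", "SEF") in edges and ("SEF", "rIFC") in edges
        # thalamus excites all three cortical regions
        for t in ("FEF", "SEF", "rIFC"):
            assert ("Thal", t) in edges

    def test_adjacency_frame_layout(self, structure):
        adj = structure.adjacency_frame()
        assert list(adj.index) == list(dcm.REGIONS)
        assert adj.to_numpy().sum() == 19
        assert np.all(np.diag(adj.to_numpy()) == 0)


# ---------------------------------------------------------------------------
# neural derivative
# ---------------------------------------------------------------------------

class TestNeuralDerivative:
    def test_zero_state_zero_input_fixed_point(self, structure):
        p = dcm.DCMParameters.zeros(structure)
        dz = oc.neural_derivative(np.zeros(6), p, 0.0, 0.0)
        assert np.allclose(dz, 0.0)

    def test_default_self_connection_rate(self, structure):
        """At theta = 0 the self-connection is the -0.5 Hz default."""
        p = dcm.DCMParameters.zeros(structure)
        z = np.zeros(6)
        z[0] = 1.0
        dz = oc.neural_derivative(z, p, 0.0, 0.0)
        assert dz[0] == pytest.approx(-0.5)

    def test_edge_coupling_hand_evaluated(self, structure):
        p = dcm.DCMParameters.zeros(structure)
        i_fef, i_sef = structure.index("FEF"), structure.index("SEF")
        p.a[i_sef, i_fef] = 0.2  # FEF -> SEF
        z = np.zeros(6)
        z[i_fef] = 1.0
        dz = oc.neural_derivative(z, p, 0.0, 0.0)
        assert dz[i_sef] == pytest.approx(0.2 - 0.0)

    def test_disallowed_edge_rejected(self, structure):
        a = np.zeros((6, 6))
        a[structure.index("FEF"), structure.index("SC")] = 0.1  # SC -> FEF is off
        with pytest.raises(InvalidInputError):
            dcm.DCMParameters(a, np.zeros(6), np.zeros((6, 6)), np.zeros(6),
                              np.zeros(6), structure)

    def test_modulation_enters_jacobian(self, structure):
        p = dcm.DCMParameters.zeros(structure)
        i_fef, i_sef = structure.index("FEF"), structure.index("SEF")
        p.a[i_sef, i_fef] = 0.1
        p.b[i_sef, i_fef] = 0.3
        assert p.jacobian(0.0)[i_sef, i_fef] == pytest.approx(0.1)
        assert p.jacobian(1.0)[i_sef, i_fef] == pytest.approx(0.4)

    def test_self_connections_always_negative(self, structure):
        for theta in (-3.0, 0.0, 2.0):
            p = dcm.DCMParameters.zeros(structure)
            p.theta_self[:] = theta
            assert np.all(np.diag(p.jacobian(0.0)) < 0)
            assert np.all(np.diag(p.jacobian(1.0)) < 0)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

class TestBoldForward:
    def test_no_input_flat_zero(self, structure, hemo, small_design):
        p = dcm.DCMParameters.zeros(structure)  # c = 0
        y = oc.bold_forward(p, hemo, small_design, noise_sd=0.0)
        assert np.allclose(y, 0.0, atol=1e-12)

    def test_impulse_peaks_3_to_7_seconds(self, structure, hemo):
        p = dcm.DCMParameters.zeros(structure)
        p.c[:] = 0.3
        n_steps = 80 * 80
        u = np.zeros(n_steps)
        onset = 800  # 20 s in
        u[onset: onset + 4] = 1.0
        d = dcm.DesignInput(u_task=u, u_redirect=np.zeros(n_steps),
                            dt=0.025, tr=2.0, n_volumes=80)
        y = oc.bold_forward(p, hemo, d, noise_sd=0.0)
        peak_lag = float(np.argmax(y[:, 0])) * 2.0 - onset * 0.025
        assert 3.0 <= peak_lag <= 7.0

    def test_seeded_noise_reproducible(self, base_params, hemo, small_design):
        y1 = oc.bold_forward(base_params, hemo, small_design, noise_sd=1e-4, seed=9)
        y2 = oc.bold_forward(base_params, hemo, small_design, noise_sd=1e-4, seed=9)
        assert np.array_equal(y1, y2)

    def test_unstable_parameters_raise(self, structure, hemo, small_design):
        p = dcm.DCMParameters.zeros(structure)
        i_fef, i_sef = structure.index("FEF"), structure.index("SEF")
        p.a[i_sef, i_fef] = 2.0
        p.a[i_fef, i_sef] = 2.0  # strong positive loop beats -0.5 decay
        with pytest.raises(StabilityError):
            oc.bold_forward(p, hemo, small_design, noise_sd=0.0)

    def test_decay_to_baseline_with_zero_couplings(self, structure):
        """With a = b = 0 and theta = 0, J(u) = -0.5 I for every u and the
        network relaxes to baseline after input ends."""
        p = dcm.DCMParameters.zeros(structure)
        assert np.allclose(p.jacobian(0.0), -0.5 * np.eye(6))
        assert np.allclose(p.jacobian(1.0), -0.5 * np.eye(6))
        p.c[:] = 0.5
        n_steps = 60 * 80
        u = np.zeros(n_steps)
        u[100: 120] = 1.0
        d = dcm.DesignInput(u_task=u, u_redirect=np.zeros(n_steps),
                            dt=0.025, tr=2.0, n_volumes=60)
        y = oc.bold_forward(p, dcm.HemodynamicParameters(), d, 0.0)
        assert np.abs(y[-5:, :]).max() < 1e-5


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

class TestInversion:
    def test_stationary_at_generating_optimum(self, structure, base_params, hemo, small_design):
        """Initialized at the generating parameters on noiseless data, the
        optimizer has (almost) nothing to gain: parameters barely move."""
        y = oc.bold_forward(base_params, hemo, small_design, noise_sd=0.0)
        res = oc.invert_dcm(y, structure, small_design, max_iter=4,
                            theta0=base_params.to_vector())
        moved = np.abs(res.theta_mean - base_params.to_vector())
        assert moved.max() < 0.01

    def test_objective_history_monotone(self, structure, base_params, hemo, small_design):
        y = oc.bold_forward(base_params, hemo, small_design, noise_sd=2e-5, seed=3)
        res = oc.invert_dcm(y, structure, small_design, max_iter=16)
        h = np.array(res.objective_history)
        assert np.all(np.diff(h) >= -1e-6)

    def test_generating_model_beats_empty_model(self, structure, base_params, hemo, small_design):
        """On data from the coupled network, the free energy of the full
        model exceeds that of a model with every between-region connection
        switched off."""
        y = oc.bold_forward(base_params, hemo, small_design, noise_sd=2e-5, seed=4)
        full = oc.invert_dcm(y, structure, small_design, max_iter=16)
        empty = oc.invert_dcm(y, structure, small_design, max_iter=16,
                              priors=dcm.Priors(var_a=0.0, var_b=0.0))
        assert full.free_energy > empty.free_energy

    def test_noiseless_recovery_from_default_init(self, structure, base_params, hemo, small_design):
        y = oc.bold_forward(base_params, hemo, small_design, noise_sd=0.0)
        res = oc.invert_dcm(y, structure, small_design, max_iter=32, tol=0.01)
        ne, n = len(structure.edges), structure.n
        true = base_params.to_vector()[: ne + n]
        est = res.theta_mean[: ne + n]
        assert np.corrcoef(true, est)[0, 1] >= 0.9

    def test_dimension_mismatch_rejected(self, structure, small_design):
        with pytest.raises(InvalidInputError):
            oc.invert_dcm(np.zeros((80, 5)), structure, small_design)


# ---------------------------------------------------------------------------
# PEB (on directly constructed subject posteriors: fast, deterministic)
# ---------------------------------------------------------------------------

def _fake_results(means, structure, var=1e-4):
    out = []
    for m in means:
        out.append(dcm.InversionResult(
            theta_mean=np.asarray(m, dtype=float),
            theta_cov=np.eye(len(m)) * var,
            params=dcm.DCMParameters.from_vector(np.asarray(m), structure),
            free_energy=0.0, objective_history=[], explained_variance=np.ones(6),
            noise_precision=np.ones(6), converged=True,
            labels=dcm.DCMParameters.zeros(structure).labels(),
        ))
    return out


class TestPeb:
    def _cohort(self, structure, effect, n=8, seed=0, jitter=0.05):
        rng = np.random.default_rng(seed)
        base = oc.default_dcm_parameters(structure).to_vector()
        j = base.size
        means, codes = [], []
        for code in (-1, 1):
            for _ in range(n):
                m = base + rng.normal(0, jitter, size=j)
                m[0] += code * effect / 2.0  # first edge parameter
                means.append(m)
                codes.append(code)
        return _fake_results(means, structure), codes

    def test_identical_groups_nothing_credible(self, structure):
        results, codes = self._cohort(structure, effect=0.0, seed=1)
        peb = oc.peb_group(results, codes)
        assert np.abs(peb.table["diff_mean"]).max() < 0.05
        assert oc.credible_set(peb, level="diff") == []

    def test_planted_difference_detected_with_sign(self, structure):
        results, codes = self._cohort(structure, effect=0.2, seed=2)
        peb = oc.peb_group(results, codes)
        label = results[0].labels[0]
        assert label in oc.credible_set(peb, level="diff")
        assert peb.table.loc[label, "diff_mean"] > 0

    def test_flipping_codes_negates_differences(self, structure):
        results, codes = self._cohort(structure, effect=0.2, seed=3)
        p1 = oc.peb_group(results, codes)
        p2 = oc.peb_group(results, [-c for c in codes])
        assert np.allclose(p1.table["diff_mean"], -p2.table["diff_mean"], atol=1e-8)
        assert np.allclose(p1.table["diff_prob"], p2.table["diff_prob"], atol=1e-8)

    def test_commonalities_track_group_average(self, structure):
        results, codes = self._cohort(structure, effect=0.0, seed=4, jitter=0.02)
        peb = oc.peb_group(results, codes)
        base = oc.default_dcm_parameters(structure).to_vector()
        big = np.abs(base) > 0.2
        est = peb.table["common_mean"].to_numpy()[big]
        assert np.corrcoef(est, base[big])[0, 1] > 0.95

    def test_mismatched_parameter_sets_rejected(self, structure):
        results, codes = self._cohort(structure, effect=0.0)
        results[0].labels = list(results[0].labels)[::-1]
        with pytest.raises(InvalidInputError):
            oc.peb_group(results, codes)

    def test_group_codes_validated(self, structure):
        results, codes = self._cohort(structure, effect=0.0)
        with pytest.raises(InvalidInputError):
            oc.peb_group(results, [0] * len(codes))


class TestCredibleSet:
    def _peb_with_probs(self, probs):
        table = pd.DataFrame({
            "diff_prob": probs,
            "common_prob": [0.5] * len(probs),
            "diff_mean": [0.1] * len(probs),
            "common_mean": [0.0] * len(probs),
        }, index=[f"p{i}" for i in range(len(probs))])
        return dcm.PEBResult(table=table)

    def test_strict_threshold(self):
        peb = self._peb_with_probs([0.95, 0.951, 0.3])
        assert oc.credible_set(peb, level="diff") == ["p1"]

    def test_zero_threshold_returns_all_nonzero(self):
        peb = self._peb_with_probs([0.95, 0.951, 0.3])
        assert oc.credible_set(peb, threshold=0.0, level="diff") == ["p0", "p1", "p2"]
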