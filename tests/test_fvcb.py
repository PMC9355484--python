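"""FvCB forward model and A/Ci fitting: hand values, round trips,
brute-force assignment oracle, temperature normalization."""

import math

import numpy as np
import pytest

from leafphys import (ACiFitter, FvCBParameters, cc_from_ci, fit_aci,
                      fvcb_forward, temperature_adjust)
from leafphys.fvcb import FvCBDomainError

P_REF = FvCBParameters(vcmax=100.0, j=150.0, rd=1.5)
CI_GRID = np.array([50, 100, 200, 200, 300, 400, 600, 800, 1000, 1200, 1500.0])


def test_forward_hand_values_at_cc_300():
    ac, aj, _, amin = fvcb_forward(P_REF, 300.0)
    # hand evaluation of both rate equations
    km = 404.9 * (1 + 210 / 278.4)
    assert ac == pytest.approx(100 * (300 - 42.75) / (300 + km) - 1.5, rel=1e-12)
    assert ac == pytest.approx(23.9622, abs=5e-4)
    assert aj == pytest.approx(150 * 257.25 / (4 * 300 + 8 * 42.75) - 1.5, rel=1e-12)
    assert aj == pytest.approx(23.5243, abs=5e-4)
    assert amin == aj  # RuBP-limited at this Cc


def test_forward_compensation_point_and_asymptote():
    ac, aj, _, amin = fvcb_forward(P_REF, P_REF.gamma_star)
    assert ac == pytest.approx(-P_REF.rd, abs=1e-12)
    assert aj == pytest.approx(-P_REF.rd, abs=1e-12)
    ac_inf, *_ = fvcb_forward(P_REF, 1e9)
    assert ac_inf == pytest.approx(P_REF.vcmax - P_REF.rd, rel=1e-6)
    with pytest.raises(FvCBDomainError):
        fvcb_forward(P_REF, -1.0)


def test_cc_from_ci():
    assert cc_from_ci(300.0, 20.0, math.inf) == pytest.approx(300.0)
    assert cc_from_ci(300.0, 20.0, 0.5) == pytest.approx(260.0)
    assert cc_from_ci(300.0, 0.0, 0.5) == pytest.approx(300.0)
    assert np.isnan(cc_from_ci(10.0, 20.0, 0.5))  # flagged for exclusion
    with pytest.raises(FvCBDomainError):
        cc_from_ci(300.0, 20.0, -1.0)


def test_noiseless_round_trip_recovery():
    _, _, _, a = fvcb_forward(P_REF, CI_GRID)
    fit = fit_aci(np.column_stack([CI_GRID, a]))
    assert fit.admissible
    assert fit.params.vcmax == pytest.approx(100.0, rel=1e-3)
    assert fit.params.j == pytest.approx(150.0, rel=1e-3)
    assert fit.params.rd == pytest.approx(1.5, rel=1e-3)
    assert math.isinf(fit.params.tpu)  # no TPU-limited point -> omitted
    assert not fit.tpu_limited


def test_tpu_limited_curve_recovery():
    p = FvCBParameters(vcmax=100.0, j=150.0, tpu=9.0, rd=1.5)
    _, _, _, a = fvcb_forward(p, CI_GRID)
    fit = fit_aci(np.column_stack([CI_GRID, a]))
    assert fit.tpu_limited
    assert fit.params.tpu == pytest.approx(9.0, rel=1e-3)
    assert fit.params.vcmax == pytest.approx(100.0, rel=1e-3)


def test_fitted_sse_never_exceeds_truth_on_noiseless_data():
    _, _, _, a = fvcb_forward(P_REF, CI_GRID)
    fit = fit_aci(np.column_stack([CI_GRID, a]))
    truth_sse = float(np.sum((fvcb_forward(P_REF, CI_GRID)[3] - a) ** 2))
    assert fit.sse <= truth_sse + 1e-12


def test_rubisco_only_curve_flags_j_unidentifiable():
    ci = np.array([60, 80, 100, 120, 140, 150.0])  # all above Γ*, Rubisco-limited
    ac, *_ = fvcb_forward(P_REF, ci)
    fit = fit_aci(np.column_stack([ci, ac]))
    assert not fit.j_identifiable
    assert fit.params.vcmax == pytest.approx(100.0, rel=1e-3)


def test_too_few_points_errors():
    with pytest.raises(FvCBDomainError):
        fit_aci([(100, 5.0), (300, 15.0), (600, 20.0), (900, 22.0)])


def test_noisy_replicate_recovery_within_5pct():
    rng = np.random.default_rng(3)
    _, _, _, a = fvcb_forward(P_REF, CI_GRID)
    recovered = []
    for _ in range(4):
        noisy = a * (1 + 0.02 * rng.standard_normal(len(a)))
        recovered.append(fit_aci(np.column_stack([CI_GRID, noisy])).params.vcmax)
    assert np.mean(recovered) == pytest.approx(100.0, rel=0.05)


def _oracle_best_assignment(ci, a, kin=P_REF, min_tpu=2, tol=0.02):
    """Independent brute force: unconstrained lstsq over every monotone
    labeling, admissibility via direct min-rule evaluation."""
    km = kin.kc * (1 + kin.o / kin.ko)
    g = kin.gamma_star
    n = len(ci)
    best = None
    for r in range(1, n + 1):
        for s in range(r, n + 1):
            if s < n and n - s < min_tpu:
                continue
            cols = [np.where(np.arange(n) < r, (ci - g) / (ci + km), 0.0)]
            if s > r:
                mask = (np.arange(n) >= r) & (np.arange(n) < s)
                cols.append(np.where(mask, (ci - g) / (4 * ci + 8 * g), 0.0))
            if s < n:
                cols.append(np.where(np.arange(n) >= s, 3.0, 0.0))
            cols.append(-np.ones(n))
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, a, rcond=None)
            if np.any(beta[:-1] < -1e-9) or beta[-1] < -1e-9:
                continue
            sse = float(np.sum((a - X @ beta) ** 2))
            # admissibility at the fitted parameters
            k = 0
            vcmax = beta[k]; k += 1
            j = beta[k] if s > r else np.inf
            k += 1 if s > r else 0
            tpu = beta[k] if s < n else np.inf
            rd = beta[-1]
            ac = vcmax * (ci - g) / (ci + km) - rd
            aj = (j * (ci - g) / (4 * ci + 8 * g) - rd) if np.isfinite(j) \
                else np.full(n, np.inf)
            ap = np.full(n, 3 * tpu - rd if np.isfinite(tpu) else np.inf)
            chosen = np.concatenate([ac[:r], aj[r:s], ap[s:]])
            amin = np.minimum(np.minimum(ac, aj), ap)
            if not np.all(np.abs(chosen - amin) <= tol * np.maximum(1, np.abs(amin))):
                continue
            if best is None or sse < best[0] - 1e-10:
                best = (sse, r, s)
    return best


@pytest.mark.parametrize("params", [
    FvCBParameters(vcmax=100.0, j=150.0, rd=1.5),
    FvCBParameters(vcmax=80.0, j=110.0, rd=0.8),
    FvCBParameters(vcmax=120.0, j=140.0, tpu=8.5, rd=2.0),
])
def test_assignment_matches_bruteforce_oracle_small_curves(params):
    ci = np.array([75, 150, 300, 500, 700, 900, 1200, 1500.0])
    _, _, _, a = fvcb_forward(params, ci)
    rng = np.random.default_rng(11)
    for noise in (0.0, 0.01):
        av = a * (1 + noise * rng.standard_normal(len(a)))
        oracle = _oracle_best_assignment(ci, av)
        est = ACiFitter().fit(ci, av)
        labels = list(est.labels_)
        r_fit = labels.count("Rubisco")
        s_fit = r_fit + labels.count("RuBP")
        assert oracle is not None
        assert est.sse_ <= oracle[0] * (1 + 1e-6) + 1e-10
        if abs(est.sse_ - oracle[0]) > 1e-6 * max(oracle[0], 1e-12):
            pytest.fail(f"SSE mismatch: {est.sse_} vs oracle {oracle[0]}")


def test_estimator_predict_matches_forward():
    _, _, _, a = fvcb_forward(P_REF, CI_GRID)
    est = ACiFitter().fit(CI_GRID, a)
    pred = est.predict(CI_GRID)
    assert np.allclose(pred, a, atol=1e-6)


def test_sklearn_param_interface():
    est = ACiFitter(gm=0.5)
    assert est.get_params()["gm"] == 0.5
    est.set_params(gm=math.inf)
    assert math.isinf(est.gm)


def test_temperature_adjust_identity_and_roundtrip():
    same = temperature_adjust(P_REF, 25.0)
    assert same.vcmax == pytest.approx(P_REF.vcmax, rel=1e-12)
    down = temperature_adjust(P_REF, 24.0, inverse=True)   # 25 °C -> 24 °C
    back = temperature_adjust(down, 24.0)                  # 24 °C -> 25 °C
    assert back.vcmax == pytest.approx(P_REF.vcmax, rel=1e-12)
    assert back.kc == pytest.approx(P_REF.kc, rel=1e-12)


def test_temperature_adjust_magnitude_and_monotonicity():
    adj24 = temperature_adjust(P_REF, 24.0)
    # exact Arrhenius factor for Ea(Vcmax) = 65.33 kJ/mol over 24 -> 25 °C
    expected = math.exp(65330.0 / 8.314 * (1 / 297.15 - 1 / 298.15))
    assert adj24.vcmax / P_REF.vcmax == pytest.approx(expected, rel=1e-12)
    assert abs(adj24.vcmax / P_REF.vcmax - 1) < 0.10  # < 10 % per °C
    assert adj24.vcmax > P_REF.vcmax  # cooler leaf -> larger 25 °C value
    adj26 = temperature_adjust(P_REF, 26.0)
    assert adj26.vcmax < P_REF.vcmax
    with pytest.raises(FvCBDomainError):
        temperature_adjust(P_REF, 55.0)
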