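"""Farquhar–von Caemmerer–Berry (FvCB) photosynthesis model and A/Ci fitting.

The steady-state biochemical model partitions net assimilation into three
potential limitations evaluated at the chloroplastic CO2 mole fraction Cc:

.. math::

    A_c = V_{cmax} \\frac{C_c - \\Gamma^*}{C_c + K_c(1 + O/K_o)} - R_d
    \\qquad
    A_j = J \\frac{C_c - \\Gamma^*}{4 C_c + 8\\Gamma^*} - R_d
    \\qquad
    A_p = 3\\,TPU - R_d

with the realized rate ``A = min(Ac, Aj, Ap)``.  Kinetic constants default to
the Bernacchi 25 °C values (Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹,
Γ* = 42.75 µmol mol⁻¹, O = 210 mmol mol⁻¹).

Fitting (:class:`ACiFitter`) follows the segmented-limitation approach of the
standard spreadsheet fitting tools: every monotone assignment of the
Ci-sorted points to the Rubisco → RuBP → TPU sequence is enumerated, and
because the model is linear in (Vcmax, J, TPU, Rd) once the assignment and gm
are fixed, each candidate is solved exactly with bounded linear least
squares.  The assignment with minimal SSE whose labels agree with the min
rule at its own fitted parameters is returned; near-ties prefer the
assignment with more Rubisco-limited points (conservative Vcmax).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import lsq_linear
from sklearn.base import BaseEstimator, RegressorMixin

R_GAS = 8.314  # J mol⁻¹ K⁻¹

#: Bernacchi-style activation energies (J mol⁻¹) for Arrhenius normalization
DEFAULT_ACTIVATION_ENERGIES = {
    "vcmax": 65330.0,
    "j": 43540.0,
    "tpu": 53100.0,
    "rd": 46390.0,
    "kc": 79430.0,
    "ko": 36380.0,
    "gamma_star": 37830.0,
}

LABELS = ("Rubisco", "RuBP", "TPU")


class FvCBDomainError(ValueError):
    pass


@dataclass
class FvCBParameters:
    """Biochemical parameters; rates in µmol m⁻² s⁻¹, Ko and O in mmol mol⁻¹."""

    vcmax: float
    j: float
    tpu: float = math.inf
    rd: float = 1.5
    gm: float = math.inf          # mol m⁻² s⁻¹ bar⁻¹
    gamma_star: float = 42.75     # µmol mol⁻¹
    kc: float = 404.9             # µmol mol⁻¹
    ko: float = 278.4             # mmol mol⁻¹
    o: float = 210.0              # mmol mol⁻¹

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc·(1 + O/Ko), µmol mol⁻¹."""
        return self.kc * (1.0 + self.o / self.ko)


def fvcb_forward(params: FvCBParameters, cc):
    """Evaluate (Ac, Aj, Ap, A_min) at chloroplastic CO2 ``cc`` (µmol mol⁻¹)."""
    cc = np.asarray(cc, dtype=float)
    if np.any(cc < 0):
        raise FvCBDomainError("cc must be ≥ 0")
    ac = params.vcmax * (cc - params.gamma_star) / (cc + params.km) - params.rd
    aj = params.j * (cc - params.gamma_star) / (4.0 * cc + 8.0 * params.gamma_star) - params.rd
    ap = np.full_like(ac, 3.0 * params.tpu - params.rd) if np.isfinite(params.tpu) \
        else np.full_like(ac, np.inf)
    a_min = np.minimum(np.minimum(ac, aj), ap)
    return ac, aj, ap, a_min


def cc_from_ci(ci, a, gm: float):
    """Chloroplastic CO2 Cc = Ci − A/gm; identity when gm is infinite.

    Points driven below zero by the correction are returned as NaN so callers
    can flag and exclude them.
    """
    ci = np.asarray(ci, dtype=float)
    if not gm > 0:
        raise FvCBDomainError("gm must be > 0 (or infinite)")
    if np.isinf(gm):
        return ci.copy()
    cc = ci - np.asarray(a, dtype=float) / gm
    return np.where(cc < 0, np.nan, cc)


def temperature_adjust(params: FvCBParameters, tleaf: float,
                       activation_energies: dict | None = None,
                       inverse: bool = False) -> FvCBParameters:
    """Arrhenius-normalize parameters measured at ``tleaf`` (°C) to 25 °C.

    With ``inverse=True`` the scaling runs 25 °C → ``tleaf`` instead, so the
    two directions compose to the identity.
    """
    if not (0 < tleaf < 50):
        raise FvCBDomainError("tleaf must be in (0, 50) °C")
    ea = dict(DEFAULT_ACTIVATION_ENERGIES)
    if activation_energies:
        ea.update(activation_energies)
    tk = tleaf + 273.15
    tref = 298.15
    out = {}
    for name, energy in ea.items():
        value = getattr(params, name)
        if not np.isfinite(value):
            out[name] = value
            continue
        factor = math.exp(energy / R_GAS * (1.0 / tk - 1.0 / tref))
        out[name] = value / factor if inverse else value * factor
    return replace(params, **out)


@dataclass
class ACiFit:
    """Result of fitting one A/Ci curve."""

    params: FvCBParameters
    labels: list[str]
    fitted: np.ndarray
    sse: float
    admissible: bool
    j_identifiable: bool = True
    tpu_limited: bool = False


class ACiFitter(RegressorMixin, BaseEstimator):
    """Fit FvCB parameters (Vcmax, J, TPU, Rd) to an A/Ci curve.

    Parameters
    ----------
    gm : float
        Mesophyll conductance (mol m⁻² s⁻¹ bar⁻¹); infinite (default) fits
        on a Ci basis.
    gamma_star, kc, ko, o : float
        Rubisco kinetic constants at 25 °C (see :class:`FvCBParameters`).
    rd_max : float
        Upper bound for the fitted day respiration.
    admissible_tol : float
        Relative band (on max(1, |A|)) within which the assigned limitation
        must agree with the min rule at the fitted parameters; wide enough to
        tolerate a noisy crossover point, exact labelings are unaffected.
    tie_rel_tol : float
        Relative SSE window within which assignments count as tied; ties go
        to the assignment with more Rubisco-limited points.

    Attributes (after ``fit``)
    --------------------------
    vcmax_, j_, tpu_, rd_ : fitted parameters (``j_`` is None when no point
        is RuBP-limited; ``tpu_`` is ``inf`` when no point is TPU-limited).
    labels_ : per-point limitation state, in the order of the input points.
    sse_, admissible_, params_, fitted_ : fit diagnostics.
    """

    def __init__(self, gm: float = math.inf, gamma_star: float = 42.75,
                 kc: float = 404.9, ko: float = 278.4, o: float = 210.0,
                 rd_max: float = 20.0, admissible_tol: float = 0.02,
                 tie_rel_tol: float = 1e-6, min_tpu_points: int = 2):
        self.gm = gm
        self.gamma_star = gamma_star
        self.kc = kc
        self.ko = ko
        self.o = o
        self.rd_max = rd_max
        self.admissible_tol = admissible_tol
        self.tie_rel_tol = tie_rel_tol
        self.min_tpu_points = min_tpu_points

    # -- internal -----------------------------------------------------------
    def _solve_assignment(self, cc, a, r, s):
        """Bounded linear LSQ for the assignment [0,r)=Rubisco, [r,s)=RuBP, [s,n)=TPU."""
        n = len(cc)
        km = self.kc * (1.0 + self.o / self.ko)
        x1 = (cc - self.gamma_star) / (cc + km)
        x2 = (cc - self.gamma_star) / (4.0 * cc + 8.0 * self.gamma_star)
        cols, names = [], []
        rub = np.zeros(n); rub[:r] = x1[:r]
        cols.append(rub); names.append("vcmax")
        if s > r:
            rubp = np.zeros(n); rubp[r:s] = x2[r:s]
            cols.append(rubp); names.append("j")
        if s < n:
            tpu = np.zeros(n); tpu[s:] = 3.0
            cols.append(tpu); names.append("tpu")
        cols.append(-np.ones(n)); names.append("rd")
        design = np.column_stack(cols)
        lo = np.zeros(design.shape[1])
        hi = np.full(design.shape[1], np.inf)
        hi[-1] = self.rd_max
        res = lsq_linear(design, a, bounds=(lo, hi))
        coef = dict(zip(names, res.x))
        fitted = design @ res.x
        sse = float(np.sum((a - fitted) ** 2))
        return coef, fitted, sse

    def _admissible(self, params, cc, r, s):
        ac, aj, ap, _ = fvcb_forward(params, cc)
        if not np.isfinite(params.j):  # J not in the fit: RuBP never binding
            aj = np.full_like(ac, np.inf)
        a_min = np.minimum(np.minimum(ac, aj), ap)
        chosen = np.empty(len(cc))
        chosen[:r] = ac[:r]
        chosen[r:s] = aj[r:s]
        chosen[s:] = ap[s:]
        return bool(np.all(np.abs(chosen - a_min) <= self.admissible_tol
                           * np.maximum(1.0, np.abs(a_min)))), chosen

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X, y):
        ci = np.asarray(X, dtype=float).reshape(-1)
        a = np.asarray(y, dtype=float).reshape(-1)
        if ci.shape != a.shape:
            raise ValueError("X and y must have the same length")
        if len(ci) < 5:
            raise FvCBDomainError("need at least 5 A/Ci points")
        if not (np.all(np.isfinite(ci)) and np.all(np.isfinite(a))):
            raise FvCBDomainError("non-finite values in curve")

        cc_all = cc_from_ci(ci, a, self.gm)
        keep = np.isfinite(cc_all)
        if keep.sum() < 5:
            raise FvCBDomainError("fewer than 5 usable points after Cc correction")
        order = np.argsort(cc_all[keep], kind="stable")
        idx = np.flatnonzero(keep)[order]
        cc = cc_all[idx]
        av = a[idx]
        n = len(cc)

        candidates = []  # (sse, r, s, coef, fitted)
        for r in range(1, n + 1):
            for s in range(r, n + 1):
                if s < n and n - s < self.min_tpu_points:
                    continue  # a TPU plateau needs enough support to be identifiable
                coef, fitted, sse = self._solve_assignment(cc, av, r, s)
                params = self._coef_to_params(coef)
                ok, _ = self._admissible(params, cc, r, s)
                candidates.append((sse, r, s, coef, fitted, ok))

        admissible = [c for c in candidates if c[5]]
        pool = admissible if admissible else candidates
        if not admissible:
            warnings.warn("no admissible limitation assignment; returning best raw fit",
                          stacklevel=2)
        best_sse = min(c[0] for c in pool)
        window = best_sse * (1.0 + self.tie_rel_tol) + 1e-12
        sse, r, s, coef, fitted, ok = max(
            (c for c in pool if c[0] <= window), key=lambda c: c[1])

        self.params_ = self._coef_to_params(coef)
        self.vcmax_ = coef["vcmax"]
        self.j_ = coef.get("j")
        self.tpu_ = coef.get("tpu", math.inf)
        self.rd_ = coef["rd"]
        self.sse_ = sse
        self.admissible_ = ok
        self.j_identifiable_ = "j" in coef
        self.tpu_limited_ = s < n
        labels = np.empty(n, dtype=object)
        labels[:r] = LABELS[0]
        labels[r:s] = LABELS[1]
        labels[s:] = LABELS[2]
        self.labels_ = np.empty(len(ci), dtype=object)
        self.labels_[:] = None
        self.labels_[idx] = labels
        fit_all = np.full(len(ci), np.nan)
        fit_all[idx] = fitted
        self.fitted_ = fit_all
        self.n_points_ = n
        return self

    def _coef_to_params(self, coef) -> FvCBParameters:
        return FvCBParameters(
            vcmax=coef["vcmax"],
            j=coef.get("j", math.inf),
            tpu=coef.get("tpu", math.inf),
            rd=coef["rd"], gm=self.gm, gamma_star=self.gamma_star,
            kc=self.kc, ko=self.ko, o=self.o,
        )

    def predict(self, X):
        ci = np.asarray(X, dtype=float).reshape(-1)
        a = np.zeros_like(ci)
        # with finite gm the realized A solves A = model(Ci − A/gm); a short
        # fixed-point iteration suffices (identity when gm is infinite)
        for _ in range(1 if np.isinf(self.gm) else 50):
            cc = np.nan_to_num(cc_from_ci(ci, a, self.gm), nan=0.0)
            _, _, _, a = fvcb_forward(self.params_, cc)
        return a

    def result_(self) -> ACiFit:
        return ACiFit(
            params=self.params_, labels=list(self.labels_), fitted=self.fitted_,
            sse=self.sse_, admissible=self.admissible_,
            j_identifiable=self.j_identifiable_, tpu_limited=self.tpu_limited_,
        )


def fit_aci(curve, **options) -> ACiFit:
    """Fit one A/Ci curve given as a sequence of (ci, a) pairs.

    Thin wrapper over :class:`ACiFitter`; ``options`` are estimator
    parameters (gm, kinetic constants, tolerances).
    """
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("curve must be a sequence of (ci, a) pairs")
    est = ACiFitter(**options).fit(pts[:, 0], pts[:, 1])
    return est.result_()
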