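"""Forward simulation of a complete waterlogging experiment.

The generator emulates a 2-cultivar × 2-treatment randomized complete block
experiment on cucumber seedlings (4 blocks, 6 measured plants per cell):
morphology traits, a steady-state gas-exchange table, raw PAM fluorescence
records, A/Ci curves and light-response curves — everything the analysis
pipeline consumes — from a :class:`ScenarioConfig` preset that encodes
treatment effect sizes as fractional declines of the control cell means.

Noise model
-----------
Each trait receives a Gaussian *plot* effect shared by the plants of one
block-cell plus an independent plant-level error at half the plot SD.
Morphology traits use additive SDs; strictly positive gas-exchange traits use
multiplicative noise with a capped coefficient of variation so that records
stay physically admissible (gs > 0 etc.).  Fluorescence is simulated in yield
space — per-plant quantum-yield targets are jittered, re-closed so the PSII
energy partition sums to one, and inverted to raw F-levels with
:func:`fluorescence_from_targets` — so every simulated record is exactly
consistent with the quenching calculus.  Response curves get per-point noise
(multiplicative for A/Ci, additive for light curves).

With all noise scales at zero the simulated cell means equal the configured
means exactly, and a fixed seed reproduces the bundle bit for bit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluorescence import estimate_fo_prime
from .fvcb import FvCBParameters, fvcb_forward
from .light import light_forward
from .records import FluorescenceRecord, ProtocolConfig, validate_record

MORPH_TRAITS = ("LN", "LA", "FM", "DM")


class ScenarioError(ValueError):
    pass


@dataclass
class FluorescenceTargets:
    """Per-cell quantum-yield targets realized by the raw-F inverse construction."""

    fv_fm: float
    phi_psii: float
    npq: float
    phi_no: float


@dataclass
class ScenarioConfig:
    """Synthetic-experiment preset.

    ``morphology_effects`` / ``physiology_effects`` map cultivar → trait →
    signed fractional change under waterlogging, with the decline-positive
    sign convention (+0.14 means a 14 % decline, −0.06 a 6 % increase).
    ``noise_sd`` holds additive plot-level SDs for morphology; ``gas_cv``
    holds plot-level CVs for the multiplicative gas-trait noise.
    """

    cultivars: tuple = ("Marketmore", "Straight 8")
    treatments: tuple = ("control", "waterlogged")
    n_blocks: int = 4
    n_plants: int = 6      # measured plants per cell (12 grown, 6 harvested)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    morphology_means: dict = field(default_factory=dict)       # trait -> control mean
    morphology_effects: dict = field(default_factory=dict)     # cultivar -> trait -> frac
    physiology_means: dict = field(default_factory=dict)       # cultivar -> trait -> mean
    physiology_effects: dict = field(default_factory=dict)     # cultivar -> trait -> frac
    fvcb_presets: dict = field(default_factory=dict)           # (cultivar, treatment) -> FvCBParameters
    light_presets: dict = field(default_factory=dict)          # (cultivar, treatment) -> ye params
    fluorescence_targets: dict = field(default_factory=dict)   # (cultivar, treatment) -> FluorescenceTargets
    fm_scale: dict = field(default_factory=dict)               # (cultivar, treatment) -> a.u.

    noise_sd: dict = field(default_factory=dict)               # morphology plot SDs
    gas_cv: dict = field(default_factory=dict)                 # gas-trait plot CVs
    fluor_noise: dict = field(default_factory=dict)            # yield-space plot SDs
    plant_sd_ratio: float = 0.5
    aci_noise_cv: float = 0.02
    light_noise_sd: float = 1.23
    alpha: float = 0.84
    f_psii: float = 0.5
    rd_day: float = 1.5    # day respiration used by the Vc/Vo partitioning
    seed: int = 0

    def cells(self):
        for cv in self.cultivars:
            for tr in self.treatments:
                yield cv, tr

    def validate(self) -> list[str]:
        findings = list(self.protocol.validate())
        if self.n_blocks < 2:
            findings.append("n_blocks ≥ 2")
        if self.n_plants < 1:
            findings.append("n_plants ≥ 1")
        for side in (self.morphology_effects, self.physiology_effects):
            for cv, effects in side.items():
                for trait, frac in effects.items():
                    if not -1 < frac < 1:
                        findings.append(f"effect {cv}/{trait} in (−1,1)")
        for name in ("noise_sd", "gas_cv", "fluor_noise"):
            for trait, sd in getattr(self, name).items():
                if sd < 0:
                    findings.append(f"{name}[{trait}] ≥ 0")
        for key in self.fluorescence_targets:
            t = self.fluorescence_targets[key]
            resid = 1.0 - t.phi_psii - t.phi_no * (1.0 + t.npq)
            if abs(resid) > 1e-9:
                findings.append(f"fluorescence targets {key}: partition residual {resid:.2e}")
        return findings

    def without_noise(self) -> "ScenarioConfig":
        """Copy of the config with every noise scale set to zero."""
        cfg = copy.deepcopy(self)
        cfg.noise_sd = {k: 0.0 for k in cfg.noise_sd}
        cfg.gas_cv = {k: 0.0 for k in cfg.gas_cv}
        cfg.fluor_noise = {k: 0.0 for k in cfg.fluor_noise}
        cfg.aci_noise_cv = 0.0
        cfg.light_noise_sd = 0.0
        return cfg


def _ye_phi_for_amax(target: float, beta: float, gamma: float, ic: float,
                     i_ref: float = 1500.0) -> float:
    """Solve the Ye amplitude φ so the forward value at ``i_ref`` hits ``target``."""
    return target * (1.0 + gamma * i_ref) / ((1.0 - beta * i_ref) * (i_ref - ic))


def default_study_config() -> ScenarioConfig:
    """The default scenario: reference effect sizes and pooled-SEM noise levels.

    Effect fractions (decline positive) per cultivar: morphology LN/LA/FM/DM
    8/8/14/8 % (Marketmore) and 14/17/25/25 % (Straight 8); gs/E/WUE
    22/14/52 % and 24/13/40 %; Ci −6/−4 % (an increase); Ls 43/34 %; Vcmax/J
    14/15 % and 33/14 %; ETR 23/26 %; light-saturated Amax 8/20 % with
    control Amax(1500) of 23.62 and 19.59 µmol m⁻² s⁻¹.  Plot-level noise
    SDs are the reference pooled SEMs scaled by √4 blocks; positive-support
    gas traits use the equivalent CV capped at 0.15 (see docs/methods.md).

    Control-cell absolute means for morphology and steady-state gas exchange
    are not authoritative — only the relative changes are — and are fixed at
    realistic values for 24-day cucumber seedlings.  Ci control means are
    derived from the joint consistency of the Ci and Ls effects
    (Ci/Ca = e_Ls/(e_Ls + |e_Ci|)); the assimilation decline follows from the
    WUE and gs effects through A = WUE·gs.
    """
    M, S = "Marketmore", "Straight 8"
    ca = 415.0

    morphology_means = {"LN": 12.0, "LA": 380.0, "FM": 10.0, "DM": 0.9}
    morphology_effects = {
        M: {"LN": 0.08, "LA": 0.08, "FM": 0.14, "DM": 0.08},
        S: {"LN": 0.14, "LA": 0.17, "FM": 0.25, "DM": 0.25},
    }
    # √4-scaled pooled SEMs: LN 0.136, LA 13.928, FM 0.403, DM 0.046
    noise_sd = {"LN": 0.272, "LA": 27.856, "FM": 0.806, "DM": 0.092}

    ls_eff = {M: 0.43, S: 0.34}
    ci_eff = {M: -0.06, S: -0.04}
    ci_mean = {cv: ca * ls_eff[cv] / (ls_eff[cv] + abs(ci_eff[cv])) for cv in (M, S)}

    physiology_means = {
        M: {"gs": 0.45, "WUE": 44.0, "E": 5.2, "Ci": ci_mean[M]},
        S: {"gs": 0.47, "WUE": 40.0, "E": 5.4, "Ci": ci_mean[S]},
    }
    physiology_effects = {
        M: {"gs": 0.22, "E": 0.14, "WUE": 0.52, "Ci": ci_eff[M], "Ls": ls_eff[M],
            "Vc": 0.23, "Vo": 0.33, "Vcmax": 0.14, "Jmax": 0.15,
            "PhiPSII": 0.22, "ETR": 0.23, "Fo": 0.05, "Amax": 0.08},
        S: {"gs": 0.24, "E": 0.13, "WUE": 0.40, "Ci": ci_eff[S], "Ls": ls_eff[S],
            "Vc": 0.19, "Vo": 0.28, "Vcmax": 0.33, "Jmax": 0.14,
            "PhiPSII": 0.25, "ETR": 0.26, "Fo": 0.06, "Amax": 0.20},
    }
    # plot-level CV = SEM·√4 / control mean, capped at 0.15
    cap = 0.15
    sems = {"gs": 0.153, "WUE": 2.77, "Ci": 4.91, "E": 0.7}
    gas_cv = {t: min(2.0 * sems[t] / physiology_means[M][t], cap) for t in sems}

    fvcb_presets = {}
    for cv, (vc0, j0) in {M: (105.0, 160.0), S: (100.0, 155.0)}.items():
        e = physiology_effects[cv]
        fvcb_presets[(cv, "control")] = FvCBParameters(vcmax=vc0, j=j0, rd=1.5)
        fvcb_presets[(cv, "waterlogged")] = FvCBParameters(
            vcmax=vc0 * (1 - e["Vcmax"]), j=j0 * (1 - e["Jmax"]), rd=1.5)

    beta, gamma, ic = 5e-5, 1.5e-3, 28.0
    amax_control = {M: 23.62, S: 19.59}
    light_presets = {}
    for cv in (M, S):
        for tr in ("control", "waterlogged"):
            target = amax_control[cv]
            if tr == "waterlogged":
                target *= 1 - physiology_effects[cv]["Amax"]
            light_presets[(cv, tr)] = {
                "phi": _ye_phi_for_amax(target, beta, gamma, ic),
                "beta": beta, "gamma": gamma, "ic": ic,
            }

    def targets(fv, phi, no):
        return FluorescenceTargets(fv_fm=fv, phi_psii=phi,
                                   npq=(1 - phi) / no - 1, phi_no=no)

    fluorescence_targets = {
        (M, "control"): targets(0.78, 0.40, 0.25),
        (S, "control"): targets(0.77, 0.40, 0.25),
        (M, "waterlogged"): targets(0.765, 0.40 * (1 - 0.23), 0.28),
        (S, "waterlogged"): targets(0.755, 0.40 * (1 - 0.26), 0.28),
    }
    fm_scale = {key: 2000.0 for key in fluorescence_targets}
    # yield-space plot SDs from the reference pooled SEMs (Fv/Fm 0.008,
    # ΦPSII 0.03, ΦNO 0.015, Fm 85.43) scaled by √4
    fluor_noise = {"fv_fm": 0.016, "phi_psii": 0.06, "phi_no": 0.03,
                   "fm_cv": 2.0 * 85.43 / 2000.0}

    return ScenarioConfig(
        morphology_means=morphology_means,
        morphology_effects=morphology_effects,
        physiology_means=physiology_means,
        physiology_effects=physiology_effects,
        fvcb_presets=fvcb_presets,
        light_presets=light_presets,
        fluorescence_targets=fluorescence_targets,
        fm_scale=fm_scale,
        noise_sd=noise_sd,
        gas_cv=gas_cv,
        fluor_noise=fluor_noise,
    )


def fluorescence_from_targets(targets, fm_scale: float = 2000.0, q: float = 1400.0,
                              alpha: float = 0.84, f_psii: float = 0.5,
                              tol: float = 1e-6,
                              clamp_fo_prime: bool = False) -> FluorescenceRecord:
    """Invert the quenching calculus: raw F-levels realizing given yields.

    ``targets`` is a :class:`FluorescenceTargets` or a (fv_fm, phi_psii, npq,
    phi_no) tuple.  The triple must satisfy the energy-partition identity
    ΦPSII = 1 − ΦNO·(1 + NPQ); otherwise a :class:`ScenarioError` reports the
    implied residual.  Construction: Fm = fm_scale, Fo = Fm·(1 − Fv/Fm),
    Fm′ = Fm/(1 + NPQ), Fs = ΦNO·Fm, Fo′ from the Oxborough–Baker relation.
    Running the forward calculus on the result recovers the targets exactly.
    """
    if not isinstance(targets, FluorescenceTargets):
        targets = FluorescenceTargets(*targets)
    t = targets
    for name, val, lo, hi in (("fv_fm", t.fv_fm, 0, 1), ("phi_psii", t.phi_psii, 0, 1),
                              ("phi_no", t.phi_no, 0, 1)):
        if not lo < val < hi:
            raise ScenarioError(f"{name} must be in ({lo},{hi})")
    if t.npq < 0:
        raise ScenarioError("npq must be ≥ 0")
    resid = 1.0 - t.phi_psii - t.phi_no * (1.0 + t.npq)
    if abs(resid) > tol:
        raise ScenarioError(
            f"inconsistent targets: ΦPSII + ΦNPQ + ΦNO − 1 residual = {-resid:.3e}")
    fm = float(fm_scale)
    fo = fm * (1.0 - t.fv_fm)
    fm_prime = fm / (1.0 + t.npq)
    fs = t.phi_no * fm
    fo_prime = estimate_fo_prime(fo, fm, fm_prime)
    if clamp_fo_prime:
        # extreme yield combinations can push the Oxborough–Baker estimate
        # above Fs; Fo′ does not enter the four target yields, so clamping
        # keeps the record admissible without disturbing the round trip
        fo_prime = min(fo_prime, fs)
    rec = FluorescenceRecord(fo=fo, fm=fm, fs=fs, fm_prime=fm_prime,
                             fo_prime=fo_prime, q=q, alpha=alpha, f_psii=f_psii)
    findings = validate_record(rec)
    if findings:
        raise ScenarioError("targets produce inadmissible record: " + "; ".join(findings))
    return rec


@dataclass
class ExperimentBundle:
    """Everything one simulated experiment produced."""

    morphology: pd.DataFrame       # long TraitTable
    gas: pd.DataFrame              # steady-state gas table (core_io dialect)
    fluorescence: pd.DataFrame     # raw F-levels per plant at actinic light
    aci_curves: pd.DataFrame       # cultivar, treatment, block, ci, a
    light_curves: pd.DataFrame     # cultivar, treatment, block, i, a
    config: ScenarioConfig = None
    seed: int = 0


ALL_PARTS = ("morphology", "gas", "fluorescence", "aci", "light")


def _effect_factor(cfg, side, cultivar, treatment, trait):
    if treatment == cfg.treatments[0]:
        return 1.0
    return 1.0 - side.get(cultivar, {}).get(trait, 0.0)


def _simulate_morphology(cfg: ScenarioConfig, rng) -> pd.DataFrame:
    rows = []
    for cv, tr in cfg.cells():
        for b in range(1, cfg.n_blocks + 1):
            plot = {t: rng.normal(0.0, cfg.noise_sd.get(t, 0.0))
                    for t in cfg.morphology_means}
            for p in range(1, cfg.n_plants + 1):
                vals = {}
                for t, mean in cfg.morphology_means.items():
                    mu = mean * _effect_factor(cfg, cfg.morphology_effects, cv, tr, t)
                    v = mu + plot[t] + rng.normal(
                        0.0, cfg.noise_sd.get(t, 0.0) * cfg.plant_sd_ratio)
                    vals[t] = v
                    rows.append({"cultivar": cv, "treatment": tr, "block": b,
                                 "plant": p, "trait": t, "value": v})
                if "DM" in vals and "FM" in vals and vals["FM"] != 0:
                    rows.append({"cultivar": cv, "treatment": tr, "block": b,
                                 "plant": p, "trait": "pct_DM",
                                 "value": 100.0 * vals["DM"] / vals["FM"]})
    return pd.DataFrame(rows)


def _yield_draw(cfg, rng, key):
    """Per-plant fluorescence yield targets: cell target + plot + plant jitter,
    re-closed so the partition identity holds exactly."""
    cell = cfg.fluorescence_targets[key]
    sd_fv = cfg.fluor_noise.get("fv_fm", 0.0)
    sd_ps = cfg.fluor_noise.get("phi_psii", 0.0)
    sd_no = cfg.fluor_noise.get("phi_no", 0.0)
    return cell, sd_fv, sd_ps, sd_no


def _simulate_fluorescence(cfg: ScenarioConfig, rng, q: float | None = None) -> pd.DataFrame:
    rows = []
    q = cfg.protocol.actinic if q is None else q
    r = cfg.plant_sd_ratio
    for cv, tr in cfg.cells():
        cell, sd_fv, sd_ps, sd_no = _yield_draw(cfg, rng, (cv, tr))
        fm0 = cfg.fm_scale[(cv, tr)]
        fm_cv = cfg.fluor_noise.get("fm_cv", 0.0)
        for b in range(1, cfg.n_blocks + 1):
            plot = rng.normal(0.0, [sd_fv, sd_ps, sd_no])
            plot_fm = rng.normal(0.0, fm_cv)
            for p in range(1, cfg.n_plants + 1):
                plant = rng.normal(0.0, [sd_fv * r, sd_ps * r, sd_no * r])
                fv = float(np.clip(cell.fv_fm + plot[0] + plant[0], 0.55, 0.87))
                psii = float(np.clip(cell.phi_psii + plot[1] + plant[1], 0.02, 0.90))
                no = float(np.clip(cell.phi_no + plot[2] + plant[2],
                                   0.05, (1.0 - psii) * 0.98))
                npq = (1.0 - psii) / no - 1.0
                fm = fm0 * max(1.0 + plot_fm + rng.normal(0.0, fm_cv * r), 0.2)
                rec = fluorescence_from_targets(
                    FluorescenceTargets(fv, psii, npq, no), fm_scale=fm, q=q,
                    alpha=cfg.alpha, f_psii=cfg.f_psii, clamp_fo_prime=True)
                rows.append({"cultivar": cv, "treatment": tr, "block": b, "plant": p,
                             "Fo": rec.fo, "Fm": rec.fm, "Fs": rec.fs,
                             "Fmp": rec.fm_prime, "Fop": rec.fo_prime, "Q": q})
    return pd.DataFrame(rows)


def _simulate_gas(cfg: ScenarioConfig, rng) -> pd.DataFrame:
    rows = []
    r = cfg.plant_sd_ratio
    traits = ("gs", "WUE", "E", "Ci")
    fluor = _simulate_fluorescence(cfg, rng, q=cfg.protocol.chamber_ppfd)
    fl_idx = fluor.set_index(["cultivar", "treatment", "block", "plant"])
    for cv, tr in cfg.cells():
        means = {t: cfg.physiology_means[cv][t]
                 * _effect_factor(cfg, cfg.physiology_effects, cv, tr, t)
                 for t in traits}
        for b in range(1, cfg.n_blocks + 1):
            plot = {t: rng.normal(0.0, cfg.gas_cv.get(t, 0.0)) for t in traits}
            for p in range(1, cfg.n_plants + 1):
                v = {}
                for t in traits:
                    factor = 1.0 + plot[t] + rng.normal(0.0, cfg.gas_cv.get(t, 0.0) * r)
                    v[t] = means[t] * max(factor, 0.05)
                fl = fl_idx.loc[(cv, tr, b, p)]
                rows.append({
                    "cultivar": cv, "treatment": tr, "block": b, "plant": p,
                    "A": v["WUE"] * v["gs"], "gs": v["gs"], "E": v["E"],
                    "Ci": v["Ci"], "Ca": cfg.protocol.chamber_co2,
                    "Q": cfg.protocol.chamber_ppfd, "Tleaf": cfg.protocol.chamber_t,
                    "RH": cfg.protocol.chamber_rh,
                    "Fo": fl["Fo"], "Fm": fl["Fm"], "Fs": fl["Fs"],
                    "Fmp": fl["Fmp"], "Fop": fl["Fop"],
                })
    return pd.DataFrame(rows)


def _simulate_aci(cfg: ScenarioConfig, rng) -> pd.DataFrame:
    rows = []
    ci = np.asarray(cfg.protocol.co2_sequence(), dtype=float)
    for cv, tr in cfg.cells():
        params = cfg.fvcb_presets[(cv, tr)]
        _, _, _, a_true = fvcb_forward(params, ci)
        for b in range(1, cfg.n_blocks + 1):
            a = a_true * (1.0 + rng.normal(0.0, cfg.aci_noise_cv, size=len(ci)))
            for x, y in zip(ci, a):
                rows.append({"cultivar": cv, "treatment": tr, "block": b,
                             "ci": x, "a": y})
    return pd.DataFrame(rows)


def _simulate_light(cfg: ScenarioConfig, rng) -> pd.DataFrame:
    rows = []
    levels = np.asarray(cfg.protocol.ppfd_levels, dtype=float)
    for cv, tr in cfg.cells():
        a_true = light_forward("ye_modified", cfg.light_presets[(cv, tr)], levels)
        for b in range(1, cfg.n_blocks + 1):
            a = a_true + rng.normal(0.0, cfg.light_noise_sd, size=len(levels))
            for x, y in zip(levels, a):
                rows.append({"cultivar": cv, "treatment": tr, "block": b,
                             "i": x, "a": y})
    return pd.DataFrame(rows)


def simulate_experiment(config: ScenarioConfig, seed: int | None = None,
                        parts=ALL_PARTS) -> ExperimentBundle:
    """Simulate one experiment; identical seeds give bit-identical bundles.

    Each part draws from its own seed stream, so generating a subset of the
    bundle reproduces exactly the tables a full simulation would have given.
    """
    findings = config.validate()
    if findings:
        raise ScenarioError("invalid scenario config: " + "; ".join(findings))
    seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(seed).spawn(len(ALL_PARTS))
    rngs = {part: np.random.default_rng(child)
            for part, child in zip(ALL_PARTS, children)}
    empty = pd.DataFrame()
    return ExperimentBundle(
        morphology=_simulate_morphology(config, rngs["morphology"])
        if "morphology" in parts else empty,
        gas=_simulate_gas(config, rngs["gas"]) if "gas" in parts else empty,
        fluorescence=_simulate_fluorescence(config, rngs["fluorescence"])
        if "fluorescence" in parts else empty,
        aci_curves=_simulate_aci(config, rngs["aci"]) if "aci" in parts else empty,
        light_curves=_simulate_light(config, rngs["light"]) if "light" in parts else empty,
        config=config, seed=seed,
    )
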