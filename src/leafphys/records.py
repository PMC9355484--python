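"""Domain records shared across the pipeline.

The package operates on two kinds of single-observation records — a
steady-state infrared-gas-analyzer (IRGA) observation and a pulse-amplitude
modulated (PAM) fluorescence quenching measurement — plus the measurement
protocol describing CO2 / light setpoint sequences.

Validation is deliberately *total*: :func:`validate_record` returns a list of
violated invariants and never raises, so a reader can report every problem in
a file instead of stopping at the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


@dataclass
class GasExchangeRecord:
    """One steady-state gas-exchange observation.

    Units follow the gas-exchange convention: ``a`` net CO2 assimilation
    (µmol CO2 m⁻² s⁻¹, may be negative for respiring leaves), ``gs`` stomatal
    conductance to water vapor (mol m⁻² s⁻¹), ``e`` transpiration
    (mmol H2O m⁻² s⁻¹), ``ci``/``ca`` intercellular/ambient CO2 mole fraction
    (µmol mol⁻¹), ``q`` incident PPFD (µmol photons m⁻² s⁻¹), ``tleaf`` leaf
    temperature (°C), ``rh`` relative humidity as a fraction.
    """

    a: float
    gs: float
    e: float
    ci: float
    ca: float
    q: float
    tleaf: float = 25.0
    rh: float = 0.5


@dataclass
class FluorescenceRecord:
    """Raw fluorescence levels of one quenching measurement (arbitrary units).

    ``fo``/``fm`` are the dark-adapted minimal/maximal levels, ``fs`` the
    light-adapted steady state, ``fm_prime`` the light-adapted maximum from a
    saturating flash, and ``fo_prime`` the light-adapted minimum after far-red
    illumination.  ``fo_prime`` is optional because the far-red step is often
    skipped in the field; it can be reconstructed downstream
    (:func:`leafphys.fluorescence.estimate_fo_prime`).

    ``q`` is the actinic PPFD, ``alpha`` the leaf absorptance and ``f_psii``
    the fraction of absorbed quanta reaching PSII (used only for ETR).
    """

    fo: float
    fm: float
    fs: float
    fm_prime: float
    fo_prime: float | None = None
    q: float = 0.0
    alpha: float = 0.84
    f_psii: float = 0.5


@dataclass
class ProtocolConfig:
    """Measurement-protocol settings for response curves and chamber climate.

    Defaults follow a common LI-6800 style auto-program: a bitonic CO2
    sequence starting at ambient and descending to 50 before climbing to
    1500 µmol mol⁻¹, a 12-level light curve, an 8000 µmol m⁻² s⁻¹ saturating
    pulse and 1400 µmol m⁻² s⁻¹ actinic illumination.
    """

    co2_setpoints: list[float] = field(
        default_factory=lambda: [300, 200, 100, 50, 200, 400, 600, 800, 1000, 1200, 1500]
    )
    ppfd_levels: list[float] = field(
        default_factory=lambda: [0, 10, 50, 75, 100, 200, 400, 600, 800, 1000, 1200, 1500]
    )
    saturating_pulse: float = 8000.0
    actinic: float = 1400.0
    chamber_co2: float = 415.0
    chamber_ppfd: float = 500.0
    chamber_rh: float = 0.5
    chamber_t: float = 24.0
    # whether the ambient starting point is recorded as an extra observation
    include_ambient_start: bool = False

    def co2_sequence(self) -> list[float]:
        seq = list(self.co2_setpoints)
        if self.include_ambient_start:
            seq = [self.chamber_co2] + seq
        return seq

    def validate(self) -> list[str]:
        findings = []
        if not self.co2_setpoints:
            findings.append("co2_setpoints non-empty")
        if not self.ppfd_levels:
            findings.append("ppfd_levels non-empty")
        for name in ("co2_setpoints", "ppfd_levels"):
            if any(v < 0 for v in getattr(self, name)):
                findings.append(f"{name} entries ≥ 0")
        return findings


def _finite_fields(record) -> list[str]:
    bad = []
    for f in fields(record):
        v = getattr(record, f.name)
        if v is None:
            continue
        if not isinstance(v, (int, float)) or not math.isfinite(v):
            bad.append(f"{f.name} finite")
    return bad


def validate_record(record) -> list[str]:
    """Return the list of violated invariants for a record (never raises).

    An empty list means every invariant of the record's type holds.  Each
    finding names the field(s) and the rule, e.g. ``"gs > 0"``.
    """
    findings = _finite_fields(record)
    if findings:
        return findings

    if isinstance(record, GasExchangeRecord):
        if not record.gs > 0:
            findings.append("gs > 0")
        if not record.ca > 0:
            findings.append("ca > 0")
        if not record.ci >= 0:
            findings.append("ci ≥ 0")
        if not record.q >= 0:
            findings.append("q ≥ 0")
        if not record.e >= 0:
            findings.append("e ≥ 0")
        if not (0 < record.rh < 1):
            findings.append("rh in (0,1)")
    elif isinstance(record, FluorescenceRecord):
        if not (0 < record.fo < record.fm):
            findings.append("0 < fo < fm")
        if not record.fs <= record.fm_prime:
            findings.append("fs ≤ fm_prime")
        if not record.fm_prime <= record.fm:
            findings.append("fm_prime ≤ fm")
        if record.fo_prime is not None and not record.fo_prime <= record.fs:
            findings.append("fo_prime ≤ fs")
        if not (0 < record.alpha <= 1):
            findings.append("alpha in (0,1]")
        if not (0 < record.f_psii <= 1):
            findings.append("f_psii in (0,1]")
        if not record.q >= 0:
            findings.append("q ≥ 0")
    else:  # pragma: no cover - defensive
        findings.append(f"unknown record type {type(record).__name__}")
    return findings
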