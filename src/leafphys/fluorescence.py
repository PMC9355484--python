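"""PAM chlorophyll-fluorescence calculus: quenching, yields, PSII energy
partitioning and linear electron transport rate.

All quantities derive from five raw fluorescence levels of a saturating-pulse
quenching measurement (Fo, Fm dark-adapted; Fs, Fm′, Fo′ light-adapted):

.. math::

    F_v/F_m = (F_m - F_o)/F_m \\qquad
    \\Phi_{PSII} = (F_m' - F_s)/F_m'

    \\Phi_{NO} = F_s/F_m \\qquad
    \\Phi_{NPQ} = F_s/F_m' - F_s/F_m \\qquad
    NPQ = (F_m - F_m')/F_m'

    qP = (F_m' - F_s)/(F_m' - F_o') \\qquad
    qL = qP \\cdot F_o'/F_s \\qquad
    F_v'/F_m' = (F_m' - F_o')/F_m'

The three quantum yields partition absorbed excitation energy and sum to one
algebraically.  ETR follows the Genty convention
:math:`ETR = \\Phi_{PSII} \\cdot Q \\cdot \\alpha \\cdot f_{PSII}` with the
community defaults α = 0.84 and f = 0.5.

When the far-red Fo′ measurement is absent it is reconstructed with the
Oxborough–Baker relation ``Fo' = Fo / (Fv/Fm + Fo/Fm')``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import FluorescenceRecord, validate_record


class FluorescenceDomainError(ValueError):
    """Raised when raw fluorescence levels violate the calculus' domain."""


@dataclass
class FluorescenceIndices:
    """Derived quenching / yield parameters of one quenching measurement."""

    fv_fm: float
    fvp_fmp: float
    phi_psii: float
    phi_npq: float
    phi_no: float
    qp: float
    ql: float
    one_minus_ql: float
    npq: float
    etr: float


def dark_adapted_indices(fo: float, fm: float) -> float:
    """Maximal PSII photochemical efficiency Fv/Fm = (Fm − Fo)/Fm."""
    if not (fo > 0 and fm > 0):
        raise FluorescenceDomainError("fo and fm must be positive")
    if not fo < fm:
        raise FluorescenceDomainError("requires fo < fm")
    return (fm - fo) / fm


def estimate_fo_prime(fo: float, fm: float, fm_prime: float) -> float:
    """Reconstruct the light-adapted minimal fluorescence Fo′.

    Uses the Oxborough–Baker relation ``Fo' = Fo / (Fv/Fm + Fo/Fm')`` — the
    standard fallback when the far-red measurement was not taken.  At
    Fm′ = Fm (no quenching) this returns Fo exactly.
    """
    if not (0 < fo < fm):
        raise FluorescenceDomainError("requires 0 < fo < fm")
    if not (0 < fm_prime <= fm):
        raise FluorescenceDomainError("requires 0 < fm_prime ≤ fm")
    fv_fm = (fm - fo) / fm
    return fo / (fv_fm + fo / fm_prime)


def light_adapted_indices(record: FluorescenceRecord) -> FluorescenceIndices:
    """Compute all quenching and energy-partition parameters for one record.

    ``fo_prime`` must be present; call :func:`estimate_fo_prime` first if the
    far-red step is missing.  The yield partition
    ΦPSII + ΦNPQ + ΦNO = 1 holds exactly by construction.
    """
    findings = validate_record(record)
    if findings:
        raise FluorescenceDomainError("invalid record: " + "; ".join(findings))
    if record.fo_prime is None:
        raise FluorescenceDomainError(
            "fo_prime missing — estimate it with estimate_fo_prime first")

    fo, fm = record.fo, record.fm
    fs, fmp, fop = record.fs, record.fm_prime, record.fo_prime
    if fmp - fop <= 0:
        raise FluorescenceDomainError("degenerate denominator for qP (fm_prime = fo_prime)")

    fv_fm = (fm - fo) / fm
    fvp_fmp = (fmp - fop) / fmp
    phi_psii = (fmp - fs) / fmp
    phi_no = fs / fm
    phi_npq = fs / fmp - fs / fm
    qp = (fmp - fs) / (fmp - fop)
    ql = qp * fop / fs
    npq = (fm - fmp) / fmp
    etr = electron_transport_rate(phi_psii, record.q, record.alpha, record.f_psii)
    return FluorescenceIndices(
        fv_fm=fv_fm, fvp_fmp=fvp_fmp, phi_psii=phi_psii, phi_npq=phi_npq,
        phi_no=phi_no, qp=qp, ql=ql, one_minus_ql=1.0 - ql, npq=npq, etr=etr,
    )


def electron_transport_rate(phi_psii: float, q: float,
                            alpha: float = 0.84, f_psii: float = 0.5) -> float:
    """Linear electron transport rate ETR = ΦPSII · Q · α · f (µmol e⁻ m⁻² s⁻¹)."""
    if not (0 <= phi_psii <= 1):
        raise FluorescenceDomainError("phi_psii must be in [0,1]")
    if q < 0:
        raise FluorescenceDomainError("q must be ≥ 0")
    if not (0 < alpha <= 1):
        raise FluorescenceDomainError("alpha must be in (0,1]")
    if not (0 < f_psii <= 1):
        raise FluorescenceDomainError("f_psii must be in (0,1]")
    return phi_psii * q * alpha * f_psii
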