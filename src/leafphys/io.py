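"""Reader/writer for the flat gas-table CSV dialect and YAML configuration.

Portable-photosynthesis-system exports are vendor specific; the package
defines one flat CSV dialect (header row; one observation per row) and a YAML
column mapping so real exports can be adapted to it.  Mandatory columns
(after mapping): cultivar, treatment, block, plant, A, gs, E, Ci, Ca, Q,
Tleaf, Fo, Fm, Fs, Fmp.  Optional: Fop, RH.  Unmapped columns are carried
along as opaque extras and written back on round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .records import FluorescenceRecord, GasExchangeRecord, ProtocolConfig

log = logging.getLogger("leafphys.io")

#: canonical column → GasExchangeRecord / FluorescenceRecord field
MANDATORY_COLUMNS = [
    "cultivar", "treatment", "block", "plant",
    "A", "gs", "E", "Ci", "Ca", "Q", "Tleaf",
    "Fo", "Fm", "Fs", "Fmp",
]
OPTIONAL_COLUMNS = ["Fop", "RH"]
_NUMERIC = ["A", "gs", "E", "Ci", "Ca", "Q", "Tleaf", "Fo", "Fm", "Fs", "Fmp", "Fop", "RH"]


class GasTableError(ValueError):
    """Problem with a gas-table file (missing column, bad cell, empty file)."""


@dataclass
class Observation:
    """One row of a gas table: design key + paired records + extras."""

    cultivar: str
    treatment: str
    block: int
    plant: int
    gas: GasExchangeRecord
    fluor: FluorescenceRecord
    extras: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.cultivar, self.treatment, self.block, self.plant)


def read_gas_table(path, dialect: dict[str, str] | None = None,
                   unit_scales: dict[str, float] | None = None) -> list[Observation]:
    """Read a gas-table CSV into paired gas-exchange / fluorescence records.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    dialect : dict, optional
        Mapping ``canonical name -> column name in the file`` for columns
        whose header differs from the canonical dialect.
    unit_scales : dict, optional
        Per-canonical-column multiplicative factor applied after parsing
        (e.g. ``{"E": 1000}`` for a file storing E in mol m⁻² s⁻¹).
    """
    path = Path(path)
    if not path.exists():
        raise GasTableError(f"file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise GasTableError(f"empty file: {path}") from None
    if df.empty:
        raise GasTableError(f"empty file (header only): {path}")

    dialect = dialect or {}
    rename = {src: canon for canon, src in dialect.items() if src in df.columns}
    df = df.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise GasTableError(f"missing mandatory column(s): {', '.join(missing)}")

    unit_scales = unit_scales or {}
    present_numeric = [c for c in _NUMERIC if c in df.columns]
    obs: list[Observation] = []
    rejected = 0
    extras_cols = [c for c in df.columns
                   if c not in MANDATORY_COLUMNS and c not in OPTIONAL_COLUMNS]
    for idx, row in df.iterrows():
        try:
            vals = {c: float(row[c]) * unit_scales.get(c, 1.0) for c in present_numeric
                    if pd.notna(row[c])}
            for c in present_numeric:
                if c not in OPTIONAL_COLUMNS and c not in vals:
                    raise ValueError(f"non-numeric or missing cell in column {c}")
        except (TypeError, ValueError) as exc:
            raise GasTableError(f"row {idx}: {exc}") from None
        gas = GasExchangeRecord(
            a=vals["A"], gs=vals["gs"], e=vals["E"], ci=vals["Ci"], ca=vals["Ca"],
            q=vals["Q"], tleaf=vals["Tleaf"], rh=vals.get("RH", 0.5),
        )
        fluor = FluorescenceRecord(
            fo=vals["Fo"], fm=vals["Fm"], fs=vals["Fs"], fm_prime=vals["Fmp"],
            fo_prime=vals.get("Fop"), q=vals["Q"],
        )
        obs.append(Observation(
            cultivar=str(row["cultivar"]), treatment=str(row["treatment"]),
            block=int(row["block"]), plant=int(row["plant"]),
            gas=gas, fluor=fluor,
            extras={c: row[c] for c in extras_cols},
        ))
    log.info("read %s: %d rows accepted, %d rejected", path, len(obs), rejected)
    return obs


def observations_to_frame(obs: list[Observation]) -> pd.DataFrame:
    rows = []
    for o in obs:
        row = {
            "cultivar": o.cultivar, "treatment": o.treatment,
            "block": o.block, "plant": o.plant,
            "A": o.gas.a, "gs": o.gas.gs, "E": o.gas.e, "Ci": o.gas.ci,
            "Ca": o.gas.ca, "Q": o.gas.q, "Tleaf": o.gas.tleaf, "RH": o.gas.rh,
            "Fo": o.fluor.fo, "Fm": o.fluor.fm, "Fs": o.fluor.fs,
            "Fmp": o.fluor.fm_prime,
        }
        if o.fluor.fo_prime is not None:
            row["Fop"] = o.fluor.fo_prime
        row.update(o.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def write_gas_table(obs: list[Observation], path) -> None:
    """Write observations back to the CSV dialect (inverse of read_gas_table)."""
    observations_to_frame(obs).to_csv(path, index=False, float_format="%.12g")


def write_report_table(tables: dict[str, pd.DataFrame], path) -> list[Path]:
    """Write named result tables as CSV, one file per table.

    ``path`` is treated as a directory; each table goes to ``<name>.csv``
    with a stable column order (the frame's own).  Numeric values are written
    with 12 significant digits so a write/read round trip is lossless at that
    precision.
    """
    if not tables:
        raise ValueError("no tables to write")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        target = outdir / f"{name}.csv"
        df.to_csv(target, index=False, float_format="%.12g")
        written.append(target)
    return written


def load_config(path) -> dict:
    """Load a YAML configuration holding protocol, column mapping, unit scales.

    Recognised top-level keys: ``protocol`` (ProtocolConfig fields),
    ``column_map`` (canonical -> file column), ``unit_scales`` (canonical ->
    factor).  Unknown keys are preserved in the returned dict.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = dict(raw)
    proto = raw.get("protocol", {})
    cfg["protocol"] = ProtocolConfig(**proto) if isinstance(proto, dict) else proto
    cfg.setdefault("column_map", {})
    cfg.setdefault("unit_scales", {})
    return cfg
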