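"""End-to-end orchestration: indices → curve fits → RCBD statistics → report.

:func:`run_full_analysis` consumes a bundle of experiment tables (simulated
by :mod:`leafphys.synthetic` or read from the CSV dialect), derives every
per-observation index, fits the A/Ci and light-response curves per plot,
runs the ANOVA / protected-LSD / pooled-SEM layer per trait, and assembles a
deterministic :class:`AnalysisReport` mirroring the structure of a factorial
waterlogging study: cell means ± pooled SEM with LSD letters, per-cultivar
percent changes, ANOVA tables and a trait correlation matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .fluorescence import light_adapted_indices
from .fvcb import ACiFitter
from .gasx import percent_change, rubisco_velocities, stomatal_indices
from .light import LightResponseFitter
from .records import FluorescenceRecord, GasExchangeRecord
from .stats import (AnovaTable, anova_factorial_rcbd, fisher_protected_lsd,
                    pearson_matrix, pooled_sem)

KEY = ["cultivar", "treatment", "block", "plant"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending group key."""


@dataclass
class AnalysisReport:
    summary: pd.DataFrame                 # per trait × cell: mean, sem, letter, % change
    anova: dict                           # trait -> AnovaTable
    aci_params: pd.DataFrame
    light_params: pd.DataFrame
    correlation: object
    metadata: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        anova_rows = []
        for trait, tab in self.anova.items():
            t = tab.table.copy()
            t.insert(0, "trait", trait)
            anova_rows.append(t)
        out = {
            "summary": self.summary,
            "anova": pd.concat(anova_rows, ignore_index=True),
            "aci_params": self.aci_params,
            "light_params": self.light_params,
        }
        if self.correlation is not None:
            out["correlation_r"] = self.correlation.r.reset_index(names="trait")
            out["correlation_p"] = self.correlation.p.reset_index(names="trait")
        return out


def derive_trait_table(bundle, rd_day: float = 1.5) -> pd.DataFrame:
    """Long-format TraitTable from all bundle components.

    Produces morphology traits verbatim, stomatal indices (WUE, Ci/Ca, Ls)
    and A/gs/E/Ci from the gas table, the full quenching calculus plus ETR
    from the fluorescence records, Vc/Vo from the A–ETR partitioning, and
    per-plot Vcmax/Jmax and light-curve cardinal points from the fits.
    """
    frames = []
    if bundle.morphology is not None and len(bundle.morphology):
        frames.append(bundle.morphology[["cultivar", "treatment", "block",
                                         "plant", "trait", "value"]])

    gas = bundle.gas
    etr_by_key = {}
    if bundle.fluorescence is not None and len(bundle.fluorescence):
        rows = []
        for _, r in bundle.fluorescence.iterrows():
            try:
                rec = FluorescenceRecord(fo=r["Fo"], fm=r["Fm"], fs=r["Fs"],
                                         fm_prime=r["Fmp"], fo_prime=r.get("Fop"),
                                         q=r["Q"])
                idx = light_adapted_indices(rec)
            except Exception as exc:
                raise PipelineError(
                    f"stage fluorescence ({tuple(r[k] for k in KEY)}): {exc}") from exc
            key = tuple(r[k] for k in KEY)
            etr_by_key[key] = idx.etr
            for trait, value in [
                    ("FvFm", idx.fv_fm), ("FvpFmp", idx.fvp_fmp),
                    ("PhiPSII", idx.phi_psii), ("PhiNPQ", idx.phi_npq),
                    ("PhiNO", idx.phi_no), ("qP", idx.qp), ("qL", idx.ql),
                    ("one_minus_qL", idx.one_minus_ql), ("NPQ", idx.npq),
                    ("ETR", idx.etr), ("Fo", r["Fo"]), ("Fm", r["Fm"]),
                    ("Fs", r["Fs"])]:
                rows.append(dict(zip(KEY, key), trait=trait, value=value))
        frames.append(pd.DataFrame(rows))

    if gas is not None and len(gas):
        rows = []
        for _, r in gas.iterrows():
            key = tuple(r[k] for k in KEY)
            rec = GasExchangeRecord(a=r["A"], gs=r["gs"], e=r["E"], ci=r["Ci"],
                                    ca=r["Ca"], q=r["Q"], tleaf=r["Tleaf"],
                                    rh=r.get("RH", 0.5))
            try:
                wue, ci_ca, ls = stomatal_indices(rec)
            except Exception as exc:
                raise PipelineError(f"stage indices ({key}): {exc}") from exc
            values = [("A", rec.a), ("gs", rec.gs), ("E", rec.e), ("Ci", rec.ci),
                      ("WUE", wue), ("Ci_Ca", ci_ca), ("Ls", ls)]
            if key in etr_by_key:
                vc, vo, ok = rubisco_velocities(rec.a, etr_by_key[key], rd_day)
                if ok:
                    values += [("Vc", vc), ("Vo", vo)]
            for trait, value in values:
                rows.append(dict(zip(KEY, key), trait=trait, value=value))
        frames.append(pd.DataFrame(rows))

    if not frames:
        raise PipelineError("stage ingest: empty bundle")
    return pd.concat(frames, ignore_index=True)


def fit_aci_curves(aci_curves: pd.DataFrame, **options) -> pd.DataFrame:
    """Per-plot FvCB fits; returns one row per cultivar×treatment×block."""
    rows = []
    for key, grp in aci_curves.groupby(["cultivar", "treatment", "block"],
                                       observed=True):
        try:
            est = ACiFitter(**options).fit(grp["ci"].to_numpy(), grp["a"].to_numpy())
        except Exception as exc:
            raise PipelineError(f"stage fit-aci ({key}): {exc}") from exc
        rows.append({"cultivar": key[0], "treatment": key[1], "block": key[2],
                     "Vcmax": est.vcmax_, "Jmax": est.j_, "TPU": est.tpu_,
                     "Rd": est.rd_, "sse": est.sse_, "admissible": est.admissible_})
    return pd.DataFrame(rows)


def fit_light_curves(light_curves: pd.DataFrame, model: str = "auto") -> pd.DataFrame:
    """Per-plot light-response fits with SSE model selection."""
    rows = []
    for key, grp in light_curves.groupby(["cultivar", "treatment", "block"],
                                         observed=True):
        try:
            est = LightResponseFitter(model=model).fit(
                grp["i"].to_numpy(), grp["a"].to_numpy())
        except Exception as exc:
            raise PipelineError(f"stage fit-light ({key}): {exc}") from exc
        rows.append({"cultivar": key[0], "treatment": key[1], "block": key[2],
                     "model": est.model_, "Amax": est.amax_1500_, "Pmax": est.pmax_,
                     "Ic": est.ic_, "Ik": est.ik_, "PhiI": est.phi_i_,
                     "Rd": est.rd_, "sse": est.sse_})
    return pd.DataFrame(rows)


def _fits_to_traits(fits: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    rows = []
    for _, r in fits.iterrows():
        for t in traits:
            if t in r and pd.notna(r[t]):
                rows.append({"cultivar": r["cultivar"], "treatment": r["treatment"],
                             "block": r["block"], "plant": 1, "trait": t,
                             "value": float(r[t])})
    return pd.DataFrame(rows)


def run_full_analysis(bundle, traits: list[str] | None = None,
                      alpha: float = 0.05, rd_day: float = 1.5,
                      correlate: list[str] | None = None) -> AnalysisReport:
    """Run the complete analysis over one experiment bundle.

    Deterministic given the bundle: repeated calls give identical reports.
    """
    table = derive_trait_table(bundle, rd_day=rd_day)

    if bundle.aci_curves is not None and len(bundle.aci_curves):
        aci = fit_aci_curves(bundle.aci_curves)
        table = pd.concat([table, _fits_to_traits(aci, ["Vcmax", "Jmax"])],
                          ignore_index=True)
    else:
        aci = pd.DataFrame()
    if bundle.light_curves is not None and len(bundle.light_curves):
        light = fit_light_curves(bundle.light_curves)
        table = pd.concat([table, _fits_to_traits(light, ["Amax", "Ic", "Ik", "PhiI"])],
                          ignore_index=True)
    else:
        light = pd.DataFrame()

    all_traits = sorted(table["trait"].unique())
    traits = traits or all_traits
    n_blocks = table["block"].nunique()

    summary_rows = []
    anovas: dict[str, AnovaTable] = {}
    cultivars = sorted(table["cultivar"].unique())
    treatments = list(dict.fromkeys(
        bundle.gas["treatment"] if bundle.gas is not None and len(bundle.gas)
        else table["treatment"]))
    control, treated = treatments[0], treatments[-1]
    for trait in traits:
        try:
            tab = anova_factorial_rcbd(table, trait, alpha=alpha)
            sem = pooled_sem(tab, n_blocks)
            plot = (table[table["trait"] == trait]
                    .groupby(["cultivar", "treatment", "block"], observed=True)["value"]
                    .mean().reset_index())
            cell_means = plot.groupby(["cultivar", "treatment"], observed=True)["value"] \
                             .mean().to_dict()
            lsd = fisher_protected_lsd(tab, cell_means, n_blocks, alpha=alpha)
        except Exception as exc:
            raise PipelineError(f"stage stats ({trait}): {exc}") from exc
        anovas[trait] = tab
        for cv in cultivars:
            c, w = cell_means[(cv, control)], cell_means[(cv, treated)]
            pct = percent_change(c, w) if c != 0 else np.nan
            for tr, mean in ((control, c), (treated, w)):
                summary_rows.append({
                    "trait": trait, "cultivar": cv, "treatment": tr,
                    "mean": mean, "pooled_sem": sem,
                    "letters": lsd.groups[(cv, tr)],
                    "percent_change": pct, "lsd": lsd.lsd_value,
                })
    summary = pd.DataFrame(summary_rows)

    corr_traits = correlate or [t for t in
                                ("FM", "DM", "A", "gs", "E", "WUE", "Ci", "FvFm",
                                 "qP", "ETR", "PhiPSII", "NPQ", "PhiNO", "PhiNPQ",
                                 "one_minus_qL", "Vcmax", "Jmax")
                                if t in all_traits]
    correlation = pearson_matrix(table, corr_traits, alpha=alpha) \
        if len(corr_traits) >= 2 else None

    config_hash = hashlib.sha256(
        repr(getattr(bundle, "config", None)).encode()).hexdigest()[:12]
    return AnalysisReport(
        summary=summary, anova=anovas, aci_params=aci, light_params=light,
        correlation=correlation,
        metadata={"config_hash": config_hash, "seed": getattr(bundle, "seed", None),
                  "version": __version__, "n_blocks": int(n_blocks)},
    )


def write_report(report: AnalysisReport, outdir) -> None:
    """Serialize a report to a CSV set plus one human-readable summary file."""
    from pathlib import Path

    from .io import write_report_table

    outdir = Path(outdir)
    write_report_table(report.tables(), outdir)
    lines = ["leafphys analysis report",
             f"version {report.metadata.get('version')}  "
             f"config {report.metadata.get('config_hash')}  "
             f"seed {report.metadata.get('seed')}", ""]
    for trait, grp in report.summary.groupby("trait"):
        lines.append(f"{trait}:")
        for _, r in grp.iterrows():
            lines.append(
                f"  {r['cultivar']:<12} {r['treatment']:<12} "
                f"{r['mean']:10.4g} ± {r['pooled_sem']:.3g} {r['letters']:<3} "
                f"(Δ {r['percent_change']:+.1f}%)")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")


def plot_report(report: AnalysisReport, outdir, traits: list[str] | None = None):
    """Optional simple figures: per-trait bar charts of cell means ± pooled SEM.

    Returns the list of files written; styling is intentionally minimal.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for trait, grp in report.summary.groupby("trait"):
        if traits and trait not in traits:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        labels = [f"{r.cultivar}\n{r.treatment}" for r in grp.itertuples()]
        ax.bar(range(len(grp)), grp["mean"], yerr=grp["pooled_sem"], capsize=3)
        for x, r in zip(range(len(grp)), grp.itertuples()):
            ax.annotate(r.letters, (x, r.mean), textcoords="offset points",
                        xytext=(0, 6), ha="center")
        ax.set_xticks(range(len(grp)), labels, fontsize=7)
        ax.set_ylabel(trait)
        fig.tight_layout()
        target = outdir / f"{trait}.png"
        fig.savefig(target, dpi=100)
        plt.close(fig)
        written.append(target)
    return written
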