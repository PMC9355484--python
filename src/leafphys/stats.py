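"""Factorial RCBD statistics: two-way ANOVA, Fisher's protected LSD,
normality diagnostics, Pearson correlation matrix and the pooled SEM.

The experimental layout is a randomized complete block design with a 2 × 2
factorial treatment structure (cultivar × waterlogging treatment) in B
blocks.  Plants measured within one block-cell are pseudo-replicates and are
averaged to plot means before the ANOVA, so the error term has
(a·b − 1)(B − 1) degrees of freedom (9 for 2 × 2 × 4).  For a balanced
Gaussian response this fixed-effects decomposition yields the same F tests as
the generalized-linear-mixed-model formulation commonly run in SAS.

The pooled standard error of a cell mean is ``sqrt(MSE / B)`` from the ANOVA
error mean square, and Fisher's protected LSD at level α is
``t(1 − α/2, df_error) · sqrt(2·MSE / n)`` gated on the omnibus F test over
the treatment structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


class DesignError(ValueError):
    pass


@dataclass
class AnovaTable:
    """Per-source ANOVA decomposition (cultivar, treatment, interaction, block, error)."""

    table: pd.DataFrame  # columns: source, df, ss, ms, f, p
    n_obs: int
    alpha: float = 0.05

    def row(self, source: str) -> pd.Series:
        m = self.table[self.table["source"] == source]
        if m.empty:
            raise KeyError(source)
        return m.iloc[0]

    @property
    def mse(self) -> float:
        return float(self.row("error")["ms"])

    @property
    def df_error(self) -> int:
        return int(self.row("error")["df"])

    def significant(self, source: str) -> bool:
        return bool(self.row(source)["p"] <= self.alpha)


@dataclass
class LsdResult:
    lsd_value: float
    groups: dict          # group key -> letter string
    means: dict
    protected: bool
    gate_p: float


@dataclass
class CorrelationMatrix:
    traits: list
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame = field(default=None)


def aggregate_plot_means(table: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """Average plants within each cultivar×treatment×block cell (pseudo-replication guard)."""
    df = table
    if trait is not None:
        df = df[df["trait"] == trait]
    return (df.groupby(["cultivar", "treatment", "block"], as_index=False,
                       observed=True)["value"].mean())


def _check_balance(df: pd.DataFrame) -> None:
    counts = df.groupby(["cultivar", "treatment", "block"], observed=True).size()
    full = df["cultivar"].nunique() * df["treatment"].nunique() * df["block"].nunique()
    if len(counts) != full:
        raise DesignError("missing cultivar×treatment×block cells")
    if counts.nunique() != 1:
        raise DesignError(
            "unbalanced design: aggregate plants to plot means first "
            "(aggregate_plot_means)")


def anova_factorial_rcbd(table: pd.DataFrame, trait: str, alpha: float = 0.05,
                         aggregate: bool = True) -> AnovaTable:
    """Two-way factorial RCBD ANOVA for one trait of a long-format table.

    ``table`` needs columns cultivar, treatment, block, trait, value (the
    trait column may be omitted when the frame holds a single trait).
    Plants are averaged to plot means first unless ``aggregate=False``.
    """
    df = table if "trait" not in table.columns else table[table["trait"] == trait]
    if df.empty:
        raise DesignError(f"no observations for trait {trait!r}")
    if df["block"].nunique() < 2:
        raise DesignError("need at least 2 blocks")
    work = aggregate_plot_means(df) if aggregate else df.copy()
    _check_balance(work)
    if not np.all(np.isfinite(work["value"])):
        raise DesignError("non-finite trait values")

    import warnings as _warnings
    with _warnings.catch_warnings():
        # a zero-variance response makes the contrast covariance rank
        # deficient; handled explicitly below
        _warnings.simplefilter("ignore")
        model = smf.ols(
            "value ~ C(cultivar) + C(treatment) + C(cultivar):C(treatment) + C(block)",
            data=work).fit()
        raw = anova_lm(model, typ=2)
    total_ss = float(raw["sum_sq"].sum())
    rename = {
        "C(cultivar)": "cultivar",
        "C(treatment)": "treatment",
        "C(cultivar):C(treatment)": "cultivar:treatment",
        "C(block)": "block",
        "Residual": "error",
    }
    rows = []
    for src, row in raw.iterrows():
        name = rename.get(src, src)
        df_ = float(row["df"])
        ss = float(row["sum_sq"])
        ms = ss / df_ if df_ > 0 else np.nan
        f = float(row["F"]) if np.isfinite(row.get("F", np.nan)) else np.nan
        p = float(row["PR(>F)"]) if np.isfinite(row.get("PR(>F)", np.nan)) else np.nan
        if name != "error" and ss <= 1e-10 * max(total_ss, 1e-8):
            f, p = 0.0, 1.0  # no variation attributable to this source
        rows.append({"source": name, "df": df_, "ss": ss, "ms": ms, "f": f, "p": p})
    order = ["cultivar", "treatment", "cultivar:treatment", "block", "error"]
    out = (pd.DataFrame(rows).set_index("source").loc[order].reset_index())
    return AnovaTable(table=out, n_obs=len(work), alpha=alpha)


def _assign_letters(means_sorted: list[tuple], lsd: float) -> dict:
    """Descending-mean sweep: maximal runs of means within one LSD share a letter."""
    keys = [k for k, _ in means_sorted]
    vals = np.array([v for _, v in means_sorted])
    k = len(vals)
    kept = []
    last_j = -1
    for i in range(k):
        j = i
        while j + 1 < k and vals[i] - vals[j + 1] <= lsd:
            j += 1
        if j > last_j or not kept:  # skip intervals contained in the previous one
            kept.append((i, j))
            last_j = j
    letters = {key: "" for key in keys}
    for letter_idx, (i, j) in enumerate(kept):
        letter = chr(ord("a") + letter_idx)
        for t in range(i, j + 1):
            letters[keys[t]] += letter
    return letters


def fisher_protected_lsd(anova: AnovaTable, means: dict, n_per_group: int,
                         alpha: float = 0.05) -> LsdResult:
    """Fisher's protected LSD mean separation over the cultivar×treatment cells.

    ``means`` maps group key → mean; all groups must share ``n_per_group``
    replications.  The omnibus gate is the joint F test of the treatment
    structure (cultivar + treatment + interaction against the error mean
    square); when it is non-significant every group shares one letter.
    """
    if n_per_group <= 1:
        raise DesignError("n_per_group must be > 1")
    mse = anova.mse
    dfe = anova.df_error
    lsd = scipy.stats.t.ppf(1 - alpha / 2, dfe) * np.sqrt(2.0 * mse / n_per_group)

    ss_trt = sum(anova.row(s)["ss"] for s in ("cultivar", "treatment", "cultivar:treatment"))
    df_trt = sum(anova.row(s)["df"] for s in ("cultivar", "treatment", "cultivar:treatment"))
    if mse > 0:
        f_gate = (ss_trt / df_trt) / mse
        gate_p = float(scipy.stats.f.sf(f_gate, df_trt, dfe))
    else:
        gate_p = 0.0 if ss_trt > 0 else 1.0

    ordered = sorted(means.items(), key=lambda kv: (-kv[1], str(kv[0])))
    if gate_p > alpha:
        letters = {k: "a" for k, _ in ordered}
    else:
        letters = _assign_letters(ordered, lsd)
    return LsdResult(lsd_value=float(lsd), groups=letters, means=dict(means),
                     protected=True, gate_p=gate_p)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p) via Royston's approximation."""
    x = np.asarray(values, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise DesignError("Shapiro–Wilk requires 3 ≤ n ≤ 5000")
    if np.ptp(x) == 0:
        raise DesignError("constant sample")
    w, p = scipy.stats.shapiro(x)
    return float(w), float(p)


def pearson_matrix(table: pd.DataFrame, traits: list[str],
                   unit_cols: tuple = ("cultivar", "treatment", "block"),
                   alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Pearson correlations between traits of a long-format table.

    Observational units are the distinct ``unit_cols`` combinations (plot
    means by default); p-values use the t transform with n−2 df and stars
    mark significance at ``alpha``.
    """
    df = table[table["trait"].isin(traits)]
    wide = (df.groupby([*unit_cols, "trait"], observed=True)["value"].mean()
              .unstack("trait"))
    missing = [t for t in traits if t not in wide.columns]
    if missing:
        raise DesignError(f"traits absent from table: {missing}")
    for t in traits:
        col = wide[t].dropna()
        if col.nunique() <= 1:
            raise DesignError(f"zero-variance trait: {t}")
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), 0)
    for a_ in range(k):
        for b_ in range(k):
            pair = wide[[traits[a_], traits[b_]]].dropna()
            n[a_, b_] = len(pair)
            if a_ == b_:
                continue
            if len(pair) < 3:
                raise DesignError("need ≥ 3 complete observations per pair")
            rr, pp = scipy.stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[a_, b_], p[a_, b_] = rr, pp
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    stars = pd.DataFrame(
        np.where((p <= alpha) & ~np.eye(k, dtype=bool), "*", ""),
        index=traits, columns=traits)
    return CorrelationMatrix(traits=list(traits), r=rdf, p=pdf,
                             n=pd.DataFrame(n, index=traits, columns=traits),
                             stars=stars)


def pooled_sem(anova: AnovaTable, n: int) -> float:
    """Pooled standard error of a cell mean, sqrt(MSE/n), from the ANOVA error term."""
    if n < 2:
        raise DesignError("n must be ≥ 2")
    return float(np.sqrt(anova.mse / n))
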