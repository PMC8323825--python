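"""Study-level statistics: buckling-rate tables, diameter-linearity fits,
three-factor ANOVA, rupture/dimpling correlations, and report generation.

A study table holds one row per insertion trial with the factors
(material, tip geometry, diameter, membrane condition), the outcome, and —
for penetrated trials — the membrane rupture force (mN) and dimpling depth
at rupture (mm).  The analyses mirror the study's layout: buckling rates as
percentages of all trials per condition, ordinary least squares of the
per-condition mean response on wire diameter (with a diameter² alternative
for model comparison), main-effects ANOVA with Type II sums of squares on
the unbalanced design, and Pearson correlations within tip/diameter strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .profile_pipeline import Membrane

__all__ = [
    "FitResult",
    "AnovaResult",
    "CorrelationResult",
    "buckling_rate_table",
    "trial_counts_from_study",
    "diameter_linearity_fit",
    "three_factor_anova",
    "rupture_dimpling_correlation",
    "dimpling_force_ratio",
    "build_report",
    "read_study",
    "write_study",
]

FACTORS = ("material", "tip", "diameter_um")
RESPONSES = ("rupture_force_mn", "dimpling_mm", "ratio_mm_per_mn")


@dataclass(frozen=True)
class FitResult:
    """OLS of per-condition mean response on diameter (and the d² alternative)."""

    slope: float
    intercept: float
    r_squared: float
    quadratic_r_squared: float
    group_means: pd.DataFrame
    response: str
    membrane: str


@dataclass(frozen=True)
class AnovaResult:
    """Per-factor F and p from a main-effects Type II ANOVA."""

    response: str
    membrane: str
    table: pd.DataFrame  # index: factor; columns: F, p, df

    def f(self, factor: str) -> float:
        return float(self.table.loc[factor, "F"])

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r between rupture force and dimpling in one stratum."""

    membrane: str
    stratum: str
    n: int
    r: float
    p: float
    strength: str


def buckling_rate_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Buckling rates (%) from penetrated/total counts per condition.

    ``counts`` needs columns ``penetrated`` and ``total`` (plus any label
    columns); a pooled ``sum`` row is appended per membrane when a
    ``membrane`` column is present, else one overall row.  The rate counts
    buckled cases as a percentage of all trials.
    """
    counts = counts.copy()
    if (counts["total"] <= 0).any():
        raise ValueError("total trials must be positive in every row")
    if (counts["penetrated"] > counts["total"]).any():
        raise ValueError("penetrated cannot exceed total")
    counts["buckling_rate_pct"] = (
        (counts["total"] - counts["penetrated"]) / counts["total"] * 100.0
    )

    group_cols = ["membrane"] if "membrane" in counts.columns else []
    pooled_rows = []
    grouped = counts.groupby(group_cols) if group_cols else [((), counts)]
    for key, sub in grouped:
        pen, tot = int(sub["penetrated"].sum()), int(sub["total"].sum())
        row = {c: "all" for c in counts.columns if c not in ("penetrated", "total", "buckling_rate_pct")}
        if group_cols:
            row["membrane"] = key[0] if isinstance(key, tuple) else key
        row.update(
            penetrated=pen, total=tot, buckling_rate_pct=(tot - pen) / tot * 100.0, pooled=True
        )
        pooled_rows.append(row)
    counts["pooled"] = False
    return pd.concat([counts, pd.DataFrame(pooled_rows)], ignore_index=True)


def trial_counts_from_study(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a trial table to penetrated/total counts per condition."""
    grouped = table.groupby(["membrane", "material", "tip", "diameter_um"], sort=True)
    out = grouped.agg(
        penetrated=("outcome", lambda s: int((s == "penetrated").sum())),
        total=("outcome", "size"),
    ).reset_index()
    return out


def _penetrated(table: pd.DataFrame, membrane: str | Membrane | None) -> pd.DataFrame:
    sub = table[table["outcome"] == "penetrated"]
    if membrane is not None:
        membrane = Membrane(membrane).value
        sub = sub[sub["membrane"] == membrane]
    return sub


def diameter_linearity_fit(
    table: pd.DataFrame,
    response: str = "rupture_force_mn",
    membrane: str | Membrane | None = None,
    on_means: bool = True,
    material: str | None = None,
    tip: str | None = None,
) -> FitResult:
    """OLS of the response on wire diameter, fit to per-condition means.

    Means are taken per (material, tip, diameter) cell, as the study plots
    them; set ``on_means=False`` to fit all trials directly.  ``material``
    and ``tip`` restrict the fit to one wire family (one plotted line).
    Also fits the response on diameter² so callers can compare the two
    models' R².
    """
    sub = _penetrated(table, membrane)
    if material is not None:
        sub = sub[sub["material"] == material]
    if tip is not None:
        sub = sub[sub["tip"] == tip]
    if sub["diameter_um"].nunique() < 2:
        raise ValueError("need at least two diameter levels to fit a slope")

    grouped = sub.groupby(["material", "tip", "diameter_um"])[response]
    means = grouped.agg(mean="mean", sem="sem", n="size").reset_index()
    if on_means:
        x = means["diameter_um"].to_numpy(float)
        y = means["mean"].to_numpy(float)
    else:
        x = sub["diameter_um"].to_numpy(float)
        y = sub[response].to_numpy(float)

    lin = stats.linregress(x, y)
    quad = stats.linregress(x**2, y)
    return FitResult(
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        r_squared=float(lin.rvalue**2),
        quadratic_r_squared=float(quad.rvalue**2),
        group_means=means,
        response=response,
        membrane=Membrane(membrane).value if membrane is not None else "all",
    )


def three_factor_anova(
    table: pd.DataFrame,
    response: str = "rupture_force_mn",
    membrane: str | Membrane | None = None,
) -> AnovaResult:
    """Main-effects ANOVA of a response on material, tip and diameter.

    Penetrated trials only; diameter enters as a categorical factor.  Type
    II sums of squares handle the unbalanced cells of the factorial layout.
    Degenerate responses (zero factor and residual variance) report F = 0.
    """
    sub = _penetrated(table, membrane).dropna(subset=[response])
    for factor in FACTORS:
        if sub[factor].nunique() < 2:
            raise ValueError(f"factor '{factor}' has fewer than two observed levels")

    data = sub.rename(columns={response: "_y"})
    y = data["_y"].to_numpy(float)
    rename = {"C(material)": "material", "C(tip)": "tip", "C(diameter_um)": "diameter_um"}
    # a degenerate (constant) response carries no evidence for any factor
    if np.var(y) <= 1e-24 * (1.0 + np.mean(y) ** 2):
        rows = {factor: {"F": 0.0, "p": 1.0, "df": np.nan} for factor in rename.values()}
        return AnovaResult(
            response=response,
            membrane=Membrane(membrane).value if membrane is not None else "all",
            table=pd.DataFrame(rows).T,
        )

    model = smf.ols("_y ~ C(material) + C(tip) + C(diameter_um)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    rows = {}
    for raw, factor in rename.items():
        ss = float(anova.loc[raw, "sum_sq"])
        f_val = float(anova.loc[raw, "F"])
        p_val = float(anova.loc[raw, "PR(>F)"])
        if not np.isfinite(f_val) and ss <= 1e-12:
            f_val, p_val = 0.0, 1.0
        rows[factor] = {"F": f_val, "p": p_val, "df": float(anova.loc[raw, "df"])}
    return AnovaResult(
        response=response,
        membrane=Membrane(membrane).value if membrane is not None else "all",
        table=pd.DataFrame(rows).T,
    )


_DEFAULT_STRATA = ("all", "sharp", "blunt", 12, 25, 50, 100)


def rupture_dimpling_correlation(
    table: pd.DataFrame,
    membrane: str | Membrane | None = None,
    strata: tuple = _DEFAULT_STRATA,
) -> list[CorrelationResult]:
    """Pearson r between rupture force and dimpling depth, per stratum.

    Strata are 'all', a tip geometry, or a diameter level; strata with no
    trials are skipped, strata with fewer than 3 report an undefined p, and
    constant vectors report an undefined r.  Classification: strong when
    p < 0.05 and |r| > 0.7; moderate when 0.3 < |r| < 0.7.
    """
    sub = _penetrated(table, membrane).dropna(subset=["rupture_force_mn", "dimpling_mm"])
    out: list[CorrelationResult] = []
    for stratum in strata:
        if stratum == "all":
            sel = sub
        elif isinstance(stratum, str):
            sel = sub[sub["tip"] == stratum]
        else:
            sel = sub[sub["diameter_um"] == stratum]
        n = len(sel)
        if n == 0:
            continue
        x = sel["rupture_force_mn"].to_numpy(float)
        y = sel["dimpling_mm"].to_numpy(float)
        if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            r = np.nan if (n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0) else float(np.corrcoef(x, y)[0, 1])
            p = np.nan
        else:
            r, p = (float(v) for v in stats.pearsonr(x, y))
        if np.isfinite(r) and np.isfinite(p) and p < 0.05 and abs(r) > 0.7:
            strength = "strong"
        elif np.isfinite(r) and 0.3 < abs(r) < 0.7:
            strength = "moderate"
        else:
            strength = "weak"
        out.append(
            CorrelationResult(
                membrane=Membrane(membrane).value if membrane is not None else "all",
                stratum=str(stratum),
                n=n,
                r=r,
                p=p,
                strength=strength,
            )
        )
    return out


def dimpling_force_ratio(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial dimpling-to-rupture-force ratio (mm/mN) and its summary.

    Returns the penetrated trials with a ``ratio_mm_per_mn`` column
    (zero-force trials excluded, with a diagnostic count) and a
    per-condition summary (mean, sem, n).
    """
    sub = table[table["outcome"] == "penetrated"].copy()
    excluded = int((sub["rupture_force_mn"] == 0).sum())
    sub = sub[sub["rupture_force_mn"] > 0]
    sub["ratio_mm_per_mn"] = sub["dimpling_mm"] / sub["rupture_force_mn"]
    summary = (
        sub.groupby(["membrane", "material", "tip", "diameter_um"])["ratio_mm_per_mn"]
        .agg(mean="mean", sem="sem", n="size")
        .reset_index()
    )
    summary.attrs["excluded_zero_force"] = excluded
    return sub, summary


def build_report(table: pd.DataFrame, outdir=None) -> dict:
    """Compute the full study report and optionally write it to ``outdir``.

    Returns a dict with the buckling-rate table, linearity fits, ANOVA
    tables and correlation tables for each membrane condition present, plus
    the dimpling-to-force ratio summary.  With ``outdir`` set, writes CSVs
    and mean±SE diameter-trend plots.
    """
    report: dict = {"n_trials": len(table)}
    if len(table) == 0:
        report.update(buckling=pd.DataFrame(), fits=[], anovas=[], correlations=[])
        return report

    report["buckling"] = buckling_rate_table(trial_counts_from_study(table))
    membranes = [m for m in (Membrane.PIA_ONLY.value, Membrane.DURA_PIA.value)
                 if (table["membrane"] == m).any()]

    with_ratio, ratio_summary = dimpling_force_ratio(table)
    report["ratio_summary"] = ratio_summary

    fits, anovas, correlations = [], [], []
    for mem in membranes:
        for response in ("rupture_force_mn", "dimpling_mm"):
            try:
                fits.append(diameter_linearity_fit(table, response, mem))
            except ValueError:
                pass
        for response in RESPONSES:
            source = with_ratio if response == "ratio_mm_per_mn" else table
            try:
                anovas.append(three_factor_anova(source, response, mem))
            except (ValueError, KeyError):
                pass
        strata = _DEFAULT_STRATA if mem == Membrane.PIA_ONLY.value else tuple(
            s for s in _DEFAULT_STRATA if s != 12
        )
        correlations.extend(rupture_dimpling_correlation(table, mem, strata))
    report.update(fits=fits, anovas=anovas, correlations=correlations)

    if outdir is not None:
        _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir) -> None:
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(report.get("buckling"), pd.DataFrame) and len(report["buckling"]):
        report["buckling"].to_csv(outdir / "buckling_rates.csv", index=False)
    if report.get("anovas"):
        rows = []
        for res in report["anovas"]:
            for factor, row in res.table.iterrows():
                rows.append({"membrane": res.membrane, "response": res.response,
                             "factor": factor, **row.to_dict()})
        pd.DataFrame(rows).to_csv(outdir / "anova.csv", index=False)
    if report.get("correlations"):
        pd.DataFrame([vars(c) for c in report["correlations"]]).to_csv(
            outdir / "correlations.csv", index=False
        )
    if isinstance(report.get("ratio_summary"), pd.DataFrame):
        report["ratio_summary"].to_csv(outdir / "dimpling_force_ratio.csv", index=False)

    for fit in report.get("fits", []):
        fig, ax = plt.subplots(figsize=(5, 4))
        for (mat, tip), sub in fit.group_means.groupby(["material", "tip"]):
            ax.errorbar(sub["diameter_um"], sub["mean"], yerr=sub["sem"],
                        marker="o", capsize=3, label=f"{mat} {tip}")
        xs = np.linspace(fit.group_means["diameter_um"].min(),
                         fit.group_means["diameter_um"].max(), 50)
        ax.plot(xs, fit.intercept + fit.slope * xs, "k--",
                label=f"fit R²={fit.r_squared:.3f}")
        ax.set_xlabel("wire diameter (µm)")
        ax.set_ylabel(fit.response)
        ax.set_title(f"{fit.membrane}: {fit.response} vs diameter")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / f"trend_{fit.membrane}_{fit.response}.png", dpi=110)
        plt.close(fig)
        fit.group_means.to_csv(
            outdir / f"means_{fit.membrane}_{fit.response}.csv", index=False
        )


def write_study(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_study(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"material", "tip", "diameter_um", "membrane", "outcome"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    return table
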