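"""Five-comparison factorial analysis of the 2x2 genotype x drug design.

Per event this computes the four context-restricted delta-PSI comparisons
(drug vs vehicle within each genotype, mutant vs WT within each treatment)
plus the cumulative comparison (mutant+drug vs WT+vehicle), the exact
path-additivity decomposition of the cumulative effect, concordance
regression of drug effects across genotypes, a beta-binomial GLM
likelihood-ratio test for drug/mutation interaction (synergy or antagonism)
on the logit scale, event classification, and trajectory tables relative to
the WT+vehicle baseline.

Scale note: interaction is defined on the logit-PSI scale (GLM with a
product term), while the "cumulative" effect is a plain PSI difference.
Large cumulative effects are therefore fully compatible with a null
interaction test — that is the design's central distinction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm

from .diff_splicing import (
    Orientation,
    bartlett_scale,
    bh_adjust,
    betabinomial_lrt,
    compare_conditions,
    mom_rho_within,
)
from .events import CONDITIONS, JunctionCountTable, condition_mean_psi

__all__ = [
    "FactorialDesign",
    "ConcordanceResult",
    "COMPARISONS",
    "run_five_comparisons",
    "cumulative_delta",
    "concordance_regression",
    "interaction_lrt",
    "classify_events",
    "trajectory_table",
]

log = logging.getLogger(__name__)

#: The five comparisons as (name, A, B, context).  Orientation of the raw
#: delta is A-minus-B throughout.
COMPARISONS = (
    ("drug_vs_veh_WT", "WT_Drug", "WT_Veh", "WT"),
    ("drug_vs_veh_MT", "MT_Drug", "MT_Veh", "MT"),
    ("mut_vs_wt_Veh", "MT_Veh", "WT_Veh", "Veh"),
    ("mut_vs_wt_Drug", "MT_Drug", "WT_Drug", "Drug"),
    ("cumulative", "MT_Drug", "WT_Veh", ""),
)


@dataclass(frozen=True)
class FactorialDesign:
    """Sample -> condition assignment for the four design cells."""

    sample_conditions: dict = field(default_factory=dict)
    min_samples_per_cell: int = 2

    def __post_init__(self):
        counts = {c: 0 for c in CONDITIONS}
        for s, c in self.sample_conditions.items():
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r} for sample {s}")
            counts[c] += 1
        short = [c for c, k in counts.items() if k < self.min_samples_per_cell]
        if short:
            raise ValueError(
                f"cells with < {self.min_samples_per_cell} samples: {short}"
            )

    @classmethod
    def from_table(cls, table: JunctionCountTable) -> "FactorialDesign":
        return cls(sample_conditions=dict(table.sample_conditions))

    def samples_for(self, condition: str) -> list:
        return [s for s, c in self.sample_conditions.items() if c == condition]


@dataclass
class ConcordanceResult:
    slope: float
    intercept: float
    r_squared: float
    f_test_p: float
    n_events: int
    criteria: str = ""


def run_five_comparisons(
    table: JunctionCountTable,
    design: FactorialDesign | None = None,
    skipping_positive: bool = False,
) -> dict:
    """Run the beta-binomial test for all five comparisons.

    Returns ``{name: results DataFrame}``; each comparison is BH-adjusted
    independently within itself.  The orientation of every delta is
    A-minus-B with A the first-named condition, optionally sign-flipped so
    positive means more skipping.
    """
    if design is None:
        design = FactorialDesign.from_table(table)
    for cond in CONDITIONS:
        if not design.samples_for(cond):
            raise ValueError(f"design is missing the {cond} cell")
    out = {}
    for name, a, b, ctx in COMPARISONS:
        orient = Orientation(a=a, b=b, context=ctx, skipping_positive=skipping_positive)
        out[name] = compare_conditions(table, a, b, orientation=orient)
    return out


def condition_psi_means(table: JunctionCountTable) -> pd.DataFrame:
    """Per-event mean PSI in each of the four conditions (events x 4)."""
    return pd.DataFrame(
        {cond: condition_mean_psi(table, cond) for cond in CONDITIONS}
    )


def cumulative_delta(psi_means, skipping_positive: bool = False):
    """Cumulative effect PSI(MT,Drug) - PSI(WT,Veh).

    ``psi_means`` is a mapping (or frame with condition columns) holding the
    four condition means.  Missing means propagate to NaN.  With
    ``skipping_positive`` the sign is flipped so positive = more skipping.
    """
    d = psi_means["MT_Drug"] - psi_means["WT_Veh"]
    return -d if skipping_positive else d


def concordance_regression(
    dpsi_wt, dpsi_mt, criteria: str = ""
) -> ConcordanceResult:
    """OLS of the drug effect in mutant cells on the drug effect in WT cells,
    with intercept; reports slope, R-squared and the overall F-test p."""
    x = np.asarray(dpsi_wt, dtype=float)
    y = np.asarray(dpsi_mt, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 events for concordance regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (zero-variance) predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return ConcordanceResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_test_p=float(model.f_pvalue),
        n_events=len(x),
        criteria=criteria,
    )


def _bb_reg_nll(params, inc, tot, x, rho=None):
    """Negative log-likelihood of a logit-link beta-binomial regression.

    If ``rho`` is None the last parameter is its logit; otherwise the
    overdispersion is held fixed and all parameters are coefficients.
    """
    k = x.shape[1]
    eta = x @ params[:k]
    mu = special.expit(eta)
    if rho is None:
        rho = special.expit(params[k])
    rho = min(max(rho, 1e-6), 1 - 1e-6)
    s = (1.0 - rho) / rho
    a = mu * s
    b = (1.0 - mu) * s
    ll = np.sum(special.betaln(inc + a, tot - inc + b) - special.betaln(a, b))
    return -ll


def _fit_bb_reg(inc, tot, x, start, rho=None):
    res = optimize.minimize(
        _bb_reg_nll,
        start,
        args=(inc, tot, x, rho),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000, "maxfev": 6000},
    )
    return -res.fun, res.x, res.success


def interaction_lrt(
    inclusion, skipping, design: FactorialDesign, sample_order=None
):
    """LRT for a drug x mutation interaction on the logit-PSI scale.

    Fits beta-binomial regressions mu ~ mut + drug (null) and
    mu ~ mut + drug + mut:drug (alternative) with a shared overdispersion;
    the statistic is referred to chi-square with 1 df.

    Returns ``(p_value, effect_sign, lrt_statistic)``; non-convergence or
    degenerate data yield NaN p.
    """
    inc = np.asarray(inclusion, dtype=float)
    skp = np.asarray(skipping, dtype=float)
    tot = inc + skp
    if sample_order is None:
        sample_order = list(design.sample_conditions)
    is_mut = np.array(
        [design.sample_conditions[s].startswith("MT") for s in sample_order],
        dtype=float,
    )
    is_drug = np.array(
        [design.sample_conditions[s].endswith("Drug") for s in sample_order],
        dtype=float,
    )
    ok = tot > 0
    if ok.sum() < 6 or len({(m, d) for m, d in zip(is_mut[ok], is_drug[ok])}) < 4:
        return float("nan"), 0.0, float("nan")
    inc, tot = inc[ok], tot[ok]
    is_mut, is_drug = is_mut[ok], is_drug[ok]

    x_null = np.column_stack([np.ones_like(is_mut), is_mut, is_drug])
    x_alt = np.column_stack([x_null, is_mut * is_drug])

    # shared overdispersion from within-cell variability, fixed in both fits
    cells = {}
    for i_, t_, m_, d_ in zip(inc, tot, is_mut, is_drug):
        cells.setdefault((m_, d_), []).append((i_, t_))
    rho_hat = mom_rho_within(
        [tuple(np.array(v).T) for v in cells.values()]
    )
    p0 = special.logit((inc.sum() + 0.5) / (tot.sum() + 1.0))
    ll_null, par_null, _ = _fit_bb_reg(
        inc, tot, x_null, np.array([p0, 0.0, 0.0]), rho=rho_hat
    )
    start_alt = np.array([*par_null[:3], 0.0])
    ll_alt, par_alt, conv = _fit_bb_reg(inc, tot, x_alt, start_alt, rho=rho_hat)
    if not np.isfinite(ll_alt) or not np.isfinite(ll_null):
        log.warning("interaction_lrt: non-finite likelihood, result dropped")
        return float("nan"), 0.0, float("nan")
    scale = bartlett_scale(len(inc), 4)
    stat = max(0.0, 2.0 * (ll_alt - ll_null)) * scale
    p = float(stats.chi2.sf(stat, df=1))
    return max(p, np.nextafter(0, 1)), float(np.sign(par_alt[3])), float(stat)


def interaction_screen(
    table: JunctionCountTable, design: FactorialDesign | None = None
) -> pd.DataFrame:
    """Interaction LRT for every event; FDR via BH over defined p values."""
    if design is None:
        design = FactorialDesign.from_table(table)
    rows = []
    for ev in table.events:
        p, sign, stat = interaction_lrt(
            table.inclusion_counts.loc[ev.event_id, table.samples].to_numpy(),
            table.skipping_counts.loc[ev.event_id, table.samples].to_numpy(),
            design,
            sample_order=table.samples,
        )
        rows.append(
            {
                "event_id": ev.event_id,
                "event_type": ev.event_type,
                "interaction_p": p,
                "effect_sign": sign,
                "lrt_statistic": stat,
            }
        )
    res = pd.DataFrame(rows)
    res["interaction_fdr"] = bh_adjust(res["interaction_p"].to_numpy())
    return res


def classify_events(
    five: dict,
    fdr_max: float = 0.10,
    min_abs_dpsi: float = 0.01,
    interaction: pd.DataFrame | None = None,
    interaction_fdr_max: float = 0.10,
) -> pd.DataFrame:
    """Per-event classification labels from the five comparisons.

    drug-concordant: both drug effects significant and same-signed.
    drug-discordant: both significant, opposite-signed.
    cumulative-exacerbated: concordant and |cumulative| > |drug effect in WT|.
    trajectory-eligible: all five comparisons pass the strict thresholds.
    interaction-significant: interaction screen FDR < threshold.
    """
    names = [c[0] for c in COMPARISONS]
    merged = None
    for name in names:
        df = five[name][["event_id", "delta_psi", "fdr"]].rename(
            columns={"delta_psi": f"dpsi_{name}", "fdr": f"fdr_{name}"}
        )
        merged = df if merged is None else merged.merge(df, on="event_id", how="inner")

    def sig(name):
        return (merged[f"fdr_{name}"] < fdr_max) & (
            merged[f"dpsi_{name}"].abs() > min_abs_dpsi
        )

    sig_wt = sig("drug_vs_veh_WT")
    sig_mt = sig("drug_vs_veh_MT")
    same_sign = (
        np.sign(merged["dpsi_drug_vs_veh_WT"]) == np.sign(merged["dpsi_drug_vs_veh_MT"])
    ) & (merged["dpsi_drug_vs_veh_WT"] != 0)
    both = sig_wt & sig_mt
    merged["drug_concordant"] = both & same_sign
    merged["drug_discordant"] = both & ~same_sign
    merged["cumulative_exacerbated"] = (
        merged["drug_concordant"]
        & (merged["dpsi_cumulative"].abs() > merged["dpsi_drug_vs_veh_WT"].abs())
    )
    merged["trajectory_eligible"] = np.logical_and.reduce([sig(n) for n in names])
    if interaction is not None:
        inter = interaction.set_index("event_id")["interaction_fdr"]
        merged["interaction_significant"] = (
            merged["event_id"].map(inter) < interaction_fdr_max
        ).fillna(False)
    else:
        merged["interaction_significant"] = False
    return merged


def trajectory_table(
    psi_means: pd.DataFrame,
    eligible_ids,
    skipping_positive: bool = False,
) -> pd.DataFrame:
    """Per-event condition trajectories relative to the WT+vehicle baseline.

    Rows give the delta-PSI of each condition against (WT,Veh); the baseline
    entry is exactly 0.  Events are split by the sign of the cumulative
    effect ("increased-skipping" vs "increased-inclusion" on the reported
    scale).
    """
    sub = psi_means.loc[list(eligible_ids)]
    sign = -1.0 if skipping_positive else 1.0
    out = pd.DataFrame(index=sub.index)
    for cond in CONDITIONS:
        out[cond] = sign * (sub[cond] - sub["WT_Veh"])
    cum = out["MT_Drug"]
    if skipping_positive:
        out["group"] = np.where(cum > 0, "increased-skipping", "increased-inclusion")
    else:
        out["group"] = np.where(cum < 0, "increased-skipping", "increased-inclusion")
    return out
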