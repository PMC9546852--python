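"""Treatment-effect estimation from per-sample signature exposures.

Covers the dose-response of platinum mutations on chemotherapy cycle count
(mixed model with per-donor random intercept), the coupling of platinum
single- and double-base substitutions (least-squares ratio), aging-rate
comparisons between treated and untreated groups, and the nonparametric
group contrasts used throughout (one-sided Wilcoxon rank-sum, Pearson
correlation with Fisher-z interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .burden import AgingModelFit, _fit_lmm_arrays, fit_aging_lmm


@dataclass
class DoseResponseFit:
    """Mixed-model slope of exposure on treatment cycle count."""

    slope: float  # mutations per cycle
    slope_se: float
    p_value: float  # two-tailed t on the slope
    n_samples: int
    n_donors: int


@dataclass
class RatioFit:
    """Least-squares coupling of DBS on SBS exposures."""

    slope_dbs_per_sbs: float
    ratio_sbs_per_dbs: float  # 1 / slope
    ratio_se: float  # delta-method SE of the ratio
    pearson_r: float
    n: int


def dose_response(
    exposures: pd.Series,
    meta: pd.DataFrame,
    cycles_col: str = "capox_cycles",
) -> DoseResponseFit:
    """Per-cycle mutational effect: exposure ~ cycles + (1 | donor), REML.

    ``exposures`` is indexed by sample_id; ``meta`` supplies cycle counts
    and donor ids.  The p-value is a two-tailed t on the slope with
    ``n_samples - 2`` residual degrees of freedom.
    """
    m = meta.set_index("sample_id").loc[exposures.index]
    cycles = m[cycles_col].to_numpy(dtype=float)
    if len(np.unique(cycles)) < 2:
        raise ValueError("no dose contrast: all samples share one cycle count")
    y = exposures.to_numpy(dtype=float)
    donor = m["donor_id"].to_numpy()
    fit = _fit_lmm_arrays(y, cycles, donor)
    if fit is None:
        raise RuntimeError("dose-response mixed model did not converge")
    df = max(len(y) - 2, 1)
    if fit.slope_se == 0:
        p = 0.0 if fit.slope != 0 else 1.0
    else:
        t = fit.slope / fit.slope_se
        p = 2 * stats.t.sf(abs(t), df)
    return DoseResponseFit(
        slope=fit.slope,
        slope_se=fit.slope_se,
        p_value=float(p),
        n_samples=fit.n_samples,
        n_donors=fit.n_donors,
    )


def sbs_dbs_ratio(sbs_exposures, dbs_exposures) -> RatioFit:
    """SBS:DBS coupling from ordinary least squares of DBS on SBS.

    Fits DBS ~ SBS with intercept; the headline quantity is the inverted
    slope (SBS mutations per DBS mutation) with a delta-method standard
    error, alongside Pearson's r.
    """
    x = np.asarray(sbs_exposures, dtype=float)
    y = np.asarray(dbs_exposures, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.var(x) == 0:
        raise ValueError("zero variance in SBS exposures")
    res = stats.linregress(x, y)
    slope, se = float(res.slope), float(res.stderr)
    if slope <= 0:
        ratio = np.nan
        ratio_se = np.nan
    else:
        ratio = 1.0 / slope
        ratio_se = se / slope**2
    return RatioFit(
        slope_dbs_per_sbs=slope,
        ratio_sbs_per_dbs=ratio,
        ratio_se=ratio_se,
        pearson_r=float(res.rvalue),
        n=x.size,
    )


def aging_rate(
    exposures: pd.DataFrame,
    meta: pd.DataFrame,
    aging_signatures: tuple[str, ...] = ("SBS1", "SBS5", "SBS18"),
) -> AgingModelFit:
    """Annual aging-signature mutation rate from summed aging exposures.

    Sums the aging-signature exposures per sample and fits the same mixed
    model as the burden aging fit; applied separately to treated and
    untreated groups their slopes are directly comparable.
    """
    cols = [s for s in aging_signatures if s in exposures.columns]
    if not cols:
        raise ValueError("no aging signature columns present in exposures")
    summed = exposures[cols].sum(axis=1)
    m = meta.set_index("sample_id").loc[summed.index]
    table = pd.DataFrame(
        {
            "donor_id": m["donor_id"].to_numpy(),
            "age": m["age"].to_numpy(dtype=float),
            "burden": summed.to_numpy(dtype=float),
        }
    )
    return fit_aging_lmm(table)


def compare_groups(values_a, values_b, alternative: str = "greater") -> float:
    """One-sided Wilcoxon rank-sum p-value for group A vs group B.

    Uses exact enumeration when both groups are small (min(n, m) <= 10)
    and tie-free, otherwise the normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def correlate(x, y) -> tuple[float, float, tuple[float, float]]:
    """Pearson correlation with two-sided p and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need paired vectors of length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if x.size > 3 and abs(r) < 1:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(x.size - 3)
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    else:
        lo, hi = (r, r)
    return r, float(p), (float(lo), float(hi))
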