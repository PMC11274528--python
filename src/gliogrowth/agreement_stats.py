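"""Agreement and classification statistics for method comparison.

The statistical layer comparing linear tumor-size estimation against the
segmented-volume reference: Pearson correlation, Lin's concordance
correlation coefficient (CCC), Bland–Altman limits of agreement,
cross-tabulation diagnostics (sensitivity, specificity, predictive values,
likelihood ratios), empirical ROC analysis with a Youden-optimal
threshold, the small/large-tumor subgroup split at MTD 35 mm, and the
ΔMTD-cutoff concordance sweep used to probe whether excluding small MTD
changes (likely measurement error) improves VDE agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "ClassificationReport",
    "pearson_r",
    "lin_ccc",
    "bland_altman",
    "crosstab_metrics",
    "roc_optimal_threshold",
    "subgroup_concordance",
    "vde_concordance_sweep",
]


@dataclass(frozen=True)
class AgreementReport:
    """Pairwise agreement between two measurement series."""

    pearson_r: float
    pearson_ci95: tuple[float, float]
    lin_ccc: float
    lin_ccc_ci95: tuple[float, float]
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float
    n: int


@dataclass(frozen=True)
class ClassificationReport:
    """2×2 diagnostics of a predictor against the volume ground truth.

    Percentages for sensitivity/specificity/PPV/NPV, plain ratios for the
    likelihood ratios; any quantity whose denominator class is absent is
    None.  The raw counts are stored so every figure is recomputable.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    lr_pos: float | None
    lr_neg: float | None
    n: int
    sensitivity_ci95: tuple[float, float] | None = None
    specificity_ci95: tuple[float, float] | None = None
    auc: float | None = None
    optimal_threshold: float | None = None


def _as_arrays(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    return x, y


def pearson_r(x, y) -> tuple[float, tuple[float, float]]:
    """Pearson correlation with a Fisher-z 95% CI."""
    x, y = _as_arrays(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    if n > 3 and abs(r) < 1:
        z = math.atanh(r)
        hw = 1.959963984540054 / math.sqrt(n - 3)
        ci = (math.tanh(z - hw), math.tanh(z + hw))
    else:
        ci = (r, r)
    return r, ci


def lin_ccc(x, y, sample_variance: bool = False
            ) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a 95% CI.

    CCC = 2·cov(x,y) / (var(x) + var(y) + (mean(x) − mean(y))²), with
    population (1/n) variances — the classical form; ``sample_variance``
    switches to 1/(n−1).  The CI applies the Fisher z-transform with
    Lin's (1989) asymptotic variance of the transformed coefficient.
    """
    x, y = _as_arrays(x, y)
    n = len(x)
    ddof = 1 if sample_variance else 0
    sx2 = float(np.var(x, ddof=ddof))
    sy2 = float(np.var(y, ddof=ddof))
    sxy = float(np.cov(x, y, ddof=ddof)[0, 1])
    dmu = float(np.mean(x) - np.mean(y))
    denom = sx2 + sy2 + dmu * dmu
    if denom == 0:
        raise ValueError("zero combined variance: CCC undefined")
    ccc = 2.0 * sxy / denom

    # Lin 1989 variance of z = atanh(ccc)
    ci = (ccc, ccc)
    if sx2 > 0 and sy2 > 0 and n > 2:
        r = sxy / math.sqrt(sx2 * sy2)
        u2 = dmu * dmu / math.sqrt(sx2 * sy2)
        c = ccc
        if abs(c) < 1 and abs(r) > 0:
            var_z = ((1 - r * r) * c * c / ((1 - c * c) * r * r)
                     + 2 * c ** 3 * (1 - c) * u2 / (r * (1 - c * c) ** 2)
                     - c ** 4 * u2 * u2 / (2 * r * r * (1 - c * c) ** 2)
                     ) / (n - 2)
            if var_z > 0:
                hw = 1.959963984540054 * math.sqrt(var_z)
                z = math.atanh(c)
                ci = (math.tanh(z - hw), math.tanh(z + hw))
    return float(ccc), ci


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland–Altman agreement: mean difference and 95% limits.

    Differences d = x − y; limits are mean(d) ± 1.96·sd(d) (sample sd).
    Swapping x and y negates all three quantities.
    """
    x, y = _as_arrays(x, y)
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def agreement_report(x, y) -> AgreementReport:
    """Bundle Pearson, CCC and Bland–Altman for one method pair."""
    r, r_ci = pearson_r(x, y)
    ccc, ccc_ci = lin_ccc(x, y)
    mean, lo, hi = bland_altman(x, y)
    return AgreementReport(pearson_r=r, pearson_ci95=r_ci, lin_ccc=ccc,
                           lin_ccc_ci95=ccc_ci, ba_mean_diff=mean,
                           ba_loa_low=lo, ba_loa_high=hi, n=len(x))


# ---------------------------------------------------------------------------
# classification diagnostics


def _clopper_pearson(k: int, n: int) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return 100 * lo, 100 * hi


def crosstab_metrics(predicted, truth) -> ClassificationReport:
    """Cross-tabulation diagnostics of progression calls against truth.

    Inputs are boolean-like vectors (True = progression).  Counts are
    cross-tabulated exactly; derived quantities use rational arithmetic on
    the counts before float conversion.  Sensitivity/specificity carry
    Clopper–Pearson 95% CIs.  Diagnostics whose defining class is absent
    are None rather than NaN.
    """
    p = np.asarray(predicted, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predicted and truth must be aligned 1D vectors")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))

    def pct(num: int, den: int) -> float | None:
        return float(100 * Fraction(num, den)) if den else None

    sens = pct(tp, tp + fn)
    spec = pct(tn, tn + fp)
    ppv = pct(tp, tp + fp)
    npv = pct(tn, tn + fn)
    lr_pos = None
    lr_neg = None
    if sens is not None and spec is not None:
        if tn + fp:
            fpr = Fraction(fp, tn + fp)
            tpr = Fraction(tp, tp + fn)
            lr_pos = float(tpr / fpr) if fpr else (math.inf if tpr else None)
            tnr = Fraction(tn, tn + fp)
            fnr = Fraction(fn, tp + fn)
            lr_neg = float(fnr / tnr) if tnr else None
    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        lr_pos=lr_pos, lr_neg=lr_neg, n=len(p),
        sensitivity_ci95=(_clopper_pearson(tp, tp + fn)
                          if tp + fn else None),
        specificity_ci95=(_clopper_pearson(tn, tn + fp)
                          if tn + fp else None),
    )


def roc_optimal_threshold(
    changes, truth, criterion: str = "youden"
) -> tuple[float, float, float, float]:
    """Empirical ROC of percent-change values against the truth labels.

    Classification reads "progression if change > t"; candidate cutoffs
    are the distinct observed changes (plus −inf for the all-positive
    corner).  Returns ``(auc, threshold, sensitivity, specificity)`` with
    sensitivity/specificity in %, AUC by the trapezoid rule.  The optimal
    threshold maximizes the Youden index J = sens + spec − 1 (ties broken
    toward higher specificity, i.e. the larger cutoff); ``criterion=
    "closest"`` instead minimizes the distance to the (0, 1) ROC corner.
    """
    c = np.asarray(changes, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if c.shape != t.shape or c.ndim != 1:
        raise ValueError("changes and truth must be aligned 1D vectors")
    n1 = int(t.sum())
    n0 = int((~t).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both truth classes present")

    cuts = np.unique(c)  # ascending
    # sens/spec for rule "change > cut"
    sens = np.array([(c[t] > u).mean() for u in cuts])
    spec = np.array([(c[~t] <= u).mean() for u in cuts])
    # staircase from (0,0) at cut=+inf, through cuts in descending order,
    # to (1,1) at cut=-inf; fpr and tpr are both non-decreasing along it
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))

    if criterion == "youden":
        j = sens + spec - 1.0
        best = np.flatnonzero(j == j.max())
        k = int(best[np.argmax(spec[best])])
    elif criterion == "closest":
        d2 = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
        best = np.flatnonzero(d2 == d2.min())
        k = int(best[np.argmax(spec[best])])
    else:
        raise ValueError("criterion must be 'youden' or 'closest'")
    return auc, float(cuts[k]), float(100 * sens[k]), float(100 * spec[k])


# ---------------------------------------------------------------------------
# VDE concordance analyses


def subgroup_concordance(
    mtd_v, vde_v, vde_3d, cut_mm: float = 35.0
) -> dict[str, dict]:
    """VDE agreement split into small (MTD.V < cut) and large (≥ cut)
    tumors.

    Small residual tumors suffer the "residue effect": satellite residues
    contribute to the segmented volume but not to the single-residue
    linear measures, degrading VDE concordance.  Returns per-subgroup
    dicts with n, Lin's CCC (None when the subgroup is too small), and the
    mean VDE difference.
    """
    if cut_mm <= 0:
        raise ValueError("cut must be > 0")
    mtd_v = np.asarray(mtd_v, dtype=float)
    vde_v = np.asarray(vde_v, dtype=float)
    vde_3d = np.asarray(vde_3d, dtype=float)
    out = {}
    for name, sel in (("small", mtd_v < cut_mm), ("large", mtd_v >= cut_mm)):
        n = int(sel.sum())
        entry: dict = {"n": n, "lin_ccc": None, "mean_diff": None,
                       "empty": n == 0}
        if n >= 3:
            try:
                entry["lin_ccc"] = lin_ccc(vde_3d[sel], vde_v[sel])[0]
            except ValueError:
                pass
        if n:
            entry["mean_diff"] = float(np.mean(vde_3d[sel] - vde_v[sel]))
        out[name] = entry
    return out


def vde_concordance_sweep(
    delta_mtd, vde_v, vde_3d, grid=None
) -> list[dict]:
    """Concordance vs minimal |ΔMTD| retention cutoff.

    For each cutoff in ``grid`` (default 0–10 mm in 0.5 mm steps), windows
    with |ΔMTD| ≥ cutoff are retained and the Lin CCC between the two VDE
    variants is recomputed, alongside the retained fraction.  CCC is None
    when fewer than 3 windows remain.
    """
    delta_mtd = np.abs(np.asarray(delta_mtd, dtype=float))
    vde_v = np.asarray(vde_v, dtype=float)
    vde_3d = np.asarray(vde_3d, dtype=float)
    if grid is None:
        grid = np.arange(0.0, 10.5, 0.5)
    out = []
    for cut in grid:
        if cut < 0:
            raise ValueError("cutoffs must be non-negative")
        sel = delta_mtd >= cut
        n = int(sel.sum())
        ccc = None
        if n >= 3:
            try:
                ccc = lin_ccc(vde_3d[sel], vde_v[sel])[0]
            except ValueError:
                pass
        out.append({"cutoff": float(cut), "lin_ccc": ccc,
                    "fraction_retained": n / len(delta_mtd), "n": n})
    return out
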