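"""Region-level activation statistics versus control.

Vocabulary (all logs natural; the statistics are base-invariant):

* log-relative density — ln(density / control-group mean density), one
  value per treatment animal and region; zero denotes no change.
* Z-score (per animal) — the animal's ln density standardized by the
  control group's mean and SD of ln density for that region.
* Z value (per region) — mean log-relative density divided by its
  standard error across treatment animals.

Significance screening refers each region's mean Z-score to its null
distribution and controls the false discovery rate with
Benjamini-Hochberg; regions are then ranked by Cohen's d and the top
fraction of significant regions is selected.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .regions import Contrast, RegionOntology, check_contrast, density_table, validate_counts

__all__ = [
    "log_relative_density",
    "per_animal_zscores",
    "control_log_stats",
    "region_significance",
    "bh_adjust",
    "cohens_d",
    "cohens_d_table",
    "select_top_effect",
    "coactivated_regions",
    "group_z_value",
    "ActivationAnalysis",
]

logger = logging.getLogger(__name__)


def _split(counts: pd.DataFrame, contrast: Contrast) -> tuple[pd.DataFrame, pd.DataFrame]:
    check_contrast(counts, contrast)
    dens = density_table(counts)
    treat = dens.loc[counts.loc[counts["group"] == contrast.treatment, "subject_id"].unique()]
    ctrl = dens.loc[counts.loc[counts["group"] == contrast.control, "subject_id"].unique()]
    return treat.T, ctrl.T  # regions x subjects


def _log_densities(dens: pd.DataFrame) -> pd.DataFrame:
    """ln density; animals with zero density become missing (no pseudocount)."""
    with np.errstate(divide="ignore"):
        out = np.log(dens)
    return out.where(dens > 0)


def log_relative_density(
    counts: pd.DataFrame,
    contrast: Contrast,
    control_mean: str = "raw",
) -> pd.DataFrame:
    """Per-animal log-relative densities (regions x treatment animals).

    value = ln(density_animal / mean of control densities).  The control
    mean is taken on the raw density scale by default
    (``control_mean="geometric"`` uses the geometric mean of the
    non-zero control densities instead).  A zero control mean, or a zero
    treatment density, yields a missing value.
    """
    if control_mean not in ("raw", "geometric"):
        raise ValueError("control_mean must be 'raw' or 'geometric'")
    treat, ctrl = _split(counts, contrast)
    if control_mean == "raw":
        ref = ctrl.mean(axis=1)
    else:
        ref = np.exp(_log_densities(ctrl).mean(axis=1))
    ref = ref.where(ref > 0)
    zero = ref.index[ref.isna()]
    if len(zero):
        logger.warning("zero/absent control mean in %d region(s): %s", len(zero), list(zero[:5]))
    return _log_densities(treat).sub(np.log(ref), axis=0)


def control_log_stats(counts: pd.DataFrame, contrast: Contrast) -> pd.DataFrame:
    """Per-region control-group ln-density mean, sample SD and n."""
    _, ctrl = _split(counts, contrast)
    lnc = _log_densities(ctrl)
    return pd.DataFrame(
        {
            "mean": lnc.mean(axis=1),
            "sd": lnc.std(axis=1, ddof=1),
            "n": lnc.notna().sum(axis=1),
        }
    )


def per_animal_zscores(counts: pd.DataFrame, contrast: Contrast) -> pd.DataFrame:
    """Per-animal Z-scores (regions x treatment animals).

    z = (ln density - control mean ln density) / control SD of ln
    density (sample SD, n-1).  Regions whose control SD is zero, or with
    fewer than two usable control animals, are entirely missing.
    """
    treat, _ = _split(counts, contrast)
    cstats = control_log_stats(counts, contrast)
    sd = cstats["sd"].where((cstats["sd"] > 0) & (cstats["n"] >= 2))
    degenerate = cstats.index[cstats["sd"].notna() & (cstats["sd"] == 0)]
    if len(degenerate):
        logger.warning(
            "zero control SD in %d region(s) (Z-scores missing): %s",
            len(degenerate),
            list(degenerate[:5]),
        )
    return _log_densities(treat).sub(cstats["mean"], axis=0).div(sd, axis=0)


def region_significance(
    z: pd.DataFrame,
    n_ctrl: int | pd.Series,
    method: str = "zmean",
) -> pd.Series:
    """Two-sided p-value per region for the null of no activation.

    Methods
    -------
    ``"zmean"`` (default)
        Exact test of the mean Z-score: under the null, with the control
        mean and SD estimated from n_c normal controls,
        zbar / sqrt(1/n_t + 1/n_c) follows Student t with n_c - 1 df.
        This is calibrated; the naive alternatives below are
        anti-conservative because the Z-scores share the estimated
        control mean.
    ``"t"``
        One-sample t-test of the Z-scores against zero.
    ``"wilcoxon"``
        Wilcoxon signed-rank test against zero.
    ``"auto"``
        Shapiro-Wilk gate at alpha 0.05: ``"t"`` if normality is not
        rejected, else ``"wilcoxon"``.

    Regions with fewer than two non-missing Z-scores get a missing p.
    """
    if method not in ("zmean", "t", "wilcoxon", "auto"):
        raise ValueError(f"unknown method {method!r}")
    vals = z.to_numpy(dtype=float)
    n_t = np.sum(~np.isnan(vals), axis=1)
    nc = n_ctrl.reindex(z.index).to_numpy(float) if isinstance(n_ctrl, pd.Series) else np.full(len(z), float(n_ctrl))
    p = np.full(len(z), np.nan)

    if method == "zmean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            zbar = np.nanmean(vals, axis=1)
        ok = (n_t >= 2) & (nc >= 2)
        T = zbar[ok] / np.sqrt(1.0 / n_t[ok] + 1.0 / nc[ok])
        p[ok] = 2.0 * stats.t.sf(np.abs(T), nc[ok] - 1)
        return pd.Series(p, index=z.index, name="p_raw")

    for i, row in enumerate(vals):
        x = row[~np.isnan(row)]
        if len(x) < 2:
            continue
        use = method
        if use == "auto":
            use = "t" if len(set(x)) < 3 or stats.shapiro(x).pvalue >= 0.05 else "wilcoxon"
        if use == "t":
            if np.std(x, ddof=1) == 0:
                # all identical: t undefined; flag with the smallest representable p
                p[i] = np.finfo(float).tiny if x[0] != 0 else 1.0
                logger.warning("degenerate region (zero SD of Z-scores) at %s", z.index[i])
            else:
                p[i] = stats.ttest_1samp(x, 0.0).pvalue
        else:
            if np.all(x == 0):
                p[i] = 1.0
            else:
                p[i] = stats.wilcoxon(x, alternative="two-sided").pvalue
    return pd.Series(p, index=z.index, name="p_raw")


def bh_adjust(p: pd.Series, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjusted q-values and significance flags.

    Missing p-values are excluded from the correction and stay missing.
    """
    p = pd.Series(p)
    out = pd.DataFrame(index=p.index, columns=["q_bh", "significant"])
    out["q_bh"] = np.nan
    out["significant"] = False
    mask = p.notna()
    if mask.any():
        rej, qvals, _, _ = multipletests(p[mask].to_numpy(), alpha=q, method="fdr_bh")
        out.loc[mask, "q_bh"] = qvals
        out.loc[mask, "significant"] = rej
    return out


def cohens_d(x, y) -> float:
    """Cohen's d with the pooled-SD denominator; NaN when the pooled SD is 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        return math.nan
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        return math.nan
    return float((np.mean(x) - np.mean(y)) / math.sqrt(s2))


def cohens_d_table(counts: pd.DataFrame, contrast: Contrast) -> pd.Series:
    """Per-region Cohen's d on ln densities (treatment vs control)."""
    treat, ctrl = _split(counts, contrast)
    lt, lc = _log_densities(treat), _log_densities(ctrl)
    d = [cohens_d(lt.loc[r], lc.loc[r]) for r in lt.index]
    return pd.Series(d, index=lt.index, name="cohen_d")


def select_top_effect(stats_table: pd.DataFrame, fraction: float = 0.40) -> list[str]:
    """Regions significant at the FDR threshold whose Cohen's d ranks in
    the top ``ceil(fraction * n_significant)`` (boundary ties included).

    Returns acronyms ordered by (-d, acronym).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    sig = stats_table[stats_table["significant"] & stats_table["cohen_d"].notna()]
    if sig.empty:
        return []
    k = math.ceil(fraction * len(sig))
    ordered = sig.sort_values(["cohen_d"], ascending=False, kind="mergesort")
    threshold = ordered["cohen_d"].iloc[k - 1]
    kept = ordered[ordered["cohen_d"] >= threshold]
    return sorted(kept.index, key=lambda a: (-kept.loc[a, "cohen_d"], a))


def coactivated_regions(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    ontology: RegionOntology | None = None,
) -> tuple[set[str], dict[str, int]]:
    """Regions significantly *activated* (q < threshold, positive mean
    log-relative density) under both contrasts; optionally tallied per
    major division."""
    if set(stats_a.index) != set(stats_b.index):
        raise ValueError("contrasts were computed on different region universes")

    def activated(s: pd.DataFrame) -> set[str]:
        return set(s.index[s["significant"] & (s["mean_log_rel"] > 0)])

    common = activated(stats_a) & activated(stats_b)
    tallies: dict[str, int] = {}
    if ontology is not None:
        for region in common:
            div = ontology.division_of(region)
            tallies[div] = tallies.get(div, 0) + 1
    return common, tallies


def group_z_value(values) -> float:
    """Z value = mean / (SD / sqrt(n)) over non-missing log-relative values.

    Positive Z means higher than control. NaN when SD is 0 or n < 2.
    """
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return math.nan
    sd = np.std(x, ddof=1)
    if sd == 0:
        return math.nan
    return float(np.mean(x) / (sd / math.sqrt(len(x))))


class ActivationAnalysis(BaseEstimator):
    """Per-region activation screen for one treatment-vs-control contrast.

    Parameters
    ----------
    treatment, control : str
        Group labels forming the contrast.
    q : float, default 0.05
        Benjamini-Hochberg false-discovery threshold.
    effect_fraction : float, default 0.40
        Fraction of significant regions kept by the Cohen's d ranking.
    method : {"zmean", "t", "wilcoxon", "auto"}, default "zmean"
        Region significance test (see :func:`region_significance`).
    control_mean : {"raw", "geometric"}, default "raw"
        Control reference for log-relative densities.

    Attributes (after :meth:`fit`)
    ------------------------------
    logrel_ : DataFrame, regions x treatment animals
    zscores_ : DataFrame, regions x treatment animals
    stats_ : DataFrame per region with columns n_treat, n_ctrl,
        mean_log_rel, se_log_rel, z_value, p_raw, q_bh, cohen_d,
        significant, selected.
    selected_ : list of region acronyms (ordered by effect size).
    """

    def __init__(
        self,
        treatment: str = "KET",
        control: str = "saline",
        q: float = 0.05,
        effect_fraction: float = 0.40,
        method: str = "zmean",
        control_mean: str = "raw",
    ):
        self.treatment = treatment
        self.control = control
        self.q = q
        self.effect_fraction = effect_fraction
        self.method = method
        self.control_mean = control_mean

    def fit(self, counts: pd.DataFrame, y=None) -> "ActivationAnalysis":
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        counts = validate_counts(counts)
        contrast = Contrast(self.treatment, self.control)
        self.contrast_ = contrast
        self.logrel_ = log_relative_density(counts, contrast, control_mean=self.control_mean)
        self.zscores_ = per_animal_zscores(counts, contrast)
        cstats = control_log_stats(counts, contrast)

        lr = self.logrel_
        n_treat = lr.notna().sum(axis=1)
        mean_lr = lr.mean(axis=1)
        se_lr = lr.std(axis=1, ddof=1) / np.sqrt(n_treat.where(n_treat > 0))
        z_value = mean_lr / se_lr.where(se_lr > 0)

        p = region_significance(self.zscores_, cstats["n"], method=self.method)
        adj = bh_adjust(p, q=self.q)
        d = cohens_d_table(counts, contrast)

        table = pd.DataFrame(
            {
                "n_treat": n_treat,
                "n_ctrl": cstats["n"],
                "mean_log_rel": mean_lr,
                "se_log_rel": se_lr,
                "z_value": z_value,
                "p_raw": p,
                "q_bh": adj["q_bh"].astype(float),
                "cohen_d": d,
                "significant": adj["significant"].astype(bool),
            }
        ).sort_index()
        self.selected_ = select_top_effect(table, fraction=self.effect_fraction)
        table["selected"] = table.index.isin(self.selected_)
        self.stats_ = table
        return self

    def fit_transform(self, counts: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(counts).stats_
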