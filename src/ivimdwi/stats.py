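"""Nonparametric group statistics and ROC analysis of the subject table.

The analysis battery: Mann-Whitney U comparisons of every diffusion
parameter between cancer and healthy groups (and across tumor-attribute
strata within the cancer group, uncorrected), Spearman rank correlation
with tumor size, a Friedman test of the per-b ADC decline with Wilcoxon
signed-rank post-hoc pairs under a Bonferroni family correction, and ROC
curves with a Youden-index optimal cutoff.

ROC orientation is fixed to "lower value implies cancer" — the direction
every discriminating parameter shows in the modeled populations — rather
than auto-oriented per variable, which would silently flip weakly
separated parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "ComparisonResult",
    "ROCResult",
    "PosthocFamily",
    "mann_whitney",
    "friedman_across_b",
    "posthoc_wilcoxon_bonferroni",
    "spearman_with_size",
    "roc_analysis",
    "ADC_COLUMNS",
    "ALL_PARAM_COLUMNS",
    "STRATA",
    "table2_report",
    "table3_report",
    "table4_report",
    "friedman_report",
    "strata_comparisons",
    "null_rejection_rate",
]

#: Per-b two-point ADC columns of the subject table, in b order.
ADC_COLUMNS = [f"adc_{b}" for b in (20, 50, 100, 200, 400, 600, 800, 1000)]
#: Every parameter column the reports cover.
ALL_PARAM_COLUMNS = ADC_COLUMNS + ["adc_total", "adc_fast", "adc_slow", "f"]
#: Tumor-attribute strata: column -> (level A, level B).
STRATA = {
    "grade": ("moderate", "poor"),
    "location": ("head", "elsewhere"),
    "t_stage": ("T1/T2", "T3/T4"),
    "nodal": ("present", "absent"),
}


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    test: str
    flag: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class ROCResult:
    """ROC summary at the Youden-optimal cutoff.

    ``cutoff`` is in the variable's natural units (the reporting layer
    rescales ADCs); the decision rule is "value <= cutoff => test-positive
    for cancer".  ``ppv``/``npv``/``accuracy`` use the sample prevalence
    (the given group sizes).
    """

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    n_cancer: int
    n_healthy: int


@dataclass(frozen=True)
class PosthocFamily:
    """All pairwise signed-rank tests over k repeated measures."""

    comparisons: dict  # (i, j) column-index pair -> ComparisonResult
    family_alpha: float
    n_pairs: int
    corrected_threshold: float

    @property
    def significant_pairs(self) -> list:
        return [
            pair
            for pair, res in self.comparisons.items()
            if not np.isnan(res.p_value) and res.p_value < self.corrected_threshold
        ]


def mann_whitney(x, y) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of the U null distribution when ``n1*n2 <= 400`` and
    the pooled sample is tie-free; otherwise the normal approximation with
    tie correction and continuity correction.  The reported statistic is
    ``U`` for the first sample (pairs where x exceeds y, ties counting a
    half).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size * y.size <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=x.size,
        n2=y.size,
        test=f"mann-whitney ({method})",
    )


def friedman_across_b(matrix) -> ComparisonResult:
    """Friedman rank test across repeated measures (columns).

    ``matrix`` is subjects x conditions (for the default scheme, the eight
    per-b ADC means).  Ties within a row get average ranks.  Missing cells
    are rejected — no imputation.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise ValueError("need >= 2 subjects and >= 3 conditions")
    if np.isnan(m).any():
        raise ValueError("missing cells are not allowed")
    if np.all(m == m[:, [0]]):  # every condition identical: no evidence
        return ComparisonResult(0.0, 1.0, m.shape[0], m.shape[1], "friedman")
    stat, p = sps.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return ComparisonResult(float(stat), float(p), m.shape[0], m.shape[1], "friedman")


def posthoc_wilcoxon_bonferroni(matrix, family_alpha: float = 0.05) -> PosthocFamily:
    """All-pairs Wilcoxon signed-rank tests with a Bonferroni threshold.

    For k conditions there are k(k-1)/2 pairs and the corrected threshold
    is ``family_alpha`` divided by the pair count (0.05/28 ≈ 0.0018 for the
    eight-b scheme).  Zero differences are discarded (Wilcoxon's
    convention); a pair whose differences are all zero is flagged
    degenerate rather than dropped silently.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise ValueError("need >= 2 subjects and >= 3 conditions")
    if np.isnan(m).any():
        raise ValueError("missing cells are not allowed")
    k = m.shape[1]
    n_pairs = k * (k - 1) // 2
    threshold = family_alpha / n_pairs
    comparisons = {}
    for i, j in itertools.combinations(range(k), 2):
        diffs = m[:, i] - m[:, j]
        if np.all(diffs == 0):
            comparisons[(i, j)] = ComparisonResult(
                np.nan, np.nan, m.shape[0], m.shape[0],
                "wilcoxon signed-rank", flag="all differences zero",
            )
            continue
        mode = "exact" if (np.count_nonzero(diffs) <= 25) else "approx"
        res = sps.wilcoxon(
            m[:, i], m[:, j], zero_method="wilcox", alternative="two-sided",
            method="auto" if mode == "exact" else "approx",
        )
        comparisons[(i, j)] = ComparisonResult(
            float(res.statistic), float(res.pvalue), m.shape[0], m.shape[0],
            "wilcoxon signed-rank",
        )
    return PosthocFamily(
        comparisons=comparisons,
        family_alpha=family_alpha,
        n_pairs=n_pairs,
        corrected_threshold=threshold,
    )


def spearman_with_size(values, sizes) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties), two-sided p.

    Raises on constant input, where the coefficient is undefined.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(sizes, dtype=float)
    if v.shape != s.shape or v.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.unique(v).size == 1 or np.unique(s).size == 1:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = sps.spearmanr(v, s)
    return float(rho), float(p)


def roc_analysis(cancer_values, healthy_values) -> ROCResult:
    """ROC analysis with the "lower value => cancer" orientation.

    AUC is the trapezoidal area over all empirical thresholds; the optimal
    cutoff maximizes Youden's J = sensitivity + specificity - 1 over the
    observed values (ties broken toward higher sensitivity).  A subject is
    called cancer-positive when its value is <= the cutoff.
    """
    cv = np.asarray(cancer_values, dtype=float)
    hv = np.asarray(healthy_values, dtype=float)
    if cv.size == 0 or hv.size == 0:
        raise ValueError("both groups must be non-empty")
    y = np.concatenate([np.ones(cv.size), np.zeros(hv.size)])
    scores = -np.concatenate([cv, hv])  # low value -> high cancer score
    auc = float(roc_auc_score(y, scores))

    candidates = np.unique(np.concatenate([cv, hv]))
    best = None
    for c in candidates:
        sens = float(np.mean(cv <= c))
        spec = float(np.mean(hv > c))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and sens > best[1]
        ):
            best = (j, sens, spec, c)
    _, sens, spec, cutoff = best
    tp = int(np.sum(cv <= cutoff))
    fn = cv.size - tp
    fp = int(np.sum(hv <= cutoff))
    tn = hv.size - fp
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    acc = (tp + tn) / (cv.size + hv.size)
    return ROCResult(
        auc=auc, cutoff=float(cutoff), sensitivity=sens, specificity=spec,
        ppv=float(ppv), npv=float(npv), accuracy=float(acc),
        n_cancer=cv.size, n_healthy=hv.size,
    )


# ---------------------------------------------------------------------------
# report builders over the subject table

_ADC_SCALE = 1e3  # mm^2/s -> x10^-3 mm^2/s for reporting


def _fmt_scale(col: str) -> float:
    return 1.0 if col == "f" else _ADC_SCALE


def _present(table: pd.DataFrame) -> list[str]:
    return [c for c in ALL_PARAM_COLUMNS if c in table.columns]


def table2_report(table: pd.DataFrame) -> pd.DataFrame:
    """Cancer-vs-healthy comparison of every parameter (group mean +/- SD
    on the x10^-3 mm^2/s scale for ADCs, Mann-Whitney p)."""
    cancer = table[table["group"] == "cancer"]
    healthy = table[table["group"] == "healthy"]
    if cancer.empty or healthy.empty:
        raise ValueError("table2 needs both groups")
    rows = []
    for col in _present(table):
        sc = _fmt_scale(col)
        res = mann_whitney(cancer[col].to_numpy(), healthy[col].to_numpy())
        rows.append(
            {
                "parameter": col,
                "cancer_mean": cancer[col].mean() * sc,
                "cancer_sd": cancer[col].std(ddof=1) * sc,
                "healthy_mean": healthy[col].mean() * sc,
                "healthy_sd": healthy[col].std(ddof=1) * sc,
                "u_statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def table3_report(table: pd.DataFrame, parameters: list[str] | None = None) -> pd.DataFrame:
    """ROC summary per parameter (cutoff on the x10^-3 mm^2/s scale)."""
    cancer = table[table["group"] == "cancer"]
    healthy = table[table["group"] == "healthy"]
    if cancer.empty or healthy.empty:
        raise ValueError("table3 needs both groups")
    rows = []
    for col in parameters or _present(table):
        sc = _fmt_scale(col)
        roc = roc_analysis(cancer[col].to_numpy(), healthy[col].to_numpy())
        rows.append(
            {
                "parameter": col,
                "cutoff": roc.cutoff * sc,
                "auc": roc.auc,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "ppv": roc.ppv,
                "npv": roc.npv,
                "accuracy": roc.accuracy,
            }
        )
    return pd.DataFrame(rows)


def strata_comparisons(table: pd.DataFrame, parameters: list[str] | None = None) -> pd.DataFrame:
    """Within-cancer attribute-stratum comparisons (uncorrected p)."""
    cancer = table[table["group"] == "cancer"]
    rows = []
    for attr, (lev_a, lev_b) in STRATA.items():
        if attr not in cancer.columns:
            continue
        ga = cancer[cancer[attr] == lev_a]
        gb = cancer[cancer[attr] == lev_b]
        if ga.empty or gb.empty:
            continue
        for col in parameters or _present(table):
            sc = _fmt_scale(col)
            res = mann_whitney(ga[col].to_numpy(), gb[col].to_numpy())
            rows.append(
                {
                    "parameter": col,
                    "attribute": attr,
                    "level_a": lev_a,
                    "level_b": lev_b,
                    "mean_a": ga[col].mean() * sc,
                    "sd_a": ga[col].std(ddof=1) * sc,
                    "mean_b": gb[col].mean() * sc,
                    "sd_b": gb[col].std(ddof=1) * sc,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)


def table4_report(table: pd.DataFrame) -> pd.DataFrame:
    """Parameter x attribute strata table; the per-stratum comparisons are
    reported uncorrected, as the study design prescribes (only the
    Friedman post-hoc family is multiplicity-corrected)."""
    return strata_comparisons(table)


def null_rejection_rate(
    n_replicates: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    parameters: list[str] | None = None,
    n_cancer: int = 51,
    n_healthy: int = 57,
) -> float:
    """Type-I calibration of the attribute-strata comparisons.

    Simulates cohorts in which tumor attributes are independent of the
    diffusion parameters (the generator's construction), runs the
    within-cancer strata battery on each, and returns the fraction of
    comparisons rejected at ``alpha``.  On a calibrated test the rate
    should sit near ``alpha``.
    """
    from .phantom import CohortSpec, sample_cohort_table

    parameters = parameters or ["f", "adc_slow", "adc_fast"]
    ss = np.random.SeedSequence(seed)
    rejected = total = 0
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        table = sample_cohort_table(
            CohortSpec(n_cancer=n_cancer, n_healthy=n_healthy, seed=rep_seed),
            derived=False,
        )
        comparisons = strata_comparisons(table, parameters)
        pvals = comparisons["p_value"].to_numpy()
        rejected += int((pvals < alpha).sum())
        total += pvals.size
    return rejected / total


def friedman_report(
    table: pd.DataFrame, group: str, family_alpha: float = 0.05
) -> tuple[ComparisonResult, PosthocFamily]:
    """Friedman test over the per-b ADC columns of one group, plus the
    Bonferroni-corrected signed-rank post-hoc family."""
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no subjects in group {group!r}")
    matrix = sub[ADC_COLUMNS].to_numpy()
    return friedman_across_b(matrix), posthoc_wilcoxon_bonferroni(matrix, family_alpha)
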