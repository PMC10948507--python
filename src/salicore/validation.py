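"""Representativeness validation of a core subset against the entire collection.

Per trait, four classical core-collection metrics are computed:

- MD% : |mean_core - mean_entire| / mean_entire * 100
- CR% : range_core / range_entire * 100 (coincidence rate of range)
- VR% : CV_core / CV_entire * 100 (variable rate)
- VD% : |CV_core - CV_entire| / CV_core * 100 (variance difference)

so that whenever the core is more variable than the entire set, VD and VR
obey VD% = (VR% - 100)/VR% * 100. A core is conventionally judged adequate
when MD% stays below 20% and CR% exceeds 80%. Diversity is summarized with
the Shannon-Weaver index over trait-value classes; distributional agreement
uses a two-group studentized-range (Newman-Keuls) test on means, the
Brown-Forsythe variant of Levene's test on spread, and the Wilcoxon rank-sum
test on medians. Correlation-structure preservation and a correlation-matrix
PCA round out the report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedStatisticError
from .traits import TraitTable

logger = logging.getLogger(__name__)


def _cv(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.mean(values))


@dataclass
class RepresentativenessReport:
    """Per-trait metrics plus summary means and verdicts."""

    per_trait: pd.DataFrame
    summary: dict[str, float]
    verdicts: dict[str, bool]


def diversity_loss_pct(h_entire: float, h_core: float) -> float:
    """Percent Shannon-diversity loss of the core relative to the entire set."""
    if h_entire == 0:
        raise UndefinedStatisticError("entire-set diversity is zero")
    return (h_entire - h_core) / h_entire * 100.0


def representativeness_metrics(entire: TraitTable, core: TraitTable,
                               shannon_scheme: str = "distinct_values",
                               shannon_bins: int = 10) -> RepresentativenessReport:
    """Full per-trait representativeness report for a core subset.

    The core's genotype ids must be a subset of the entire set's; traits with
    zero entire-set mean or range get missing metrics with a warning rather
    than an error.
    """
    if not set(core.genotype_ids).issubset(entire.genotype_ids):
        raise ValueError("core genotypes must be a subset of the entire collection")
    if list(core.trait_names) != list(entire.trait_names):
        raise ValueError("core and entire tables must share the same trait set")

    rows = []
    for trait in entire.trait_names:
        e = entire.data[trait].to_numpy(dtype=float)
        c = core.data[trait].to_numpy(dtype=float)
        mean_e, mean_c = float(np.mean(e)), float(np.mean(c))
        range_e = float(np.ptp(e))
        row: dict[str, float] = {"trait": trait}
        if mean_e == 0 or range_e == 0:
            warnings.warn(f"trait {trait!r}: zero entire-set mean or range; "
                          "metrics reported as missing", UserWarning, stacklevel=2)
            row.update({k: np.nan for k in ("md_pct", "vd_pct", "cr_pct", "vr_pct")})
        else:
            cv_e, cv_c = _cv(e), _cv(c)
            row["md_pct"] = abs(mean_c - mean_e) / mean_e * 100.0
            row["cr_pct"] = float(np.ptp(c)) / range_e * 100.0
            row["vr_pct"] = cv_c / cv_e * 100.0
            row["vd_pct"] = abs(cv_c - cv_e) / cv_c * 100.0 if cv_c != 0 else np.nan
        row["h_core"] = shannon_weaver(c, scheme=shannon_scheme, bins=shannon_bins)
        row["h_entire"] = shannon_weaver(e, scheme=shannon_scheme, bins=shannon_bins)
        row.update(distribution_tests(e, c))
        rows.append(row)

    per_trait = pd.DataFrame(rows).set_index("trait")
    summary = {
        "mean_md_pct": float(per_trait["md_pct"].mean()),
        "mean_cr_pct": float(per_trait["cr_pct"].mean()),
        "mean_vr_pct": float(per_trait["vr_pct"].mean()),
        "mean_vd_pct": float(per_trait["vd_pct"].mean()),
        "mean_h_core": float(per_trait["h_core"].mean()),
        "mean_h_entire": float(per_trait["h_entire"].mean()),
    }
    summary["diversity_loss_pct"] = diversity_loss_pct(summary["mean_h_entire"],
                                                       summary["mean_h_core"])
    verdicts = {
        "md_below_20": bool((per_trait["md_pct"].dropna() < 20).all()),
        "cr_above_80": bool((per_trait["cr_pct"].dropna() > 80).all()),
    }
    return RepresentativenessReport(per_trait, summary, verdicts)


def shannon_weaver(values: Sequence[float],
                   scheme: str = "distinct_values", bins: int = 10) -> float:
    """Shannon-Weaver diversity H = -sum(p ln p) over value classes (nats).

    ``distinct_values`` treats each unique value as its own class, so H
    approaches ln(sample size) when values rarely tie; ``fixed_bins`` uses
    ``bins`` equal-width classes over the observed range.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise UndefinedStatisticError("Shannon index undefined for empty input")
    if scheme == "distinct_values":
        _, counts = np.unique(v, return_counts=True)
    elif scheme == "fixed_bins":
        counts, _ = np.histogram(v, bins=bins)
        counts = counts[counts > 0]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def distribution_tests(entire_col: Sequence[float], core_col: Sequence[float],
                       exact_threshold: int = 25) -> dict[str, float]:
    """Mean, spread, and location tests between the two samples.

    - ``p_mean``: two-group studentized-range test (q = |t|*sqrt(2) on the
      pooled t statistic), algebraically equivalent to the pooled two-sample
      t-test.
    - ``p_levene``: Brown-Forsythe (median-centered) Levene test.
    - ``p_wilcoxon``: Wilcoxon rank-sum / Mann-Whitney, exact when both
      samples are at or below ``exact_threshold``, otherwise the normal
      approximation with continuity correction.
    """
    e = np.asarray(entire_col, dtype=float)
    c = np.asarray(core_col, dtype=float)
    if e.size < 3 or c.size < 3:
        raise UndefinedStatisticError("distribution tests require >= 3 values per sample")

    var_e, var_c = np.var(e, ddof=1), np.var(c, ddof=1)
    df = e.size + c.size - 2
    if var_e == 0 and var_c == 0:
        warnings.warn("zero variance in both samples; mean-test p set to 1",
                      UserWarning, stacklevel=2)
        p_mean = 1.0
    else:
        pooled = ((e.size - 1) * var_e + (c.size - 1) * var_c) / df
        t = (np.mean(e) - np.mean(c)) / np.sqrt(pooled * (1 / e.size + 1 / c.size))
        q = abs(t) * np.sqrt(2.0)
        p_mean = float(stats.studentized_range.sf(q, 2, df))

    if var_e == 0 and var_c == 0:
        p_levene = 1.0
    else:
        p_levene = float(stats.levene(e, c, center="median").pvalue)

    method = "exact" if max(e.size, c.size) <= exact_threshold else "asymptotic"
    p_wilcoxon = float(stats.mannwhitneyu(e, c, alternative="two-sided",
                                          method=method, use_continuity=True).pvalue)
    return {"p_mean": p_mean, "p_levene": p_levene, "p_wilcoxon": p_wilcoxon}


@dataclass
class CorrelationComparison:
    entire_corr: pd.DataFrame
    core_corr: pd.DataFrame
    difference: pd.DataFrame
    max_abs_difference: float
    sign_agreement: float


def correlation_preservation(entire: TraitTable, core: TraitTable) -> CorrelationComparison:
    """Pearson correlation matrices of both tables and their discrepancy.

    Pairs involving a constant column are masked (NaN) in both matrices; the
    sign-agreement fraction is computed over unmasked off-diagonal pairs.
    """
    if list(core.trait_names) != list(entire.trait_names):
        raise ValueError("core and entire tables must share the same trait set")
    r_e = entire.data.corr()
    r_c = core.data.corr()
    for df, table in ((r_e, entire), (r_c, core)):
        const = [t for t in table.trait_names if table.data[t].nunique() <= 1]
        df.loc[const, :] = np.nan
        df.loc[:, const] = np.nan
    diff = r_c - r_e
    mask = np.triu(np.ones(diff.shape, dtype=bool), k=1)
    off_e = r_e.to_numpy()[mask]
    off_c = r_c.to_numpy()[mask]
    valid = np.isfinite(off_e) & np.isfinite(off_c)
    agree = float(np.mean(np.sign(off_e[valid]) == np.sign(off_c[valid]))) if valid.any() else np.nan
    max_abs = float(np.nanmax(np.abs(diff.to_numpy()[mask]))) if valid.any() else np.nan
    return CorrelationComparison(r_e, r_c, diff, max_abs, agree)


@dataclass
class PCAResult:
    loadings: pd.DataFrame
    variance_explained_pct: np.ndarray
    cumulative_pct: np.ndarray


def pca_compare(entire: TraitTable, core: TraitTable,
                n_components: int = 5) -> dict[str, PCAResult]:
    """Correlation-matrix PCA of each set, standardized within the set.

    Components are ordered by decreasing eigenvalue; each component's sign is
    fixed so its largest-magnitude loading is positive. Requesting more
    components than traits truncates with a warning.
    """
    return {"entire": _pca(entire, n_components), "core": _pca(core, n_components)}


def _pca(table: TraitTable, n_components: int) -> PCAResult:
    x = table.data.to_numpy(dtype=float)
    n_traits = x.shape[1]
    if n_components > n_traits:
        warnings.warn(f"n_components={n_components} truncated to {n_traits}",
                      UserWarning, stacklevel=3)
        n_components = n_traits
    corr = np.corrcoef((x - x.mean(axis=0)) / x.std(axis=0, ddof=1), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    var_pct = eigval / eigval.sum() * 100.0
    loadings = pd.DataFrame(eigvec[:, :n_components], index=table.trait_names,
                            columns=[f"PC{i + 1}" for i in range(n_components)])
    return PCAResult(loadings, var_pct[:n_components], np.cumsum(var_pct)[:n_components])


def load_core_benchmark() -> pd.DataFrame:
    """Published per-trait representativeness benchmark for a 64-of-318 mini-core.

    Columns: trait, cr_pct, vr_pct, vd_pct, md_pct, h_core, h_entire. Used as
    a reference fixture for the VD/VR identity and summary arithmetic.
    """
    path = resources.files("salicore.data").joinpath("core_benchmark.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")
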