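"""Fuzzy membership scoring, tolerance classification, and the predictive model.

Each trait column is min-max normalized into a membership function value
(MFV) in [0, 1]:

    positive direction:  F_ij = (X_ij - X_jmin) / (X_jmax - X_jmin)
    negative direction:  F_ij = 1 - (X_ij - X_jmin) / (X_jmax - X_jmin)

The comprehensive salt-tolerance score D_i is the arithmetic mean of a
genotype's MFVs over the supplied traits; higher D means more tolerant.
Genotypes are graded into five levels (HST, ST, MST, SS, HSS) by cutting a
hierarchical cluster tree of the one-dimensional D values, and a linear
model predicts D from seven directly measurable traits so new genotypes can
be graded without the full 14-trait assay.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy

from .exceptions import DegenerateTraitWarning, SchemaError, UndefinedStatisticError
from .traits import TraitTable

logger = logging.getLogger(__name__)

#: Tolerance grades, most to least tolerant.
GRADES: tuple[str, ...] = ("HST", "ST", "MST", "SS", "HSS")

#: Predictors of the seven-trait reference model, in its canonical order.
REFERENCE_PREDICTORS: tuple[str, ...] = ("SNC", "RNIL", "RWC", "RGR", "RKC", "Sen", "RNC")

Linkage = Literal["single", "complete", "average", "ward"]


@dataclass
class MembershipMatrix:
    """Per-genotype, per-trait membership values with the min/max used."""

    values: pd.DataFrame
    trait_min: pd.Series
    trait_max: pd.Series
    degenerate_traits: list[str] = field(default_factory=list)


def membership_matrix(table: TraitTable) -> MembershipMatrix:
    """Min-max membership values for every trait column, direction-aware.

    Min and max are taken over the rows of the supplied table. A trait whose
    max equals its min carries no ranking information; its column is set to
    0.5 with a :class:`DegenerateTraitWarning` rather than failing.
    """
    if len(table.data) < 2:
        raise UndefinedStatisticError("membership requires at least 2 genotypes")
    x = table.data
    xmin = x.min(axis=0)
    xmax = x.max(axis=0)
    span = xmax - xmin
    degenerate = [t for t in x.columns if span[t] == 0]
    if degenerate:
        msg = f"trait(s) with zero range set to membership 0.5: {degenerate}"
        logger.warning(msg)
        warnings.warn(msg, DegenerateTraitWarning, stacklevel=2)
    f = pd.DataFrame(index=x.index, columns=x.columns, dtype=float)
    for trait in x.columns:
        if span[trait] == 0:
            f[trait] = 0.5
            continue
        scaled = (x[trait] - xmin[trait]) / span[trait]
        f[trait] = 1.0 - scaled if table.directions[trait] == "negative" else scaled
    return MembershipMatrix(f, xmin, xmax, degenerate)


def comprehensive_d(mfv: MembershipMatrix) -> pd.Series:
    """D value per genotype: arithmetic mean of its membership values."""
    if mfv.values.shape[1] == 0:
        raise UndefinedStatisticError("cannot average over an empty trait set")
    if mfv.values.isna().any().any():
        raise UndefinedStatisticError("membership matrix contains missing entries")
    d = mfv.values.mean(axis=1)
    d.name = "D"
    return d


@dataclass
class ToleranceClassification:
    """Five-grade (or fewer) classification of genotypes by D value."""

    labels: pd.Series
    cluster_of: pd.Series
    cluster_mean_d: dict[int, float]
    cut_height: float
    linkage: str
    n_merged: int = 0

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def _grade_names(k: int) -> list[str]:
    # Spread k ranked clusters over the 5-grade scale; a lone cluster is MST.
    if k == 1:
        return ["MST"]
    idx = np.round(np.linspace(0, len(GRADES) - 1, min(k, len(GRADES)))).astype(int)
    return [GRADES[i] for i in idx]


def classify_tolerance(d_values: pd.Series | Sequence[float],
                       cut_height: float = 0.12,
                       linkage: Linkage = "complete",
                       max_levels: int = 5) -> ToleranceClassification:
    """Grade genotypes by hierarchical clustering of their D values.

    One-dimensional Euclidean agglomerative clustering, tree cut at
    ``cut_height``. Clusters are ranked by mean D (descending) and mapped onto
    the HST..HSS grade scale; if the cut yields more than ``max_levels``
    clusters, the two clusters with closest mean D are merged until
    ``max_levels`` remain.
    """
    d = pd.Series(d_values, dtype=float)
    if len(d) < 2:
        raise UndefinedStatisticError("classification requires at least 2 genotypes")

    if float(d.max() - d.min()) == 0.0:
        msg = "all D values identical; single MST cluster"
        logger.warning(msg)
        warnings.warn(msg, DegenerateTraitWarning, stacklevel=2)
        cluster = pd.Series(1, index=d.index)
        labels = pd.Series("MST", index=d.index, name="grade")
        return ToleranceClassification(labels, cluster, {1: float(d.mean())},
                                       cut_height, linkage)

    z = hierarchy.linkage(d.to_numpy().reshape(-1, 1), method=linkage, metric="euclidean")
    cluster = pd.Series(hierarchy.fcluster(z, t=cut_height, criterion="distance"),
                        index=d.index)

    means = {int(c): float(d[cluster == c].mean()) for c in cluster.unique()}
    n_merged = 0
    while len(means) > max_levels:
        ranked = sorted(means, key=means.get)
        gaps = [(means[ranked[i + 1]] - means[ranked[i]], ranked[i], ranked[i + 1])
                for i in range(len(ranked) - 1)]
        _, keep, absorb = min(gaps)
        cluster[cluster == absorb] = keep
        means[keep] = float(d[cluster == keep].mean())
        del means[absorb]
        n_merged += 1

    ranked_desc = sorted(means, key=means.get, reverse=True)
    names = _grade_names(len(ranked_desc))
    grade_of = {c: names[i] for i, c in enumerate(ranked_desc)}
    labels = cluster.map(grade_of).rename("grade")
    return ToleranceClassification(labels, cluster, means, cut_height, linkage, n_merged)


@dataclass
class ToleranceModel:
    """Affine predictor of the comprehensive D value from a trait subset."""

    intercept: float
    predictors: tuple[str, ...]
    coefficients: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def coefficient(self, predictor: str) -> float:
        return float(self.coefficients[self.predictors.index(predictor)])

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "intercept": float(self.intercept),
            "predictors": list(self.predictors),
            "coefficients": [float(b) for b in self.coefficients],
            "diagnostics": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for k, v in self.diagnostics.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ToleranceModel":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(
            intercept=float(payload["intercept"]),
            predictors=tuple(payload["predictors"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            diagnostics=dict(payload.get("diagnostics", {})),
        )


def reference_model() -> ToleranceModel:
    """The published seven-trait seedling salt-tolerance model for Miscanthus.

    Y = 0.6895 - 0.0012*SNC + 0.1242*RNIL + 0.0057*RWC + 0.0516*RGR
        - 0.0023*RKC - 0.0202*Sen - 0.0010*RNC

    Bundled as a text fixture so predictions can be verified against the
    published genotype panel without refitting.
    """
    path = resources.files("salicore.data").joinpath("reference_model.yaml")
    with resources.as_file(path) as p:
        return ToleranceModel.from_yaml(p)


def load_verification_panel() -> pd.DataFrame:
    """Published 15-genotype verification rows: grade, seven traits, D and Y.

    Three genotypes per tolerance grade, with the D value computed from the
    full 14-trait assay and the Y value printed for the seven-trait model.
    """
    path = resources.files("salicore.data").joinpath("verification_panel.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")


_CONDITION_THRESHOLD = 1e8


def fit_tolerance_model(table: TraitTable, d: pd.Series | Sequence[float],
                        mode: Literal["fixed_predictors", "stepwise"] = "fixed_predictors",
                        predictors: Sequence[str] | None = None,
                        entry_p: float = 0.05) -> ToleranceModel:
    """Fit D on trait columns by OLS.

    ``fixed_predictors`` regresses D on a named subset (default: the seven
    reference predictors). ``stepwise`` builds the model by forward selection,
    at each step adding the candidate with the largest partial F, stopping
    when no candidate enters below ``entry_p``.
    """
    y = np.asarray(pd.Series(d, dtype=float))
    if len(table.data) != len(y):
        raise ValueError("table rows and D vector length differ")
    if mode == "fixed_predictors":
        chosen = list(predictors) if predictors is not None else list(REFERENCE_PREDICTORS)
        missing = [p for p in chosen if p not in table.data.columns]
        if missing:
            raise SchemaError(f"predictor(s) not in table: {missing}")
    elif mode == "stepwise":
        chosen = _forward_select(table.data, y, entry_p,
                                 candidates=list(predictors) if predictors else None)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if len(y) < len(chosen) + 2:
        raise UndefinedStatisticError("too few rows for the requested predictor count")

    x = sm.add_constant(table.data[chosen].to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(y, x).fit()
    cond = float(np.linalg.cond(x))
    diagnostics = {
        "r_squared": float(res.rsquared),
        "stderr": res.bse[1:].tolist(),
        "intercept_stderr": float(res.bse[0]),
        "t": res.tvalues[1:].tolist(),
        "p": res.pvalues[1:].tolist(),
        "condition_number": cond,
        "n": int(len(y)),
        "mode": mode,
    }
    if cond > _CONDITION_THRESHOLD:
        from .exceptions import CollinearityWarning

        diagnostics["collinearity_warning"] = True
        warnings.warn(f"design condition number {cond:.3g} exceeds {_CONDITION_THRESHOLD:.0e}",
                      CollinearityWarning, stacklevel=2)
    return ToleranceModel(float(res.params[0]), tuple(chosen),
                          np.asarray(res.params[1:], dtype=float), diagnostics)


def _forward_select(data: pd.DataFrame, y: np.ndarray, entry_p: float,
                    candidates: list[str] | None = None) -> list[str]:
    remaining = list(candidates) if candidates is not None else list(data.columns)
    chosen: list[str] = []
    while remaining and len(y) >= len(chosen) + 3:
        best_p, best_f, best_c = None, -np.inf, None
        for cand in remaining:
            x = sm.add_constant(data[chosen + [cand]].to_numpy(dtype=float),
                                has_constant="add")
            try:
                res = sm.OLS(y, x).fit()
            except np.linalg.LinAlgError:  # pragma: no cover - singular candidate
                continue
            t = res.tvalues[-1]
            f_partial = float(t * t)
            if f_partial > best_f:
                best_p, best_f, best_c = float(res.pvalues[-1]), f_partial, cand
        if best_c is None or best_p is None or best_p >= entry_p:
            break
        chosen.append(best_c)
        remaining.remove(best_c)
    return chosen


def predict_tolerance(model: ToleranceModel, traits: Mapping[str, float],
                      ) -> dict[str, float]:
    """Y = intercept + sum(beta_i * X_i); returns unrounded and 4-decimal values.

    Raises :class:`SchemaError` naming the first missing predictor.
    """
    missing = [p for p in model.predictors if p not in traits]
    if missing:
        raise SchemaError(f"missing predictor(s): {', '.join(missing)}")
    x = np.array([float(traits[p]) for p in model.predictors])
    y = float(model.intercept + model.coefficients @ x)
    return {"Y": y, "Y_rounded": round(y, 4)}
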