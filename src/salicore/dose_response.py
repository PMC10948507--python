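"""Salt-injury dose-response fitting and screening-concentration selection.

A pilot panel is grown across a ladder of NaCl concentrations; for each
growth trait the salt-injury index SII = 1 - stress/control is averaged over
pilot genotypes at each level and regressed linearly on concentration. The
concentration at which a trait's SII reaches 50% is solved from the fitted
line, and a screening level is recommended among the candidate ladder by
proximity to those per-trait 50%-injury concentrations, using the diversity
of the senescence score across genotypes as a tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDesignError, NoSolutionError, RecommendationUndefinedError


@dataclass
class DoseResponseFit:
    """Linear fit of mean SII on NaCl concentration (mM) for one trait."""

    trait_name: str
    intercept: float
    slope: float
    r_squared: float
    slope_stderr: float = float("nan")
    c_at_target: float = float("nan")
    target_sii: float = 0.5


def fit_sii_line(concentrations_mM: Sequence[float], mean_sii: Sequence[float],
                 trait_name: str = "", target_sii: float = 0.5) -> DoseResponseFit:
    """Ordinary least squares of mean SII on concentration.

    Requires at least two distinct concentrations. ``c_at_target`` is filled
    by inverting the line at ``target_sii`` (NaN when the slope is zero).
    """
    c = np.asarray(concentrations_mM, dtype=float)
    y = np.asarray(mean_sii, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentrations and mean SII must have equal length")
    if np.unique(c).size < 2:
        raise DegenerateDesignError("all concentrations identical; cannot fit a line")
    res = stats.linregress(c, y)
    fit = DoseResponseFit(
        trait_name=trait_name,
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        slope_stderr=float(res.stderr),
        target_sii=target_sii,
    )
    if fit.slope != 0.0:
        fit.c_at_target = concentration_at_sii(fit, target_sii)
    return fit


def concentration_at_sii(fit: DoseResponseFit, target_sii: float = 0.5) -> float:
    """Invert the fitted line: concentration producing the target injury level."""
    if fit.slope == 0.0:
        raise NoSolutionError("slope is zero; target SII is never reached")
    return (target_sii - fit.intercept) / fit.slope


def average_sii(per_genotype_sii: Mapping[str, Sequence[float]] | pd.DataFrame) -> np.ndarray:
    """Equal-weight genotype mean of per-genotype SII vectors (one value per level)."""
    if isinstance(per_genotype_sii, pd.DataFrame):
        return per_genotype_sii.to_numpy(dtype=float).mean(axis=0)
    arr = np.asarray([np.asarray(v, dtype=float) for v in per_genotype_sii.values()])
    return arr.mean(axis=0)


@dataclass
class Recommendation:
    """Chosen screening level plus the evidence it was chosen on."""

    recommended_mM: float
    c_at_target_by_trait: dict[str, float]
    mean_abs_distance_by_level: dict[float, float]
    sen_variance_by_level: dict[float, float] = field(default_factory=dict)
    tie_break_used: bool = False


def recommend_concentration(fits: Iterable[DoseResponseFit],
                            candidate_levels_mM: Sequence[float],
                            sen_by_level: Mapping[float, Sequence[float]] | None = None,
                            ) -> Recommendation:
    """Pick the candidate level closest to the per-trait 50%-injury concentrations.

    Primary criterion: minimal mean absolute distance between the candidate
    level and each fit's ``c_at_target``. Ties (within 1e-9 mM) are broken
    toward the level with the largest senescence-score variance, when
    ``sen_by_level`` is supplied; remaining ties go to the lower level.
    """
    candidates = list(dict.fromkeys(float(c) for c in candidate_levels_mM))
    if not candidates:
        raise RecommendationUndefinedError("no candidate levels supplied")
    targets = {f.trait_name or f"trait{i}": f.c_at_target
               for i, f in enumerate(fits) if np.isfinite(f.c_at_target)}
    if not targets:
        raise RecommendationUndefinedError("no fit has a finite target concentration")

    dist = {lvl: float(np.mean([abs(lvl - t) for t in targets.values()])) for lvl in candidates}
    sen_var = {}
    if sen_by_level is not None:
        sen_var = {float(lvl): float(np.var(np.asarray(v, dtype=float), ddof=1))
                   if len(v) > 1 else 0.0
                   for lvl, v in sen_by_level.items()}

    best_d = min(dist.values())
    tied = sorted(lvl for lvl, d in dist.items() if d <= best_d + 1e-9)
    tie_break = len(tied) > 1
    if tie_break and sen_var:
        tied.sort(key=lambda lvl: (-sen_var.get(lvl, 0.0), lvl))
    return Recommendation(
        recommended_mM=tied[0],
        c_at_target_by_trait=targets,
        mean_abs_distance_by_level=dist,
        sen_variance_by_level=sen_var,
        tie_break_used=tie_break,
    )


def load_dose_response(path) -> pd.DataFrame:
    """Read a dose-response CSV with columns trait, concentration_mM, mean_sii."""
    df = pd.read_csv(path, comment="#")
    required = {"trait", "concentration_mM", "mean_sii"}
    missing = required - set(df.columns)
    if missing:
        from .exceptions import SchemaError

        raise SchemaError(f"dose-response CSV missing column(s): {sorted(missing)}")
    return df


def fit_all(dose_table: pd.DataFrame, target_sii: float = 0.5) -> list[DoseResponseFit]:
    """One :func:`fit_sii_line` per trait in a long dose-response table."""
    return [
        fit_sii_line(sub["concentration_mM"], sub["mean_sii"], trait_name=str(trait),
                     target_sii=target_sii)
        for trait, sub in dose_table.groupby("trait", sort=False)
    ]
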