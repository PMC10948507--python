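"""Synthetic germplasm panels with the statistical structure of the real assay.

The default 14-trait specification reproduces the marginal moments (mean,
CV, observed min/max, skew sign) reported for a 318-genotype Miscanthus
seedling panel under 150 mM NaCl, together with the strongest published
trait correlations (e.g. SWC-RWC +0.73, Sen-SNC +0.66, Sen-RNIL -0.52).
Draws use a Gaussian copula: correlated standard normals are pushed through
skew-normal marginals matched to each trait's mean/CV/skew sign and
truncated to the observed range. Correlations not pinned by the
specification are zero before a nearest-PSD repair.

Additional generators plant known structure for recovery tests: raw
phenotype trials with known stress/control ratios, linear dose-response
tables, and cluster-separated panels for core-selection geometry checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SyntheticSpecError
from .traits import DEFAULT_DIRECTIONS, TRAIT_NAMES, RawPhenotypeRecord, TraitTable

#: Per-trait {mean, cv, min, max, skew_sign} targets for the default panel.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "RGR":   {"mean": 0.49,   "cv": 0.53, "min": 0.03,  "max": 1.77,   "skew_sign": 1},
    "RNIL":  {"mean": 0.47,   "cv": 0.33, "min": 0.00,  "max": 0.94,   "skew_sign": 1},
    "RLER":  {"mean": 0.61,   "cv": 0.28, "min": 0.19,  "max": 1.09,   "skew_sign": 1},
    "Sen":   {"mean": 6.33,   "cv": 0.16, "min": 3.67,  "max": 8.78,   "skew_sign": -1},
    "SWC":   {"mean": 15.57,  "cv": 0.29, "min": 4.37,  "max": 28.78,  "skew_sign": 1},
    "RWC":   {"mean": 11.10,  "cv": 0.32, "min": 3.57,  "max": 22.62,  "skew_sign": 1},
    "SNC":   {"mean": 126.00, "cv": 0.21, "min": 53.20, "max": 220.31, "skew_sign": 1},
    "RNC":   {"mean": 45.22,  "cv": 0.24, "min": 23.97, "max": 82.13,  "skew_sign": 1},
    "SN/RN": {"mean": 3.13,   "cv": 0.24, "min": 1.17,  "max": 5.68,   "skew_sign": 1},
    "SKC":   {"mean": 68.39,  "cv": 0.12, "min": 44.32, "max": 104.75, "skew_sign": 1},
    "RKC":   {"mean": 26.20,  "cv": 0.21, "min": 12.83, "max": 39.50,  "skew_sign": 1},
    "SK/RK": {"mean": 2.94,   "cv": 0.28, "min": 1.60,  "max": 6.03,   "skew_sign": 1},
    "SK/N":  {"mean": 0.59,   "cv": 0.26, "min": 0.33,  "max": 1.33,   "skew_sign": 1},
    "RK/N":  {"mean": 0.63,   "cv": 0.30, "min": 0.26,  "max": 1.22,   "skew_sign": 1},
}

#: Strong published trait correlations; unlisted pairs default to zero.
DEFAULT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("SWC", "RWC"): 0.73,
    ("Sen", "SNC"): 0.66,
    ("SN/RN", "SNC"): 0.58,
    ("SN/RN", "Sen"): 0.55,
    ("SN/RN", "RK/N"): 0.53,
    ("Sen", "SK/N"): -0.54,
    ("Sen", "RNIL"): -0.52,
    ("Sen", "RLER"): -0.45,
}


@dataclass
class SyntheticSpec:
    """Targets for a synthetic trait panel draw."""

    n_genotypes: int = 318
    marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()})
    correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    seed: int | None = None

    def __post_init__(self) -> None:
        for trait, m in self.marginals.items():
            if not m["min"] < m["max"]:
                raise SyntheticSpecError(f"trait {trait!r}: min must be < max")
            if m["cv"] <= 0:
                raise SyntheticSpecError(f"trait {trait!r}: CV must be positive")

    def correlation_matrix(self) -> np.ndarray:
        traits = list(self.marginals)
        idx = {t: i for i, t in enumerate(traits)}
        r = np.eye(len(traits))
        for (a, b), rho in self.correlations.items():
            if a in idx and b in idx:
                r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
        return nearest_psd(r)


def nearest_psd(corr: np.ndarray, tol: float = 0.35) -> np.ndarray:
    """Eigenvalue-clipped nearest positive semi-definite correlation matrix.

    Raises when the repair would move the matrix further (spectral shift)
    than ``tol``, which signals an inconsistent correlation specification.
    """
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() >= 0:
        return corr
    if -eigval.min() > tol:
        raise SyntheticSpecError(
            f"correlation spec too far from PSD (min eigenvalue {eigval.min():.3f})")
    warnings.warn("correlation matrix repaired to nearest PSD", UserWarning, stacklevel=2)
    clipped = np.clip(eigval, 1e-10, None)
    repaired = eigvec @ np.diag(clipped) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    return repaired / np.outer(d, d)


def _skewnorm_params(mean: float, sd: float, skew_sign: float,
                     shape: float = 4.0) -> tuple[float, float, float]:
    # Solve (loc, scale) so the untruncated skew-normal hits the target moments.
    a = shape * (1 if skew_sign >= 0 else -1)
    delta = a / np.sqrt(1 + a * a)
    scale = sd / np.sqrt(1 - 2 * delta * delta / np.pi)
    loc = mean - scale * delta * np.sqrt(2 / np.pi)
    return a, loc, scale


def simulate_trait_table(spec: SyntheticSpec | None = None,
                         seed: int | None = None) -> TraitTable:
    """Draw a genotype x trait panel from the Gaussian-copula model.

    Deterministic for a given (spec, seed); ``seed`` overrides ``spec.seed``
    when given. Every value respects the spec's [min, max] truncation.
    """
    spec = spec if spec is not None else SyntheticSpec()
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    traits = list(spec.marginals)
    corr = spec.correlation_matrix()
    z = rng.multivariate_normal(np.zeros(len(traits)), corr, size=spec.n_genotypes,
                                method="cholesky")
    u = stats.norm.cdf(z)

    data = {}
    for j, trait in enumerate(traits):
        m = spec.marginals[trait]
        a, loc, scale = _skewnorm_params(m["mean"], m["cv"] * m["mean"], m["skew_sign"])
        dist = stats.skewnorm(a, loc=loc, scale=scale)
        lo, hi = dist.cdf(m["min"]), dist.cdf(m["max"])
        data[trait] = dist.ppf(lo + u[:, j] * (hi - lo))
    df = pd.DataFrame(data, index=[f"G{i + 1:03d}" for i in range(spec.n_genotypes)])
    df.index.name = "genotype_id"
    directions = {t: DEFAULT_DIRECTIONS.get(t, "positive") for t in traits}
    return TraitTable(df, directions)


def simulate_raw_trial(n_genotypes: int = 10,
                       effect_profile: Mapping[str, Mapping[str, float]] | None = None,
                       seed: int | None = None,
                       replicates: int = 3,
                       noise: float = 0.05) -> list[RawPhenotypeRecord]:
    """Raw control/stress records with known true stress/control growth ratios.

    ``effect_profile`` maps genotype id -> {"RGR": sti, "RNIL": sti,
    "RLER": sti}; when omitted, ratios are drawn around the panel means.
    Replicate noise is multiplicative on each replicate's growth rate, so at
    ``noise=0`` the assembled ratios equal the planted ones exactly. Planted
    ratios must lie in (0, 1.8] (indices up to 1.77 occur in real panels).
    """
    rng = np.random.default_rng(seed)
    if effect_profile is None:
        effect_profile = {
            f"G{i + 1:03d}": {
                "RGR": float(np.clip(rng.normal(0.49, 0.2), 0.05, 1.77)),
                "RNIL": float(np.clip(rng.normal(0.47, 0.15), 0.05, 0.94)),
                "RLER": float(np.clip(rng.normal(0.61, 0.17), 0.19, 1.09)),
            }
            for i in range(n_genotypes)
        }
    for gid, profile in effect_profile.items():
        for trait, sti in profile.items():
            if not 0 < sti <= 1.8:
                raise SyntheticSpecError(
                    f"genotype {gid}: planted {trait} STI {sti} outside (0, 1.8]")

    records: list[RawPhenotypeRecord] = []
    for gid, profile in effect_profile.items():
        gr_ck = float(rng.uniform(0.2, 0.8))
        nil_ck = float(rng.uniform(1.5, 3.0))
        ler_ck = float(rng.uniform(0.8, 1.8))
        h2 = float(rng.uniform(8, 20))
        leaves1 = float(rng.integers(3, 7))
        l2 = float(rng.uniform(3, 8))
        for treatment in ("control", "stress"):
            scale = {"GR": 1.0, "NIL": 1.0, "LER": 1.0} if treatment == "control" else {
                "GR": profile["RGR"], "NIL": profile["RNIL"], "LER": profile["RLER"]}
            for rep in range(1, replicates + 1):
                eps = rng.normal(0.0, noise, size=3) if noise > 0 else np.zeros(3)
                gr = gr_ck * scale["GR"] * (1 + eps[0])
                nil = nil_ck * scale["NIL"] * (1 + eps[1])
                ler = ler_ck * scale["LER"] * (1 + eps[2])
                fresh_s = float(rng.uniform(2, 6))
                fresh_r = float(rng.uniform(1, 3))
                rec = RawPhenotypeRecord(
                    genotype_id=gid, treatment=treatment, replicate=rep,
                    height_cm_at_das={2: h2, 7: h2 + 5 * gr, 17: h2 + 15 * gr},
                    leaf_count_at_das={1: leaves1, 17: leaves1 + nil},
                    marked_leaf_length_cm_at_das={2: l2, 7: l2 + 5 * ler, 12: l2 + 10 * ler},
                    shoot_fresh_g=fresh_s, shoot_dry_g=fresh_s * 0.85,
                    root_fresh_g=fresh_r, root_dry_g=fresh_r * 0.89,
                )
                if treatment == "stress":
                    rec.senescence_score = float(np.clip(rng.normal(6.3, 1.0), 1, 9))
                    rec.shoot_na_mg_g = float(rng.uniform(53, 220))
                    rec.root_na_mg_g = float(rng.uniform(24, 82))
                    rec.shoot_k_mg_g = float(rng.uniform(44, 105))
                    rec.root_k_mg_g = float(rng.uniform(13, 40))
                records.append(rec)
    return records


def simulate_dose_response(intercept: float, slope: float,
                           concentrations: Sequence[float] = (0, 100, 150, 200, 250),
                           noise_sd: float = 0.0, seed: int | None = None,
                           trait: str = "NIL") -> pd.DataFrame:
    """Mean-SII dose-response table from a planted line, clipped to [0, 1]."""
    if noise_sd < 0:
        raise SyntheticSpecError("noise_sd must be non-negative")
    if slope <= 0:
        raise SyntheticSpecError("an injury curve needs a positive slope")
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, dtype=float)
    sii = intercept + slope * c
    if noise_sd > 0:
        sii = sii + rng.normal(0.0, noise_sd, size=c.size)
    return pd.DataFrame({"trait": trait, "concentration_mM": c,
                         "mean_sii": np.clip(sii, 0.0, 1.0)})


def simulate_clustered_panel(n_clusters: int = 3, per_cluster: int = 5,
                             separation: float = 0.5, seed: int | None = None,
                             n_traits: int = 14) -> TraitTable:
    """Panel whose genotypes form well-separated clusters in Gower space.

    Cluster centroids sit at equal spacings along every trait axis so their
    pairwise Gower distance is at least ``separation``; within-cluster spread
    is bounded by ``separation / 4``. Raises when the requested separation
    cannot be packed into the unit Gower range.
    """
    if separation <= 0:
        raise SyntheticSpecError("separation must be positive")
    rng = np.random.default_rng(seed)
    if n_clusters > 1:
        # Gower divides by each trait's observed range, so raw jitter shrinks
        # the normalized centroid spacing 1/((c-1) + 2*gamma). gamma is capped
        # so centroids stay >= separation apart and within-cluster spread
        # stays <= separation/4 after normalization.
        gamma = min((1.0 / separation - (n_clusters - 1)) / 2.0,
                    separation * (n_clusters - 1) / 10.0)
        if gamma < 0:
            raise SyntheticSpecError(
                f"cannot place {n_clusters} centroids {separation} apart within unit range")
        centers = np.arange(n_clusters, dtype=float)
        spread = gamma
    else:
        centers = np.array([0.5])
        spread = separation / 8.0
    rows, ids = [], []
    for k, center in enumerate(centers):
        for i in range(per_cluster):
            rows.append(center + rng.uniform(-spread, spread, size=n_traits))
            ids.append(f"C{k + 1}_{i + 1}")
    names = list(TRAIT_NAMES[:n_traits]) if n_traits <= len(TRAIT_NAMES) else [
        f"T{j + 1}" for j in range(n_traits)]
    df = pd.DataFrame(np.asarray(rows), index=ids, columns=names)
    df.index.name = "genotype_id"
    directions = {t: DEFAULT_DIRECTIONS.get(t, "positive") for t in names}
    return TraitTable(df, directions)
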