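"""Flux/metabolite-to-trait layer: all-subsets multiple linear regression
selected by the corrected Akaike information criterion (AICc).

Features are the 37 steady-state fluxes (V1..V37) and 24 metabolite
concentrations (M1..M24) per line, rounded to five decimal places before
selection so that near-zero features cannot be rescued by huge coefficients.
Predictors with pairwise |Pearson r| above 0.95 are pruned (keep-first in
canonical flux-then-metabolite order); an exhaustive search over predictor
subsets up to ``max_terms`` then minimises AICc per trait.  Predictions are
clamped to be non-negative, and percentage-valued traits to at most 100.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trait",
    "TRAITS",
    "TRAIT_NAMES",
    "is_percentage",
    "FEATURE_DECIMALS",
    "round_features",
    "feature_columns",
    "collinearity_filter",
    "aicc",
    "all_subsets_select",
    "TraitModel",
    "TraitModelSet",
    "predict_traits",
    "clamp_prediction",
    "SelectionError",
]

FEATURE_DECIMALS = 5
DEFAULT_MAX_TERMS = 5
COLLINEARITY_THRESHOLD = 0.95


@dataclass(frozen=True)
class Trait:
    name: str
    unit: str
    is_percentage: bool


#: The 25 lignin and wood properties modelled.
TRAITS: tuple[Trait, ...] = (
    Trait("lignin_content", "%", True),
    Trait("s_g_ratio", "ratio", False),
    Trait("s_subunits", "%", True),
    Trait("g_subunits", "%", True),
    Trait("h_subunits", "%", True),
    Trait("p_hydroxybenzoic_acid", "%", True),
    Trait("c_l_ratio", "ratio", False),
    Trait("aldehyde_content", "%", True),
    Trait("beta_O_4", "%", True),
    Trait("beta_5", "%", True),
    Trait("beta_beta", "%", True),
    Trait("beta_1", "%", True),
    Trait("cinnamyl_alcohol_endgroups", "%", True),
    Trait("height", "cm", False),
    Trait("diameter", "mm", False),
    Trait("stem_volume", "cm3", False),
    Trait("glucose", "%", True),
    Trait("xylose", "%", True),
    Trait("total_carbohydrates", "%", True),
    Trait("relative_density", "dimensionless", False),
    Trait("moe", "MPa", False),
    Trait("sacch_glucose_unpretreated", "%", True),
    Trait("sacch_xylose_unpretreated", "%", True),
    Trait("sacch_glucose_pretreated", "%", True),
    Trait("sacch_xylose_pretreated", "%", True),
)

TRAIT_NAMES = tuple(t.name for t in TRAITS)
_TRAIT_BY_NAME = {t.name: t for t in TRAITS}


def is_percentage(trait: str) -> bool:
    return _TRAIT_BY_NAME[trait].is_percentage


def feature_columns(n_fluxes: int = 37, n_metabolites: int = 24) -> list[str]:
    """Canonical feature order: fluxes first, then metabolites."""
    return [f"V{i}" for i in range(1, n_fluxes + 1)] + [
        f"M{i}" for i in range(1, n_metabolites + 1)
    ]


def round_features(features: pd.DataFrame, decimals: int = FEATURE_DECIMALS) -> pd.DataFrame:
    return features.round(decimals)


class SelectionError(RuntimeError):
    pass


def collinearity_filter(
    features: pd.DataFrame, threshold: float = COLLINEARITY_THRESHOLD
) -> list[str]:
    """Greedy keep-first pruning of collinear predictors.

    Scans columns in their given (canonical) order; a column is dropped when
    its |Pearson r| with any already-retained column exceeds ``threshold``.
    Zero-variance columns are dropped with a warning.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 rows to assess collinearity")
    X = features.to_numpy(float)
    cols = list(features.columns)
    sd = X.std(axis=0, ddof=0)
    retained: list[int] = []
    dropped_const: list[str] = []
    Z = np.zeros_like(X)
    nz = sd > 0
    Z[:, nz] = (X[:, nz] - X[:, nz].mean(axis=0)) / sd[:, None].T[:, nz]
    n = len(features)
    for j, col in enumerate(cols):
        if not nz[j]:
            dropped_const.append(col)
            continue
        ok = True
        for k in retained:
            r = float(np.dot(Z[:, j], Z[:, k])) / n
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            retained.append(j)
    if dropped_const:
        warnings.warn(f"dropped zero-variance feature(s): {dropped_const}")
    return [cols[j] for j in retained]


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected AIC: n ln(rss/n) + 2k + 2k(k+1)/(n-k-1).

    ``k`` counts all estimated mean parameters including the intercept.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    if rss <= 0:
        raise ValueError("rss must be > 0")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class TraitModel:
    """AICc-selected linear model for one trait."""

    trait: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]
    aicc: float
    adjusted_r_squared: float
    max_terms: int
    clamp_percentage: bool

    def predict_raw(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictors if c not in features.columns]
        if missing:
            raise KeyError(f"trait {self.trait}: missing feature column(s) {missing}")
        X = features[list(self.predictors)].to_numpy(float)
        return self.intercept + X @ np.asarray(self.coefficients)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return clamp_prediction(self.predict_raw(features), self.clamp_percentage)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "predictors": list(self.predictors),
            "intercept": self.intercept,
            "coefficients": list(self.coefficients),
            "aicc": self.aicc,
            "adjusted_r_squared": self.adjusted_r_squared,
            "max_terms": self.max_terms,
            "clamp_percentage": self.clamp_percentage,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TraitModel":
        return cls(
            trait=d["trait"],
            predictors=tuple(d["predictors"]),
            intercept=float(d["intercept"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            aicc=float(d["aicc"]),
            adjusted_r_squared=float(d["adjusted_r_squared"]),
            max_terms=int(d["max_terms"]),
            clamp_percentage=bool(d["clamp_percentage"]),
        )


@dataclass
class TraitModelSet:
    models: dict[str, TraitModel]

    def __getitem__(self, trait: str) -> TraitModel:
        return self.models[trait]

    def __iter__(self):
        return iter(self.models.values())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({t: m.to_dict() for t, m in self.models.items()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TraitModelSet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls({t: TraitModel.from_dict(d) for t, d in doc.items()})


def clamp_prediction(values: np.ndarray | float, percentage: bool) -> np.ndarray | float:
    clipped = np.clip(values, 0.0, 100.0 if percentage else np.inf)
    if np.isscalar(values):
        return float(clipped)
    return clipped


def _rss_floor(syy: float, n: int) -> float:
    # keeps AICc finite on exactly-fitting (noise-free) data; ties then fall
    # to the smaller subset via the enumeration order
    return max(syy, 1.0) * 1e-16 + 1e-300


def all_subsets_select(
    features: pd.DataFrame,
    y: pd.Series | np.ndarray,
    trait: str | None = None,
    max_terms: int = DEFAULT_MAX_TERMS,
) -> TraitModel:
    """Exhaustive best-subset search minimising AICc.

    Evaluates every predictor subset of size 0..max_terms (intercept always
    included) and returns the global minimum.  Ties are broken toward the
    smaller subset, then lexicographically by column order, by enumerating
    sizes in ascending order and requiring a strict improvement to switch.
    """
    cols = list(features.columns)
    n = len(features)
    if n <= max_terms + 2:
        raise SelectionError(
            f"need more rows ({n}) than max_terms + 2 ({max_terms + 2})"
        )
    yv = np.asarray(y, float)
    X = features.to_numpy(float)
    A = np.column_stack([np.ones(n), X])
    G = A.T @ A
    b = A.T @ yv
    syy = float(yv @ yv)
    floor = _rss_floor(syy, n)

    best: tuple[float, tuple[int, ...], np.ndarray, float] | None = None
    p = len(cols)
    for k in range(0, min(max_terms, p) + 1):
        combos = list(itertools.combinations(range(p), k))
        idx = np.array([(0,) + tuple(c + 1 for c in combo) for combo in combos])
        Gs = G[idx[:, :, None], idx[:, None, :]]
        bs = b[idx]
        try:
            beta = np.linalg.solve(Gs, bs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.full_like(bs, np.nan)
            for i in range(len(combos)):
                try:
                    beta[i] = np.linalg.solve(Gs[i], bs[i])
                except np.linalg.LinAlgError:
                    pass
        rss = syy - np.einsum("ij,ij->i", beta, bs)
        # Gram-based RSS loses ~eps*syy*cond to cancellation; recompute
        # near-perfect fits from explicit residuals so exact fits tie at the
        # floor and the subset-size tie-break can act
        near = np.where(np.isfinite(rss) & (rss < max(syy, 1.0) * 1e-7))[0]
        for i in near:
            resid = yv - A[:, idx[i]] @ beta[i]
            rss[i] = float(resid @ resid)
        rss = np.where(np.isfinite(rss), np.maximum(rss, floor), np.nan)
        kk = k + 1  # parameters incl. intercept
        if n <= kk + 1:
            continue
        scores = n * np.log(rss / n) + 2 * kk + 2 * kk * (kk + 1) / (n - kk - 1)
        for i, combo in enumerate(combos):
            s = scores[i]
            if not np.isfinite(s):
                continue
            if best is None or s < best[0] - 1e-12:
                best = (float(s), combo, beta[i].copy(), float(rss[i]))
    if best is None:
        raise SelectionError("no valid subset: all candidate fits are degenerate")
    score, combo, beta, rss = best
    k = len(combo)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss > 0 and n - k - 1 > 0:
        adj_r2 = 1.0 - (rss / (n - k - 1)) / (tss / (n - 1))
    else:
        adj_r2 = 1.0
    trait_name = trait if trait is not None else "trait"
    pct = is_percentage(trait_name) if trait_name in _TRAIT_BY_NAME else False
    return TraitModel(
        trait=trait_name,
        predictors=tuple(cols[j] for j in combo),
        intercept=float(beta[0]),
        coefficients=tuple(float(v) for v in beta[1:]),
        aicc=score,
        adjusted_r_squared=float(min(adj_r2, 1.0)),
        max_terms=max_terms,
        clamp_percentage=pct,
    )


def predict_traits(
    models: TraitModelSet, features: pd.DataFrame
) -> pd.DataFrame:
    """Clamped trait predictions, lines x traits."""
    out = {}
    for m in models:
        out[m.trait] = m.predict(features)
    return pd.DataFrame(out, index=features.index)
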