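"""End-to-end integrative analysis: transcripts -> proteins -> pathway steady
state -> lignin and wood traits, with full re-estimating k-fold
cross-validation.

The fitted pipeline holds the per-gene translation coefficients (beta_i), a
fixed kinetic parameter registry, the calibrated phenylalanine input, and
the AICc-selected trait regressions.  Kinetic parameters are never
re-estimated; only the translation and trait-regression layers are fitted
from data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics import calibrate_phenylalanine, solve_steady_state
from .pathway import KineticParameterSet, PathwayDefinition
from .traits import (
    COLLINEARITY_THRESHOLD,
    DEFAULT_MAX_TERMS,
    TRAIT_NAMES,
    TraitModelSet,
    all_subsets_select,
    collinearity_filter,
    feature_columns,
    predict_traits,
    round_features,
)
from .translation import (
    TranslationModel,
    fit_translation_model,
    predict_protein,
    to_wide,
)

__all__ = [
    "FittedPipeline",
    "CVReport",
    "compute_features",
    "fit_full",
    "run_forward",
    "cross_validate",
    "PipelineError",
]

log = logging.getLogger(__name__)

DEFAULT_TARGET_SG = 2.16
MIN_LINES = 10


class PipelineError(ValueError):
    pass


def compute_features(
    pathway: PathwayDefinition,
    params: KineticParameterSet,
    proteins_wide: pd.DataFrame,
    phe: float,
    **solve_kw,
) -> tuple[pd.DataFrame, pd.Series]:
    """Steady-state feature matrix (fluxes + metabolite concentrations).

    Returns (features, converged flags); features rows for non-converged
    lines are still reported but should be excluded from fitting.
    """
    rows = {}
    conv = {}
    for line_id, row in proteins_wide.iterrows():
        ss = solve_steady_state(pathway, params, row.to_dict(), phe, **solve_kw)
        rows[line_id] = ss.feature_vector()
        conv[line_id] = ss.converged
    feats = pd.DataFrame.from_dict(rows, orient="index")
    feats = feats[feature_columns(len(pathway.reactions), len(pathway.metabolites))]
    feats.index.name = "line_id"
    return feats, pd.Series(conv, name="converged")


@dataclass
class FittedPipeline:
    """All fitted components of the integrative analysis."""

    pathway: PathwayDefinition
    kinetics: KineticParameterSet
    translation: TranslationModel
    phenylalanine: float
    trait_models: TraitModelSet
    retained_features: tuple[str, ...]
    wt_transcripts: dict[str, float]
    wt_traits: dict[str, float]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.phenylalanine > 0:
            raise PipelineError("calibrated phenylalanine must be > 0")

    def config_hash(self) -> str:
        payload = json.dumps(
            {"phe": self.phenylalanine, "config": self.config,
             "betas": self.translation.to_dict()},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_forward(
    transcripts: pd.DataFrame | Mapping[str, float],
    pipeline: FittedPipeline,
    **solve_kw,
) -> tuple[pd.DataFrame, pd.Series]:
    """Predict the 25 traits per line from transcript abundances alone.

    Returns (traits lines x 25, converged flags).  Trait values for
    non-converged lines are NaN.
    """
    proteins = predict_protein(transcripts, pipeline.translation)
    feats, conv = compute_features(
        pipeline.pathway, pipeline.kinetics, proteins, pipeline.phenylalanine,
        **solve_kw,
    )
    feats = round_features(feats)
    preds = predict_traits(pipeline.trait_models, feats)
    preds[~conv.reindex(preds.index).fillna(False)] = np.nan
    return preds, conv


def _check_alignment(
    transcripts: pd.DataFrame, proteins: pd.DataFrame, traits: pd.DataFrame
) -> list:
    for name, df in (("transcripts", transcripts), ("proteins", proteins)):
        dup = df.duplicated(subset=["line_id", "gene_id"])
        if dup.any():
            raise PipelineError(
                f"duplicate (line_id, gene_id) rows in {name}: "
                f"{df.loc[dup, 'line_id'].unique().tolist()[:5]}"
            )
    if traits.index.duplicated().any():
        dup_ids = traits.index[traits.index.duplicated()].unique().tolist()
        raise PipelineError(f"duplicate line id(s) in traits: {dup_ids}")
    t_lines = set(transcripts["line_id"])
    p_lines = set(proteins["line_id"])
    y_lines = set(traits.index)
    common = t_lines & p_lines & y_lines
    orphans = (t_lines | p_lines | y_lines) - common
    if orphans:
        raise PipelineError(f"line id(s) not present in all tables: {sorted(orphans, key=str)[:10]}")
    return sorted(common, key=str)


def fit_full(
    transcripts: pd.DataFrame,
    proteins: pd.DataFrame,
    traits: pd.DataFrame,
    pathway: PathwayDefinition,
    params: KineticParameterSet,
    target_sg: float = DEFAULT_TARGET_SG,
    max_terms: int = DEFAULT_MAX_TERMS,
    collinearity_threshold: float = COLLINEARITY_THRESHOLD,
    phe: float | None = None,
    **solve_kw,
) -> FittedPipeline:
    """Fit the full pipeline from aligned transcript, protein and trait tables.

    ``traits`` is a wide table indexed by line_id with one column per trait.
    Phenylalanine is calibrated on the wildtype-mean transcript profile so
    that the wildtype S/G flux ratio matches ``target_sg`` (skipped when an
    explicit ``phe`` is given).
    """
    lines = _check_alignment(transcripts, proteins, traits)
    if len(lines) < MIN_LINES:
        raise PipelineError(
            f"refusing to fit on {len(lines)} lines (<{MIN_LINES}): "
            "subset selection is unstable"
        )
    translation = fit_translation_model(transcripts, proteins)

    wt = transcripts[transcripts["genotype"] == "wildtype"]
    if wt.empty:
        raise PipelineError("no wildtype lines: cannot calibrate phenylalanine")
    wt_transcripts = wt.groupby("gene_id")["value"].mean().to_dict()
    wt_proteins = predict_protein(wt_transcripts, translation).iloc[0].to_dict()
    if phe is None:
        phe = calibrate_phenylalanine(pathway, params, wt_proteins, target_sg)

    pred_proteins = predict_protein(transcripts, translation).loc[lines]
    feats, conv = compute_features(pathway, params, pred_proteins, phe, **solve_kw)
    feats = round_features(feats)
    n_bad = int((~conv).sum())
    if n_bad:
        log.warning("excluding %d non-converged line(s) from trait regression", n_bad)
    good = conv[conv].index
    retained = collinearity_filter(feats.loc[good], collinearity_threshold)

    trait_cols = [c for c in traits.columns if c in TRAIT_NAMES]
    models = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for trait in trait_cols:
            y = traits.loc[good, trait].astype(float)
            models[trait] = all_subsets_select(
                feats.loc[good, retained], y, trait=trait, max_terms=max_terms
            )
    model_set = TraitModelSet(models)

    wt_feats, _ = compute_features(
        pathway, params,
        predict_protein(wt_transcripts, translation), phe, **solve_kw,
    )
    wt_traits = predict_traits(model_set, round_features(wt_feats)).iloc[0].to_dict()

    return FittedPipeline(
        pathway=pathway,
        kinetics=params,
        translation=translation,
        phenylalanine=float(phe),
        trait_models=model_set,
        retained_features=tuple(retained),
        wt_transcripts=dict(wt_transcripts),
        wt_traits=wt_traits,
        config={"target_sg": target_sg, "max_terms": max_terms,
                "collinearity_threshold": collinearity_threshold},
    )


@dataclass
class CVReport:
    """k-fold cross-validation summary with full per-fold re-estimation."""

    fold_assignment: pd.Series           # line_id -> fold index
    train_r2: pd.DataFrame               # folds x traits, adjusted R² (train)
    validation_r2: pd.DataFrame          # folds x traits, adjusted R² (validation)
    bias: pd.DataFrame                   # folds x traits, mean(pred / measured)
    seed: int

    @property
    def fold_sizes(self) -> list[int]:
        return self.fold_assignment.value_counts().sort_index().tolist()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "train_adj_r2": self.train_r2.mean(),
            "validation_adj_r2": self.validation_r2.mean(),
            "bias": self.bias.mean(),
        })

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "fold_sizes": self.fold_sizes,
            "fold_assignment": {str(k): int(v) for k, v in
                                self.fold_assignment.items()},
            "train_adj_r2": self.train_r2.to_dict(),
            "validation_adj_r2": self.validation_r2.to_dict(),
            "bias": self.bias.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _adjusted_r2(y: np.ndarray, yhat: np.ndarray, k: int) -> float:
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum((y - yhat) ** 2))
    if tss <= 0 or n - k - 1 <= 0:
        return np.nan
    return 1.0 - (rss / (n - k - 1)) / (tss / (n - 1))


def cross_validate(
    transcripts: pd.DataFrame,
    proteins: pd.DataFrame,
    traits: pd.DataFrame,
    pathway: PathwayDefinition,
    params: KineticParameterSet,
    n_folds: int = 5,
    seed: int = 0,
    target_sg: float = DEFAULT_TARGET_SG,
    recalibrate_phe: bool = False,
    max_terms: int = DEFAULT_MAX_TERMS,
    **fit_kw,
) -> CVReport:
    """Randomly partition lines into ``n_folds`` near-equal folds; per fold,
    re-fit every free parameter (beta_i and trait regressions) on the
    training lines and evaluate on the held-out lines.

    Phenylalanine is calibrated once on the full data by default; per-fold
    recalibration is available via ``recalibrate_phe``.  A fold whose
    training split has no wildtype lines falls back to the full-data
    calibration with a warning.
    """
    lines = _check_alignment(transcripts, proteins, traits)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(lines) < n_folds:
        raise ValueError("fewer lines than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(lines))
    folds = np.zeros(len(lines), dtype=int)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        folds[chunk] = f
    assignment = pd.Series(folds, index=pd.Index(lines, name="line_id"), name="fold")

    # one calibration on the full data, reused per fold unless re-calibrating
    full_translation = fit_translation_model(transcripts, proteins)
    wt = transcripts[transcripts["genotype"] == "wildtype"]
    if wt.empty:
        raise PipelineError("no wildtype lines: cannot calibrate phenylalanine")
    wt_proteins = predict_protein(
        wt.groupby("gene_id")["value"].mean().to_dict(), full_translation
    ).iloc[0].to_dict()
    phe_full = calibrate_phenylalanine(pathway, params, wt_proteins, target_sg)

    train_rows, val_rows, bias_rows = [], [], []
    for f in range(n_folds):
        val_lines = [l for l, ff in zip(lines, folds) if ff == f]
        tr_lines = [l for l, ff in zip(lines, folds) if ff != f]
        tr_mask_t = transcripts["line_id"].isin(tr_lines)
        tr_mask_p = proteins["line_id"].isin(tr_lines)
        has_wt = (transcripts.loc[tr_mask_t, "genotype"] == "wildtype").any()
        if not has_wt:
            warnings.warn(
                f"fold {f}: no wildtype lines in training split; using "
                "full-data phenylalanine calibration"
            )
        phe_arg = None if (recalibrate_phe and has_wt) else phe_full
        fold_fit = fit_full(
            transcripts[tr_mask_t], proteins[tr_mask_p], traits.loc[tr_lines],
            pathway, params, target_sg=target_sg, max_terms=max_terms,
            phe=phe_arg, **fit_kw,
        )
        pred_tr, _ = run_forward(transcripts[tr_mask_t], fold_fit)
        pred_va, _ = run_forward(
            transcripts[transcripts["line_id"].isin(val_lines)], fold_fit
        )
        tr_r2, va_r2, bias = {}, {}, {}
        for m in fold_fit.trait_models:
            t = m.trait
            k = len(m.predictors)
            ytr = traits.loc[pred_tr.index, t].to_numpy(float)
            yva = traits.loc[pred_va.index, t].to_numpy(float)
            ok_tr = np.isfinite(pred_tr[t].to_numpy(float))
            ok_va = np.isfinite(pred_va[t].to_numpy(float))
            tr_r2[t] = _adjusted_r2(ytr[ok_tr], pred_tr[t].to_numpy(float)[ok_tr], k)
            va_r2[t] = _adjusted_r2(yva[ok_va], pred_va[t].to_numpy(float)[ok_va], k)
            pos = ok_va & (yva > 0)
            bias[t] = float(np.mean(pred_va[t].to_numpy(float)[pos] / yva[pos])) \
                if pos.any() else np.nan
        train_rows.append(tr_r2)
        val_rows.append(va_r2)
        bias_rows.append(bias)

    idx = pd.RangeIndex(n_folds, name="fold")
    return CVReport(
        fold_assignment=assignment,
        train_r2=pd.DataFrame(train_rows, index=idx),
        validation_r2=pd.DataFrame(val_rows, index=idx),
        bias=pd.DataFrame(bias_rows, index=idx),
        seed=seed,
    )
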