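"""Transcript-to-protein layer: batch normalization and the per-gene
zero-intercept linear maps (beta_i values).

Omics tables are tidy DataFrames with columns
``line_id, batch, genotype, gene_id, value`` (value in µM, or relative to
wildtype after :func:`normalize_to_batch_wildtype`).  Each gene gets a simple
regression through the origin, protein = beta * transcript, so that zero
transcript implies zero protein.  The goodness of fit is the uncentered
(through-origin) coefficient of determination R² = 1 - RSS / sum(y²); the
centered convention is not valid without an intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationError",
    "TranslationError",
    "GeneTranslation",
    "TranslationModel",
    "normalize_to_batch_wildtype",
    "fit_translation_model",
    "predict_protein",
    "to_wide",
]

OMICS_COLUMNS = ("line_id", "batch", "genotype", "gene_id", "value")


class NormalizationError(ValueError):
    pass


class TranslationError(ValueError):
    pass


def _check_columns(df: pd.DataFrame) -> None:
    missing = [c for c in OMICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"omics table missing column(s): {missing}")


def to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy omics table to lines x genes (values µM)."""
    _check_columns(df)
    return df.pivot_table(index="line_id", columns="gene_id", values="value",
                          aggfunc="mean")


def normalize_to_batch_wildtype(profiles: pd.DataFrame) -> pd.DataFrame:
    """Divide every value by its batch's wildtype mean for the same gene.

    Works for transcript and protein tables alike.  Raises
    :class:`NormalizationError` naming any batch without a wildtype replicate.
    """
    _check_columns(profiles)
    wt = profiles[profiles["genotype"] == "wildtype"]
    have_wt = set(wt["batch"].unique())
    missing = sorted(set(profiles["batch"].unique()) - have_wt, key=str)
    if missing:
        raise NormalizationError(
            f"batch(es) without wildtype replicates: {missing}"
        )
    ref = wt.groupby(["batch", "gene_id"])["value"].mean().rename("wt_mean")
    out = profiles.merge(ref, on=["batch", "gene_id"], how="left")
    zero = out["wt_mean"] == 0
    if zero.any():
        genes = sorted(out.loc[zero, "gene_id"].unique())
        raise NormalizationError(f"zero wildtype mean for gene(s): {genes}")
    out["value"] = out["value"] / out["wt_mean"]
    return out.drop(columns="wt_mean")


@dataclass(frozen=True)
class GeneTranslation:
    beta: float          # protein µM per transcript µM
    r_squared: float     # through-origin (uncentered)
    n_observations: int


@dataclass
class TranslationModel:
    """Per-gene translation coefficients beta_i."""

    genes: dict[str, GeneTranslation]

    def __getitem__(self, gene: str) -> GeneTranslation:
        return self.genes[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def betas(self) -> dict[str, float]:
        return {g: t.beta for g, t in self.genes.items()}

    def to_dict(self) -> dict:
        return {
            g: {"beta": t.beta, "r_squared": t.r_squared, "n": t.n_observations}
            for g, t in self.genes.items()
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "TranslationModel":
        return cls({
            g: GeneTranslation(float(d["beta"]), float(d["r_squared"]), int(d["n"]))
            for g, d in doc.items()
        })

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TranslationModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_origin(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise TranslationError("all-zero transcript vector: slope undefined")
    beta = float(np.dot(x, y)) / sxx
    syy = float(np.dot(y, y))
    rss = float(np.sum((y - beta * x) ** 2))
    r2 = 1.0 - rss / syy if syy > 0 else 1.0
    return beta, r2


def fit_translation_model(
    transcripts: pd.DataFrame,
    proteins: pd.DataFrame,
    genes: Iterable[str] | None = None,
    merge: Iterable[tuple[str, ...]] = (),
) -> TranslationModel:
    """Fit one through-origin regression per gene on paired observations.

    Observations are paired by (line_id, gene_id); a gene needs at least two
    pairs with a non-zero transcript vector.  Genes grouped in ``merge`` are
    pooled into a single regression and share the resulting beta.
    """
    _check_columns(transcripts)
    _check_columns(proteins)
    tx = transcripts.rename(columns={"value": "x"})[["line_id", "gene_id", "x"]]
    pr = proteins.rename(columns={"value": "y"})[["line_id", "gene_id", "y"]]
    paired = tx.merge(pr, on=["line_id", "gene_id"])
    wanted = list(genes) if genes is not None else sorted(paired["gene_id"].unique())
    group_of = {}
    for group in merge:
        for g in group:
            group_of[g] = tuple(group)
    out: dict[str, GeneTranslation] = {}
    for gene in wanted:
        members = group_of.get(gene, (gene,))
        sub = paired[paired["gene_id"].isin(members)]
        if len(sub) < 2:
            raise TranslationError(
                f"gene {gene}: need >=2 paired observations, have {len(sub)}"
            )
        x = sub["x"].to_numpy(float)
        y = sub["y"].to_numpy(float)
        try:
            beta, r2 = _fit_origin(x, y)
        except TranslationError as exc:
            raise TranslationError(f"gene {gene}: {exc}") from exc
        out[gene] = GeneTranslation(beta, r2, len(sub))
    return TranslationModel(out)


def predict_protein(
    transcripts: pd.DataFrame | Mapping[str, float],
    model: TranslationModel,
) -> pd.DataFrame:
    """Predicted protein abundances (µM), lines x genes.

    ``transcripts`` may be a tidy table or a single {gene: µM} mapping (then
    the result has one row, line_id "line").
    """
    if isinstance(transcripts, Mapping):
        wide = pd.DataFrame([transcripts], index=pd.Index(["line"], name="line_id"))
    else:
        wide = to_wide(transcripts)
    missing = [g for g in wide.columns if g not in model]
    if missing:
        raise TranslationError(f"gene(s) missing from translation model: {missing}")
    betas = pd.Series({g: model[g].beta for g in wide.columns})
    return wide.mul(betas, axis=1)
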