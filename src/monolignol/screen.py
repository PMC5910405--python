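"""In-silico combinatorial gene-family perturbation screen.

Each of the 10 monolignol gene families is set to one of a discrete set of
expression levels relative to wildtype (by default 5% and 1000%, i.e.
multipliers 0.05 and 10.0), with at most ``max_modified`` families away from
wildtype at once.  Over 10 families, two levels and up to three simultaneous
modifications this enumerates 1161 configurations including the all-wildtype
baseline.  Each configuration is pushed through the fitted pipeline and the
predicted traits are ranked either on a single trait or by the proportional
score sum((predicted_i - desired_i)^2), lower being closer to the design
target.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pipeline import FittedPipeline, run_forward

__all__ = [
    "PerturbationConfig",
    "ScreenRow",
    "enumerate_configs",
    "predict_for_config",
    "run_screen",
    "proportional_score",
    "rank_configs",
    "ExtrapolationWarning",
]

log = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.05, 10.0)
DEFAULT_MAX_MODIFIED = 3


class ExtrapolationWarning(UserWarning):
    """A multiplier above wildtype extrapolates beyond the measured range."""


@dataclass(frozen=True)
class PerturbationConfig:
    """Per-family expression multipliers relative to wildtype."""

    multipliers: tuple[tuple[str, float], ...]  # (family, multiplier), all families

    @property
    def modified(self) -> tuple[tuple[str, float], ...]:
        return tuple((f, m) for f, m in self.multipliers if m != 1.0)

    @property
    def n_modified(self) -> int:
        return len(self.modified)

    @property
    def config_id(self) -> str:
        if not self.modified:
            return "WT"
        return "|".join(f"{f}x{m:g}" for f, m in self.modified)

    def as_dict(self) -> dict[str, float]:
        return dict(self.multipliers)


def enumerate_configs(
    families: Sequence[str],
    levels: Sequence[float] = DEFAULT_LEVELS,
    max_modified: int = DEFAULT_MAX_MODIFIED,
) -> list[PerturbationConfig]:
    """All configurations with 0..max_modified families off wildtype.

    The count is sum_{m=0}^{M} C(F, m) * |levels|^m, including the
    all-wildtype configuration; untargeted families stay at 1.0.
    """
    if not families:
        raise ValueError("need at least one family")
    if 1.0 in levels:
        raise ValueError("levels are non-wildtype multipliers; remove 1.0")
    if max_modified > len(families):
        raise ValueError("max_modified exceeds the number of families")
    out: list[PerturbationConfig] = []
    for m in range(0, max_modified + 1):
        for subset in itertools.combinations(range(len(families)), m):
            for combo in itertools.product(levels, repeat=m):
                mult = {f: 1.0 for f in families}
                for j, lev in zip(subset, combo):
                    mult[families[j]] = float(lev)
                out.append(PerturbationConfig(tuple(mult.items())))
    return out


@dataclass
class ScreenRow:
    config: PerturbationConfig
    traits: dict[str, float]
    percent_change: dict[str, float]   # NaN where the wildtype baseline is 0
    converged: bool
    score: float | None = None
    rank: int | None = None


def predict_for_config(
    config: PerturbationConfig,
    pipeline: FittedPipeline,
    wt_transcripts: Mapping[str, float] | None = None,
    wt_traits: Mapping[str, float] | None = None,
    **solve_kw,
) -> ScreenRow:
    """Scale every member gene of each modified family and run the pipeline."""
    wt_tx = dict(wt_transcripts if wt_transcripts is not None
                 else pipeline.wt_transcripts)
    wt_tr = dict(wt_traits if wt_traits is not None else pipeline.wt_traits)
    mult = config.as_dict()
    if any(m > 1.0 for m in mult.values()):
        warnings.warn(
            f"{config.config_id}: multiplier above wildtype extrapolates "
            "beyond the experimental expression range",
            ExtrapolationWarning,
        )
    fam_of = pipeline.pathway.gene_families
    tx = {g: v * mult.get(fam_of.get(g, ""), 1.0) for g, v in wt_tx.items()}
    preds, conv = run_forward(tx, pipeline, **solve_kw)
    traits = preds.iloc[0].to_dict()
    converged = bool(conv.iloc[0])
    pct = {}
    for t, v in traits.items():
        base = wt_tr.get(t)
        if base is None or base == 0 or not np.isfinite(v):
            pct[t] = float("nan")
        else:
            pct[t] = 100.0 * (v - base) / base
    return ScreenRow(config, traits, pct, converged)


def proportional_score(
    predicted: Mapping[str, float], desired: Mapping[str, float]
) -> float:
    """sum over desired traits of (predicted - desired)^2; >= 0, 0 iff equal."""
    pk, dk = set(predicted), set(desired)
    if pk != dk:
        raise ValueError(
            f"trait sets differ: only-predicted={sorted(pk - dk)}, "
            f"only-desired={sorted(dk - pk)}"
        )
    return float(sum((predicted[t] - desired[t]) ** 2 for t in desired))


def rank_configs(
    results: Sequence[ScreenRow],
    objective: tuple[str, str] | Mapping[str, float],
) -> list[ScreenRow]:
    """Order screen rows by the objective; flagged (non-converged) rows are
    excluded.

    ``objective`` is either ``(trait, "max"|"min")`` for a single-trait
    ranking, or a {trait: desired value} mapping ranked by ascending
    proportional score.  Ties break toward fewer modified families, then
    lexicographic config id.
    """
    rows = [r for r in results if r.converged]
    if not rows:
        raise ValueError("no converged configurations to rank")
    if isinstance(objective, tuple):
        trait, direction = objective
        if direction not in ("max", "min"):
            raise ValueError("direction must be 'max' or 'min'")
        sign = -1.0 if direction == "max" else 1.0
        for r in rows:
            r.score = None

        def key(r: ScreenRow):
            return (sign * r.traits[trait], r.config.n_modified, r.config.config_id)
    else:
        for r in rows:
            r.score = proportional_score(
                {t: r.traits[t] for t in objective}, dict(objective)
            )

        def key(r: ScreenRow):
            return (r.score, r.config.n_modified, r.config.config_id)

    ordered = sorted(rows, key=key)
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def run_screen(
    pipeline: FittedPipeline,
    levels: Sequence[float] = DEFAULT_LEVELS,
    max_modified: int = DEFAULT_MAX_MODIFIED,
    objective: tuple[str, str] | Mapping[str, float] | None = None,
    **solve_kw,
) -> list[ScreenRow]:
    """Enumerate, predict and (optionally) rank all configurations."""
    families = pipeline.pathway.families
    configs = enumerate_configs(families, levels, max_modified)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        rows = [predict_for_config(c, pipeline, **solve_kw) for c in configs]
    n_bad = sum(not r.converged for r in rows)
    if n_bad:
        log.warning("%d configuration(s) did not converge and are excluded "
                    "from ranking", n_bad)
    if objective is not None:
        rank_configs(rows, objective)
    return rows


def screen_table(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Flat results table: config id, modification count, traits, % change,
    score and rank."""
    recs = []
    for r in rows:
        rec = {"config_id": r.config.config_id,
               "n_modified": r.config.n_modified,
               "converged": r.converged,
               "score": r.score, "rank": r.rank}
        rec.update(r.traits)
        rec.update({f"pct_{t}": v for t, v in r.percent_change.items()})
        recs.append(rec)
    return pd.DataFrame(recs)
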