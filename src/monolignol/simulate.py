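"""Synthetic transgenic-population generator with recorded ground truth.

Emulates the statistical structure of a knockdown population of
*P. trichocarpa* lines: per-line targeted suppression of a gene, gene pair
or whole family (residual expression drawn from a 5-95% band), multiplicative
cross-family indirect effects, batch (seasonal) structure with wildtype
controls in every batch, lognormal replicate noise, proteins proportional to
transcripts through per-gene translation coefficients beta_i (average scale
1.5e4 protein molecules per transcript), and traits generated by a sparse
linear rule on the line's true steady-state fluxes and metabolite
concentrations.

Everything random is driven by explicit seeds; the generating parameters are
returned as a :class:`GroundTruth` for parameter-recovery tests.  Kinetic
constants are synthetic stand-ins for assay-derived values: log-uniform
draws accepted only if the wildtype steady state converges, is robust to
random initial conditions, and (optionally) can be calibrated to a target
S/G ratio.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import calibrate_phenylalanine, lhs_robustness, solve_steady_state
from .pathway import ComplexSpec, KineticParameterSet, PathwayDefinition
from .traits import (
    collinearity_filter,
    feature_columns,
    is_percentage,
    round_features,
)
from .translation import predict_protein, TranslationModel, GeneTranslation

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "SyntheticDataset",
    "generate_kinetics",
    "generate_population",
    "GenerationError",
    "WILDTYPE_TRAIT_BASELINES",
]


class GenerationError(RuntimeError):
    pass


#: Nominal wildtype trait values used as intercept anchors (units per trait).
WILDTYPE_TRAIT_BASELINES: dict[str, float] = {
    "lignin_content": 21.7,
    "s_g_ratio": 2.16,
    "s_subunits": 63.0,
    "g_subunits": 30.0,
    "h_subunits": 1.5,
    "p_hydroxybenzoic_acid": 5.0,
    "c_l_ratio": 3.2,
    "aldehyde_content": 2.5,
    "beta_O_4": 85.0,
    "beta_5": 6.0,
    "beta_beta": 6.5,
    "beta_1": 1.0,
    "cinnamyl_alcohol_endgroups": 9.0,
    "height": 300.0,
    "diameter": 20.0,
    "stem_volume": 350.0,
    "glucose": 49.8,
    "xylose": 16.2,
    "total_carbohydrates": 69.8,
    "relative_density": 0.35,
    "moe": 4000.0,
    "sacch_glucose_unpretreated": 20.0,
    "sacch_xylose_unpretreated": 15.0,
    "sacch_glucose_pretreated": 55.0,
    "sacch_xylose_pretreated": 40.0,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions of the emulated transgenic population."""

    n_lines: int = 239
    seed: int = 20180420          # structural seed: beta_i, wildtype abundances
    knockdown_range: tuple[float, float] = (0.05, 0.95)  # fraction of WT remaining
    indirect_sd: float = 0.2      # lognormal sd of cross-family effects (~±20%)
    n_batches: int = 6
    batch_sd: float = 0.1         # lognormal sd of batch (seasonal) effects
    replicate_sd: float = 0.05    # lognormal sd of residual per-line variation
    beta_median: float = 1.5e4    # median protein molecules per transcript
    beta_sigma: float = 0.6       # lognormal spread of beta_i across genes
    protein_noise_cv: float = 0.2
    trait_noise_cv: float = 0.1   # noise sd as a fraction of the trait's population spread
    effect_fraction: float = 0.2  # per-predictor effect sd as fraction of baseline
    max_true_support: int = 3
    support_max_corr: float = 0.85  # cap on |r| between true predictors and others
    kcat_range: tuple[float, float] = (0.1, 100.0)   # 1/s
    km_range: tuple[float, float] = (1.0, 1000.0)    # µM
    ki_range: tuple[float, float] = (1.0, 1000.0)    # µM
    wt_protein_range: tuple[float, float] = (0.5, 10.0)  # µM
    target_sg: float = 2.16
    phe_ref: float = 1.4          # µM, anchor for S/G tuning
    lhs_check_n: int = 50
    require_perturbation_viability: bool = False  # single-family 5%/1000% must settle

    def __post_init__(self) -> None:
        lo, hi = self.knockdown_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("knockdown fractions must lie in (0, 1]")
        for name in ("kcat_range", "km_range", "ki_range", "wt_protein_range"):
            a, b = getattr(self, name)
            if not (0 < a <= b):
                raise ValueError(f"{name} must be positive with lo <= hi")

    def structural(self, pathway: PathwayDefinition):
        """Deterministic per-gene beta_i and wildtype abundances (from ``seed``)."""
        rng = np.random.default_rng(self.seed)
        genes = list(pathway.gene_families)
        betas = {
            g: float(self.beta_median * np.exp(rng.normal(0.0, self.beta_sigma)))
            for g in genes
        }
        lo, hi = self.wt_protein_range
        wt_proteins = {
            g: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for g in genes
        }
        wt_transcripts = {g: wt_proteins[g] / betas[g] for g in genes}
        return betas, wt_transcripts, wt_proteins


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_kinetics(
    pathway: PathwayDefinition, spec: GeneratorSpec, rng: np.random.Generator
) -> KineticParameterSet:
    rp = {}
    for r in pathway.reactions:
        if not r.active:
            continue
        for g in r.enzymes:
            rp[(r.id, g)] = (
                _loguniform(rng, *spec.kcat_range),
                _loguniform(rng, *spec.km_range),
            )
    ip = {
        (i.inhibitor, i.reaction): _loguniform(rng, *spec.ki_range)
        for i in pathway.inhibitions
    }
    cs = ComplexSpec(
        stoichiometry={"Ptr4CL3": 3, "Ptr4CL5": 1},
        reactions=(7, 8),
        params={
            7: (_loguniform(rng, *spec.kcat_range), _loguniform(rng, *spec.km_range)),
            8: (_loguniform(rng, *spec.kcat_range), _loguniform(rng, *spec.km_range)),
        },
    )
    return KineticParameterSet(rp, ip, cs)


def _scale_reaction_kcat(
    params: KineticParameterSet, reaction_id: int, factor: float
) -> KineticParameterSet:
    rp = {
        key: ((kc * factor, km) if key[0] == reaction_id else (kc, km))
        for key, (kc, km) in params.reaction_params.items()
    }
    return KineticParameterSet(rp, params.inhibition_params, params.complex_spec)


#: The coniferaldehyde-5-hydroxylation flux; scaling its kcat shifts flux from
#: the G branch (V34) into the S branch, moving S/G monotonically.
_SG_TUNING_REACTION = 24


def _tune_sg(
    pathway: PathwayDefinition,
    params: KineticParameterSet,
    wt_proteins: Mapping[str, float],
    target_sg: float,
    phe_ref: float,
) -> KineticParameterSet | None:
    def sg_of(theta: float) -> float:
        ks = _scale_reaction_kcat(params, _SG_TUNING_REACTION, theta)
        ss = solve_steady_state(pathway, ks, wt_proteins, phe_ref)
        return ss.sg_ratio if ss.converged else float("nan")

    thetas = np.geomspace(1e-3, 1e3, 13)
    vals = np.array([sg_of(t) for t in thetas])
    for lo, hi, flo, fhi in zip(thetas[:-1], thetas[1:], vals[:-1], vals[1:]):
        if np.isnan(flo) or np.isnan(fhi):
            continue
        if (flo - target_sg) * (fhi - target_sg) < 0:
            try:
                theta = brentq(lambda t: sg_of(t) - target_sg, lo, hi, rtol=1e-8)
            except ValueError:  # non-convergent point inside the bracket
                continue
            return _scale_reaction_kcat(params, _SG_TUNING_REACTION, theta)
        if flo == target_sg:
            return _scale_reaction_kcat(params, _SG_TUNING_REACTION, lo)
    return None


def generate_kinetics(
    pathway: PathwayDefinition,
    spec: GeneratorSpec,
    seed: int,
    target_sg: float | None = None,
    max_attempts: int = 400,
) -> KineticParameterSet:
    """Draw a synthetic kinetic registry (log-uniform within spec ranges).

    A draw is accepted once the wildtype steady state converges, reaches the
    same state from ``spec.lhs_check_n`` random initial conditions, and — if
    ``target_sg`` is given — the S-branch can be tuned so the wildtype S/G
    ratio equals ``target_sg`` at ``spec.phe_ref`` µM phenylalanine.
    """
    rng = np.random.default_rng(seed)
    _, _, wt_proteins = spec.structural(pathway)
    for _ in range(max_attempts):
        params = _draw_kinetics(pathway, spec, rng)
        ss = solve_steady_state(pathway, params, wt_proteins, spec.phe_ref)
        if not ss.converged:
            continue
        if target_sg is not None:
            tuned = _tune_sg(pathway, params, wt_proteins, target_sg, spec.phe_ref)
            if tuned is None:
                continue
            params = tuned
            # calibration must stay well-posed under small shifts of the
            # wildtype anchor: the S/G curve has to cross the target with
            # margin inside the phenylalanine bracket
            sgs = np.array([
                solve_steady_state(pathway, params, wt_proteins, phe).sg_ratio
                for phe in np.geomspace(0.01, 100.0, 9)
            ])
            sgs = sgs[np.isfinite(sgs)]
            if len(sgs) == 0 or sgs.max() < 1.1 * target_sg \
                    or sgs.min() > 0.9 * target_sg:
                continue
        if spec.require_perturbation_viability:
            # the packaged registry backs the perturbation screen, so the
            # pathway must settle within the integration horizon for every
            # single-family knockdown and overexpression, as the measured
            # system does
            ok = True
            for fam in pathway.families:
                for level in (spec.knockdown_range[0], 10.0):
                    prot = dict(wt_proteins)
                    for g in pathway.family_members(fam):
                        prot[g] *= level
                    if not solve_steady_state(pathway, params, prot,
                                              spec.phe_ref).converged:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
        if spec.lhs_check_n > 0:
            frac = lhs_robustness(
                pathway, params, wt_proteins, spec.phe_ref,
                n_samples=spec.lhs_check_n, seed=seed,
            )
            if frac < 1.0:
                continue
        return params
    raise GenerationError(
        f"no acceptable kinetic parameter set in {max_attempts} attempts; "
        "consider wider ranges"
    )


@dataclass
class GroundTruth:
    """Generating parameters recorded alongside every synthetic dataset."""

    betas: dict[str, float]
    wt_transcripts: dict[str, float]
    phenylalanine: float
    target_sg: float
    trait_supports: dict[str, tuple[str, ...]]
    trait_coefficients: dict[str, tuple[float, ...]]
    trait_intercepts: dict[str, float]
    noise_free_traits: pd.DataFrame
    knockdown: dict[str, float]          # line_id -> residual fraction (targets)
    target_genes: dict[str, tuple[str, ...]]

    def translation_model(self) -> TranslationModel:
        return TranslationModel({
            g: GeneTranslation(beta=b, r_squared=1.0, n_observations=0)
            for g, b in self.betas.items()
        })

    def to_json(self, path) -> None:
        doc = {
            "betas": self.betas,
            "wt_transcripts": self.wt_transcripts,
            "phenylalanine": self.phenylalanine,
            "target_sg": self.target_sg,
            "trait_supports": {t: list(s) for t, s in self.trait_supports.items()},
            "trait_coefficients": {t: list(c) for t, c in
                                   self.trait_coefficients.items()},
            "trait_intercepts": self.trait_intercepts,
            "knockdown": self.knockdown,
            "target_genes": {k: list(v) for k, v in self.target_genes.items()},
            "noise_free_traits": self.noise_free_traits.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


@dataclass
class SyntheticDataset:
    transcripts: pd.DataFrame    # tidy: line_id, batch, genotype, gene_id, value
    proteins: pd.DataFrame
    traits: pd.DataFrame         # wide: line_id x 25 traits
    ground_truth: GroundTruth


def _assign_constructs(
    pathway: PathwayDefinition, n_transgenic: int, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Target gene set per transgenic line: whole family, pair, or single."""
    families = pathway.families
    out = []
    for i in range(n_transgenic):
        fam = families[i % len(families)]
        members = pathway.family_members(fam)
        u = rng.random()
        if u < 0.5 or len(members) == 1:
            targets = members                       # family-wide RNAi
        elif u < 0.75 and len(members) >= 2:
            targets = tuple(rng.choice(members, size=2, replace=False))
        else:
            targets = (str(rng.choice(members)),)   # gene-specific amiRNA
        out.append(tuple(sorted(targets)))
    return out


def generate_population(
    pathway: PathwayDefinition,
    kinetics: KineticParameterSet,
    spec: GeneratorSpec,
    seed: int,
) -> SyntheticDataset:
    """Generate transcripts, proteins and traits for ``spec.n_lines`` lines.

    Each batch carries three wildtype replicate lines; the remaining lines
    are transgenic.  Traits follow a sparse linear ground-truth rule on the
    line's true steady-state features (rounded to the same five decimals the
    fitting uses), built on predictors that survive the collinearity filter
    so the regression layer's assumptions hold exactly.
    """
    if spec.n_lines < 10:
        warnings.warn("n_lines < 10: downstream fitting will refuse this dataset")
    rng = np.random.default_rng(seed)
    betas, wt_tx, _ = spec.structural(pathway)
    genes = list(pathway.gene_families)

    n_wt = 3 * spec.n_batches
    if spec.n_lines <= n_wt:
        raise GenerationError(
            f"n_lines={spec.n_lines} too small for {n_wt} wildtype controls"
        )
    n_tg = spec.n_lines - n_wt
    constructs = _assign_constructs(pathway, n_tg, rng)

    batch_eff = {
        (b, g): float(np.exp(rng.normal(0.0, spec.batch_sd)))
        for b in range(spec.n_batches) for g in genes
    }

    fams = pathway.families
    beta_vec = np.array([betas[g] for g in genes])

    def draw_transcripts(batch: int, targets: tuple[str, ...], kd: float,
                         transgenic: bool) -> np.ndarray:
        target_fams = {pathway.gene_families[g] for g in targets}
        indirect = {
            f: float(np.exp(rng.normal(0.0, spec.indirect_sd)))
            for f in fams if f not in target_fams
        } if transgenic else {}
        row = np.empty(len(genes))
        for gi, g in enumerate(genes):
            v = wt_tx[g] * batch_eff[(batch, g)]
            v *= float(np.exp(rng.normal(0.0, spec.replicate_sd)))
            fam = pathway.gene_families[g]
            if g in targets:
                v *= kd
            elif fam in indirect:
                v *= indirect[fam]
            row[gi] = v
        return row

    # wildtype control lines: three replicates per batch
    line_ids, batches, genotypes = [], [], []
    tx_rows: list[np.ndarray] = []
    for b in range(spec.n_batches):
        for r in range(3):
            line_ids.append(f"WT-{b}-{r}")
            batches.append(b)
            genotypes.append("wildtype")
            tx_rows.append(draw_transcripts(b, (), 1.0, transgenic=False))

    # phenylalanine: same calibration the fitting layer performs, anchored on
    # the realized wildtype-mean transcript profile and the true betas; the
    # "measured" wildtype S/G of this synthetic study is whatever that anchor
    # produces at the reference phenylalanine
    anchor_tx = dict(zip(genes, np.mean(tx_rows, axis=0)))
    truth_model = TranslationModel({
        g: GeneTranslation(betas[g], 1.0, 0) for g in genes
    })
    anchor_prot = predict_protein(anchor_tx, truth_model).iloc[0].to_dict()
    sg_anchor = solve_steady_state(
        pathway, kinetics, anchor_prot, spec.phe_ref
    ).sg_ratio
    if not np.isfinite(sg_anchor):
        raise GenerationError("wildtype anchor has no finite S/G ratio")
    phe = calibrate_phenylalanine(pathway, kinetics, anchor_prot, sg_anchor)

    feat_rows: list[dict[str, float]] = []
    for line, row in zip(line_ids, tx_rows):
        ss = solve_steady_state(pathway, kinetics, dict(zip(genes, row * beta_vec)), phe)
        if not ss.converged:
            raise GenerationError(f"wildtype line {line} did not reach steady state")
        feat_rows.append(ss.feature_vector())

    # transgenic lines; like the source study, only viable lines enter the
    # population: a draw whose pathway state cannot settle within the
    # integration horizon is replaced by a fresh draw for the same construct
    knockdown: dict[str, float] = {}
    target_genes: dict[str, tuple[str, ...]] = {}
    max_retries = 20
    for i, targets in enumerate(constructs):
        line = f"TG-{i:03d}"
        b = i % spec.n_batches
        for attempt in range(max_retries):
            kd = float(rng.uniform(*spec.knockdown_range))
            row = draw_transcripts(b, targets, kd, transgenic=True)
            ss = solve_steady_state(pathway, kinetics,
                                    dict(zip(genes, row * beta_vec)), phe)
            if ss.converged:
                break
        else:
            raise GenerationError(
                f"line {line} (targets {targets}) found no steady state in "
                f"{max_retries} draws"
            )
        line_ids.append(line)
        batches.append(b)
        genotypes.append("transgenic")
        tx_rows.append(row)
        feat_rows.append(ss.feature_vector())
        knockdown[line] = kd
        target_genes[line] = targets

    tx_values = np.vstack(tx_rows)
    true_prot = tx_values * beta_vec
    prot_noise = rng.normal(0.0, 1.0, size=tx_values.shape)
    obs_prot = np.maximum(true_prot * (1.0 + spec.protein_noise_cv * prot_noise), 0.0)

    def tidy(values: np.ndarray) -> pd.DataFrame:
        recs = []
        for li, (line, b, gt) in enumerate(zip(line_ids, batches, genotypes)):
            for gi, g in enumerate(genes):
                recs.append((line, b, gt, g, values[li, gi]))
        return pd.DataFrame(
            recs, columns=["line_id", "batch", "genotype", "gene_id", "value"]
        )

    transcripts = tidy(tx_values)
    proteins = tidy(obs_prot)

    feats = pd.DataFrame(feat_rows, index=pd.Index(line_ids, name="line_id"))
    feats = feats[feature_columns(len(pathway.reactions), len(pathway.metabolites))]
    feats = round_features(feats)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        retained = collinearity_filter(feats)
    fmat = feats[retained]
    sds = fmat.std(axis=0, ddof=0)
    means = fmat.mean(axis=0)
    # trait rules are built on informative predictors only: features whose
    # across-population variation is real (above the rounding quantum) and
    # substantial relative to their mean, as measured predictors would be
    usable = [
        c for c in retained
        if sds[c] > max(0.05 * abs(means[c]), 1e-3)
    ]
    # and safely below the collinearity threshold against every other
    # retained feature, so subsample refits (cross-validation folds) cannot
    # evict a true predictor through correlation fluctuations
    if len(usable) > 1:
        corr = fmat[usable].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        keep = corr.max(axis=1) <= spec.support_max_corr
        usable = [c for c, k in zip(usable, keep) if k]
    if not usable:
        raise GenerationError("no informative features for trait ground truth")

    supports: dict[str, tuple[str, ...]] = {}
    coefs: dict[str, tuple[float, ...]] = {}
    intercepts: dict[str, float] = {}
    nf = {}
    for trait in WILDTYPE_TRAIT_BASELINES:
        base = WILDTYPE_TRAIT_BASELINES[trait]
        k = int(rng.integers(1, spec.max_true_support + 1))
        k = min(k, len(usable))
        cols = tuple(sorted(str(c) for c in rng.choice(usable, size=k, replace=False)))
        c = np.array([
            rng.choice([-1.0, 1.0]) * spec.effect_fraction * base / sds[col]
            for col in cols
        ])
        raw = base + (fmat[list(cols)].to_numpy(float) - means[list(cols)].to_numpy(float)) @ c
        # keep the noise-free rule strictly inside the clamp bounds so the
        # linear ground truth is exactly recoverable
        hi = 100.0 if is_percentage(trait) else np.inf
        margin_lo, margin_hi = 0.02 * base, hi - 0.02 * base if np.isfinite(hi) else np.inf
        shrink = 1.0
        lo_v, hi_v = raw.min(), raw.max()
        if lo_v < margin_lo or hi_v > margin_hi:
            span = max(base - lo_v, hi_v - base, 1e-12)
            allowed = min(base - margin_lo,
                          (margin_hi - base) if np.isfinite(margin_hi) else np.inf)
            shrink = max(min(allowed / span, 1.0), 0.0)
        c = c * shrink
        raw = base + (fmat[list(cols)].to_numpy(float) - means[list(cols)].to_numpy(float)) @ c
        intercept = base - float(means[list(cols)].to_numpy(float) @ c)
        supports[trait] = cols
        coefs[trait] = tuple(float(v) for v in c)
        intercepts[trait] = intercept
        nf[trait] = raw
    noise_free = pd.DataFrame(nf, index=fmat.index)

    # measurement noise scales with each trait's realized population spread
    # (noise-to-signal), so bounded traits keep a realistic signal fraction
    noise = rng.normal(0.0, 1.0, size=noise_free.shape)
    scale = noise_free.std(axis=0, ddof=0).to_numpy() * spec.trait_noise_cv
    observed = noise_free + noise * scale
    for t in noise_free.columns:
        hi = 100.0 if is_percentage(t) else np.inf
        observed[t] = observed[t].clip(lower=0.0, upper=hi)

    gt = GroundTruth(
        betas=betas,
        wt_transcripts=wt_tx,
        phenylalanine=float(phe),
        target_sg=float(sg_anchor),
        trait_supports=supports,
        trait_coefficients=coefs,
        trait_intercepts=intercepts,
        noise_free_traits=noise_free,
        knockdown=knockdown,
        target_genes=target_genes,
    )
    return SyntheticDataset(transcripts, proteins, observed, gt)
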