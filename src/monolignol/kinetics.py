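"""Mass-balance kinetics of the monolignol grid.

Every active reaction follows an irreversible Michaelis-Menten rate law
scaled by the abundance of its catalysing enzyme(s), with declared
metabolite inhibitions applied as competitive (apparent-Km), uncompetitive
(apparent-substrate) or noncompetitive (whole-rate) factors:

    v = sum_g  kcat_{r,g} * E_g * S / (Km_{r,g} * a_c + S * a_u) / a_n

where a_c = 1 + sum(I/Ki) over competitive inhibitors of r, and likewise
for a_u (uncompetitive) and a_n (noncompetitive).  Reactions 7 and 8 route
through the Ptr4CL3/Ptr4CL5 heterotetramer pool (3:1 stoichiometry): the
complex concentration is min(P_4CL3/3, P_4CL5) and carries its own
kcat/Km; leftover monomers retain monomer kinetics by default.

Phenylalanine (metabolite 1) is a clamped boundary species.  The three
monolignols (20, 22, 24) accumulate as sinks and are excluded from the
steady-state criterion.  The system is integrated with a stiff solver from
0 to 10,000 s; the endpoint is then polished with a damped Newton step
(``scipy.optimize.root``) which is accepted only if it stays non-negative
and close to the integrated endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root
from scipy.stats import qmc

from .pathway import (
    INACTIVE_REACTIONS,
    SG_DENOMINATOR_FLUX,
    SG_NUMERATOR_FLUX,
    SINK_METABOLITES,
    SOURCE_METABOLITE,
    KineticParameterSet,
    PathwayDefinition,
    Reaction,
    SchemaError,
)

__all__ = [
    "SteadyState",
    "CalibrationError",
    "CompiledModel",
    "reaction_rate",
    "solve_steady_state",
    "calibrate_phenylalanine",
    "lhs_robustness",
]

#: Integration horizon (s); long enough for the grid to settle.
T_END = 10_000.0
#: Steady-state criterion: max |dC/dt| / max(C, 1 µM-scale floor) on internal metabolites.
SS_TOL = 1e-6
_RESIDUAL_FLOOR = 1e-6  # µM; avoids flagging numerically-zero pools


class CalibrationError(RuntimeError):
    """Phenylalanine calibration could not bracket the target S/G ratio."""


@dataclass
class SteadyState:
    """Converged state of the grid for one enzyme-abundance profile.

    ``metabolite_conc`` maps every metabolite id to µM: the clamped
    phenylalanine value, internal steady-state concentrations, and for the
    three sinks the amount accumulated over the integration horizon (sinks
    are excluded from the steady-state criterion).
    """

    metabolite_conc: dict[int, float]
    fluxes: dict[int, float]
    sg_ratio: float
    converged: bool
    residual: float

    def feature_vector(self) -> dict[str, float]:
        """Fluxes V1..V37 then metabolites M1..M24, the trait-regression features."""
        out = {f"V{i}": self.fluxes[i] for i in sorted(self.fluxes)}
        out.update({f"M{i}": self.metabolite_conc[i] for i in sorted(self.metabolite_conc)})
        return out

    def to_tsv(self, path) -> None:
        import pandas as pd

        met = pd.DataFrame(
            {"metabolite_id": sorted(self.metabolite_conc),
             "conc_uM": [self.metabolite_conc[i] for i in sorted(self.metabolite_conc)]}
        )
        flx = pd.DataFrame(
            {"flux_id": sorted(self.fluxes),
             "flux_uM_per_s": [self.fluxes[i] for i in sorted(self.fluxes)]}
        )
        with open(path, "w") as fh:
            met.to_csv(fh, sep="\t", index=False)
            fh.write("\n")
            flx.to_csv(fh, sep="\t", index=False)


def _inhibition_factors(
    pathway: PathwayDefinition,
    params: KineticParameterSet,
    reaction_id: int,
    conc_of,
) -> tuple[float, float, float]:
    a_c = a_u = a_n = 1.0
    for inh in pathway.inhibitions:
        if inh.reaction != reaction_id:
            continue
        ki = params.inhibition_params.get((inh.inhibitor, inh.reaction))
        if ki is None:
            continue
        term = conc_of(inh.inhibitor) / ki
        if inh.mechanism == "competitive":
            a_c += term
        elif inh.mechanism == "uncompetitive":
            a_u += term
        else:
            a_n += term
    return a_c, a_u, a_n


def _complex_pools(
    params: KineticParameterSet, enzymes: Mapping[str, float]
) -> tuple[float, dict[str, float]]:
    """Return (complex µM, leftover monomer µM per member gene)."""
    cs = params.complex_spec
    if cs is None:
        return 0.0, {}
    pool = min(enzymes.get(g, 0.0) / s for g, s in cs.stoichiometry.items())
    pool = max(pool, 0.0)
    leftover = {
        g: max(enzymes.get(g, 0.0) - s * pool, 0.0)
        for g, s in cs.stoichiometry.items()
    }
    return pool, leftover


def reaction_rate(
    reaction: Reaction,
    enzymes: Mapping[str, float],
    conc: Mapping[int, float],
    params: KineticParameterSet,
    pathway: PathwayDefinition,
) -> float:
    """Rate (µM/s) of one reaction at the given enzyme and metabolite state."""
    if not reaction.active:
        return 0.0
    s_conc = max(conc.get(reaction.substrate, 0.0), 0.0)
    a_c, a_u, a_n = _inhibition_factors(
        pathway, params, reaction.id, lambda m: max(conc.get(m, 0.0), 0.0)
    )
    cs = params.complex_spec
    in_complex = cs is not None and reaction.id in cs.reactions
    rate = 0.0
    if in_complex:
        pool, leftover = _complex_pools(params, enzymes)
        kcat, km = cs.params[reaction.id]
        rate += kcat * pool * s_conc / (km * a_c + s_conc * a_u) / a_n if s_conc > 0 else 0.0
        monomer_e = leftover if cs.leftover_active else {}
    else:
        monomer_e = dict(enzymes)
    for gene in reaction.enzymes:
        pair = params.reaction_params.get((reaction.id, gene))
        if pair is None:
            if not in_complex:
                raise SchemaError(
                    f"missing kinetic parameters for reaction {reaction.id}, "
                    f"enzyme {gene}"
                )
            continue
        e = monomer_e.get(gene, 0.0) if in_complex else enzymes.get(gene, 0.0)
        if e <= 0 or s_conc <= 0:
            continue
        kcat, km = pair
        rate += kcat * e * s_conc / (km * a_c + s_conc * a_u) / a_n
    return rate


class CompiledModel:
    """Vectorised right-hand side of the mass-balance ODE system.

    Built once per (pathway, params, proteins); state vector holds all 24
    metabolites in id order, with phenylalanine clamped.
    """

    def __init__(
        self,
        pathway: PathwayDefinition,
        params: KineticParameterSet,
        proteins: Mapping[str, float],
        phe_conc: float,
    ):
        params.validate(pathway)
        for g, e in proteins.items():
            if e < 0:
                raise ValueError(f"negative enzyme abundance for {g}")
        if phe_conc < 0:
            raise ValueError("phenylalanine concentration must be >= 0")
        self.pathway = pathway
        self.params = params
        self.phe_conc = float(phe_conc)
        self.n_met = len(pathway.metabolites)
        ordered = sorted(pathway.metabolites, key=lambda m: m.id)
        self.met_index = {m.id: i for i, m in enumerate(ordered)}
        self.source_idx = self.met_index[SOURCE_METABOLITE]
        self.sink_idx = np.array(sorted(self.met_index[m] for m in SINK_METABOLITES))
        self.internal_idx = np.array(
            sorted(self.met_index[m] for m in pathway.internal_metabolites)
        )
        self.active = [r for r in pathway.reactions if r.active]

        # flatten (reaction, enzyme) entries
        ent_rxn, ent_kcat, ent_km, ent_e = [], [], [], []
        cs = params.complex_spec
        pool, leftover = _complex_pools(params, proteins)
        for k, r in enumerate(self.active):
            in_complex = cs is not None and r.id in cs.reactions
            if in_complex:
                kcat, km = cs.params[r.id]
                ent_rxn.append(k); ent_kcat.append(kcat); ent_km.append(km)
                ent_e.append(pool)
            for gene in r.enzymes:
                pair = params.reaction_params.get((r.id, gene))
                if pair is None:
                    continue
                if in_complex:
                    if not cs.leftover_active:
                        continue
                    e = leftover.get(gene, 0.0)
                else:
                    e = proteins.get(gene, 0.0)
                ent_rxn.append(k); ent_kcat.append(pair[0]); ent_km.append(pair[1])
                ent_e.append(e)
        self.ent_rxn = np.array(ent_rxn, dtype=int)
        self.ent_vmax = np.array(ent_kcat) * np.array(ent_e)  # kcat * E
        self.ent_km = np.array(ent_km)
        self.sub_idx = np.array([self.met_index[r.substrate] for r in self.active])
        self.ent_sub = self.sub_idx[self.ent_rxn]

        # inhibition entries grouped by mechanism
        def _mech_arrays(mech: str):
            met, rxn, ki = [], [], []
            for inh in pathway.inhibitions:
                if inh.mechanism != mech:
                    continue
                k = params.inhibition_params.get((inh.inhibitor, inh.reaction))
                if k is None:
                    continue
                for j, r in enumerate(self.active):
                    if r.id == inh.reaction:
                        met.append(self.met_index[inh.inhibitor])
                        rxn.append(j)
                        ki.append(k)
            return np.array(met, dtype=int), np.array(rxn, dtype=int), np.array(ki)

        self.inh = {m: _mech_arrays(m) for m in
                    ("competitive", "uncompetitive", "noncompetitive")}

        # stoichiometry: rates -> dC/dt
        self.prod_idx = np.array([self.met_index[r.product] for r in self.active])
        self.n_active = len(self.active)

    def rates(self, y: np.ndarray) -> np.ndarray:
        """Per-active-reaction rates at state y (length n_met)."""
        c = np.maximum(y, 0.0)
        a = {}
        for mech, (met, rxn, ki) in self.inh.items():
            alpha = np.ones(self.n_active)
            if len(met):
                np.add.at(alpha, rxn, c[met] / ki)
            a[mech] = alpha
        s = c[self.ent_sub]
        denom = (self.ent_km * a["competitive"][self.ent_rxn]
                 + s * a["uncompetitive"][self.ent_rxn])
        with np.errstate(invalid="ignore", divide="ignore"):
            v_ent = np.where(denom > 0, self.ent_vmax * s / denom, 0.0)
        v_ent = v_ent / a["noncompetitive"][self.ent_rxn]
        v = np.zeros(self.n_active)
        np.add.at(v, self.ent_rxn, v_ent)
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        v = self.rates(y)
        dy = np.zeros_like(y)
        np.subtract.at(dy, self.sub_idx, v)
        np.add.at(dy, self.prod_idx, v)
        dy[self.source_idx] = 0.0  # clamped
        return dy

    def flux_dict(self, y: np.ndarray) -> dict[int, float]:
        v = self.rates(y)
        out = {r.id: 0.0 for r in self.pathway.reactions}
        for r, val in zip(self.active, v):
            out[r.id] = float(val)
        return out

    def initial_state(self, init: Mapping[int, float] | None) -> np.ndarray:
        y0 = np.zeros(self.n_met)
        y0[self.source_idx] = self.phe_conc
        if init is not None:
            for mid, val in init.items():
                if mid == SOURCE_METABOLITE:
                    continue
                y0[self.met_index[mid]] = max(float(val), 0.0)
        return y0

    def residual(self, y: np.ndarray) -> float:
        dy = self.rhs(0.0, y)
        yi = y[self.internal_idx]
        return float(np.max(np.abs(dy[self.internal_idx])
                            / np.maximum(np.abs(yi), _RESIDUAL_FLOOR)))


def solve_steady_state(
    pathway: PathwayDefinition,
    params: KineticParameterSet,
    proteins: Mapping[str, float],
    phe_conc: float,
    init: Mapping[int, float] | None = None,
    t_end: float = T_END,
    ss_tol: float = SS_TOL,
    rtol: float = 1e-8,
    atol: float = 1e-9,
    polish: bool = True,
) -> SteadyState:
    """Integrate the grid to ``t_end`` and report the (near-)steady state.

    Non-convergence is reported through ``converged=False`` and the residual,
    never as an exception.
    """
    model = CompiledModel(pathway, params, proteins, phe_conc)
    y0 = model.initial_state(init)
    if model.ent_vmax.sum() == 0.0 or phe_conc == 0.0 and init is None:
        y_end = y0
    else:
        sol = solve_ivp(
            model.rhs, (0.0, t_end), y0, method="LSODA",
            t_eval=[t_end], rtol=rtol, atol=atol,
        )
        y_end = sol.y[:, -1] if sol.success else y0 * np.nan
    if np.all(np.isfinite(y_end)):
        y_end = np.maximum(y_end, 0.0)
        y_end[model.source_idx] = phe_conc
        if polish:
            y_end = _newton_polish(model, y_end)
        res = model.residual(y_end)
        converged = res < ss_tol
    else:
        res = np.inf
        converged = False
        y_end = np.zeros_like(y0) * np.nan

    conc = {m.id: float(y_end[model.met_index[m.id]]) for m in pathway.metabolites}
    fluxes = (model.flux_dict(y_end) if np.all(np.isfinite(y_end))
              else {r.id: float("nan") for r in pathway.reactions})
    for rid in INACTIVE_REACTIONS & set(fluxes):
        fluxes[rid] = 0.0
    v34 = fluxes.get(SG_DENOMINATOR_FLUX, 0.0)
    v35 = fluxes.get(SG_NUMERATOR_FLUX, 0.0)
    sg = v35 / v34 if v34 > 0 else float("nan")
    return SteadyState(conc, fluxes, float(sg), bool(converged), float(res))


def _newton_polish(model: CompiledModel, y_end: np.ndarray) -> np.ndarray:
    """Refine internal metabolites with a root solve; keep only safe results.

    Sinks have no steady state (they accumulate), so only internal species
    are solved; the polished point must stay non-negative and within 5%
    (relative, 1e-3 µM floor) of the integrated endpoint.
    """
    idx = model.internal_idx

    def fun(x):
        y = y_end.copy()
        y[idx] = x
        return model.rhs(0.0, y)[idx]

    try:
        sol = root(fun, y_end[idx], method="hybr", options={"xtol": 1e-12})
    except Exception:
        return y_end
    if not sol.success:
        return y_end
    x = sol.x
    ref = np.maximum(np.abs(y_end[idx]), 1e-3)
    if np.any(x < -1e-12) or np.any(np.abs(x - y_end[idx]) > 0.05 * ref):
        return y_end
    y = y_end.copy()
    y[idx] = np.maximum(x, 0.0)
    return y


def calibrate_phenylalanine(
    pathway: PathwayDefinition,
    params: KineticParameterSet,
    wt_proteins: Mapping[str, float],
    target_sg: float,
    bracket: tuple[float, float] = (0.01, 100.0),
    n_scan: int = 13,
    xtol: float = 1e-8,
    **solve_kw,
) -> float:
    """Solve for the clamped phenylalanine (µM) giving the target S/G ratio.

    Scans a log-spaced grid over ``bracket`` for a sign change of
    S/G - target, then refines with Brent's method.
    """
    if target_sg <= 0:
        raise ValueError("target_sg must be > 0")

    def f(phe: float) -> float:
        ss = solve_steady_state(pathway, params, wt_proteins, phe, **solve_kw)
        return ss.sg_ratio - target_sg

    sg_tol = 1e-3 * target_sg  # acceptance in S/G space for tangent targets

    def scan(points, values):
        for lo, hi, flo, fhi in zip(points[:-1], points[1:],
                                    values[:-1], values[1:]):
            if np.isnan(flo) or np.isnan(fhi):
                continue
            if flo == 0.0:
                return float(lo)
            if flo * fhi < 0:
                return float(brentq(f, lo, hi, xtol=xtol))
        return None

    grid = np.geomspace(bracket[0], bracket[1], n_scan)
    vals = np.array([f(p) for p in grid])
    found = scan(grid, vals)
    # the target may sit at a tangency (an interior extremum of the S/G
    # curve): refine around the closest approach before giving up
    for _ in range(4):
        if found is not None:
            return found
        finite = np.where(np.isfinite(vals))[0]
        if len(finite) == 0:
            break
        j = finite[np.argmin(np.abs(vals[finite]))]
        if abs(vals[j]) <= sg_tol:
            return float(grid[j])
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        grid = np.geomspace(lo, hi, 9)
        vals = np.array([f(p) for p in grid])
        found = scan(grid, vals)
    if found is not None:
        return found
    sg_seen = vals + target_sg
    finite = sg_seen[np.isfinite(sg_seen)]
    rng = (float(finite.min()), float(finite.max())) if len(finite) else (np.nan, np.nan)
    raise CalibrationError(
        f"S/G ratio never crosses {target_sg} on phe in "
        f"[{bracket[0]}, {bracket[1]}] µM; scanned S/G range {rng}"
    )


def lhs_robustness(
    pathway: PathwayDefinition,
    params: KineticParameterSet,
    proteins: Mapping[str, float],
    phe: float,
    n_samples: int,
    ranges: Mapping[int, tuple[float, float]] | None = None,
    seed: int = 0,
    rel_tol: float = 0.01,
    **solve_kw,
) -> float:
    """Fraction of Latin-hypercube random initial conditions reaching the
    reference steady state (all internal metabolites and active fluxes within
    ``rel_tol`` relative difference).  Non-converged samples count as not-same.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    internal = pathway.internal_metabolites
    lo = np.zeros(len(internal))
    hi = np.full(len(internal), 100.0)
    if ranges is not None:
        for j, mid in enumerate(internal):
            if mid in ranges:
                lo[j], hi[j] = ranges[mid]
    if np.any(lo < 0) or np.any(hi < lo):
        raise ValueError("LHS ranges must be non-negative with hi >= lo")

    ref = solve_steady_state(pathway, params, proteins, phe, **solve_kw)
    if not ref.converged:
        warnings.warn("reference steady state did not converge; robustness is 0")
        return 0.0
    ref_c = np.array([ref.metabolite_conc[m] for m in internal])
    active_ids = [r.id for r in pathway.reactions if r.active]
    ref_f = np.array([ref.fluxes[i] for i in active_ids])

    sampler = qmc.LatinHypercube(d=len(internal), seed=seed)
    pts = qmc.scale(sampler.random(n_samples), lo, hi)
    same = 0
    for row in pts:
        init = dict(zip(internal, row))
        ss = solve_steady_state(pathway, params, proteins, phe, init=init, **solve_kw)
        if not ss.converged:
            continue
        c = np.array([ss.metabolite_conc[m] for m in internal])
        fl = np.array([ss.fluxes[i] for i in active_ids])
        ok_c = np.abs(c - ref_c) <= rel_tol * np.maximum(np.abs(ref_c), _RESIDUAL_FLOOR)
        ok_f = np.abs(fl - ref_f) <= rel_tol * np.maximum(np.abs(ref_f), _RESIDUAL_FLOOR)
        if ok_c.all() and ok_f.all():
            same += 1
    return same / n_samples
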