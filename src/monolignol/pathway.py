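"""Monolignol pathway grid: topology, gene families, and kinetic parameter registry.

The pathway converts phenylalanine (metabolite 1) through a grid of
hydroxylation, O-methylation, CoA-ligation, and reduction steps into the
three monolignols: 4-coumaryl alcohol (20, H-lignin precursor), coniferyl
alcohol (22, G), and sinapyl alcohol (24, S).  The grid has 24 metabolites
and 37 enzymatic reactions catalysed by 21 genes grouped into 10 families.
Four reactions (16, 20, 21, 26) have no measured kinetics and are held at
zero flux.

Topology and parameters are plain JSON documents; a default transcription of
the grid ships with the package (``load_default_pathway``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "SchemaError",
    "Metabolite",
    "Reaction",
    "Inhibition",
    "PathwayDefinition",
    "ComplexSpec",
    "KineticParameterSet",
    "build_pathway",
    "load_default_pathway",
    "load_default_kinetics",
    "GENES",
    "GENE_FAMILIES",
    "INACTIVE_REACTIONS",
    "SOURCE_METABOLITE",
    "SINK_METABOLITES",
    "SG_NUMERATOR_FLUX",
    "SG_DENOMINATOR_FLUX",
]

#: The 21 monolignol biosynthesis genes of P. trichocarpa used here.
GENES = (
    "PtrPAL1", "PtrPAL2", "PtrPAL3", "PtrPAL4", "PtrPAL5",
    "PtrC4H1", "PtrC4H2",
    "PtrC3H3",
    "Ptr4CL3", "Ptr4CL5",
    "PtrHCT1", "PtrHCT6",
    "PtrCCoAOMT1", "PtrCCoAOMT2", "PtrCCoAOMT3",
    "PtrCCR2",
    "PtrCAld5H1", "PtrCAld5H2",
    "PtrAldOMT2",
    "PtrCAD1", "PtrCAD2",
)

#: Gene -> family map (10 families).
GENE_FAMILIES: Mapping[str, str] = {
    g: (
        "PAL" if g.startswith("PtrPAL")
        else "C4H" if g.startswith("PtrC4H")
        else "C3H" if g.startswith("PtrC3H")
        else "4CL" if g.startswith("Ptr4CL")
        else "HCT" if g.startswith("PtrHCT")
        else "CCoAOMT" if g.startswith("PtrCCoAOMT")
        else "CCR" if g.startswith("PtrCCR")
        else "CAld5H" if g.startswith("PtrCAld5H")
        else "AldOMT" if g.startswith("PtrAldOMT")
        else "CAD"
    )
    for g in GENES
}

INACTIVE_REACTIONS = frozenset({16, 20, 21, 26})
SOURCE_METABOLITE = 1
SINK_METABOLITES = frozenset({20, 22, 24})
#: S/G ratio = V35 / V34 (sinapyl- over coniferyl-alcohol-forming flux).
SG_NUMERATOR_FLUX = 35
SG_DENOMINATOR_FLUX = 34


class SchemaError(ValueError):
    """A pathway or kinetics document violates its schema."""


@dataclass(frozen=True)
class Metabolite:
    id: int
    name: str
    role: str  # source | internal | sink


@dataclass(frozen=True)
class Reaction:
    id: int
    substrate: int
    product: int
    enzymes: tuple[str, ...]
    family: str
    active: bool = True


@dataclass(frozen=True)
class Inhibition:
    inhibitor: int       # metabolite id
    reaction: int        # target flux id
    mechanism: str = "competitive"  # competitive | uncompetitive | noncompetitive


_MECHANISMS = {"competitive", "uncompetitive", "noncompetitive"}


@dataclass(frozen=True)
class PathwayDefinition:
    """Validated grid topology: metabolites, reactions, inhibitions, families."""

    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    inhibitions: tuple[Inhibition, ...]
    gene_families: Mapping[str, str]

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise SchemaError(f"duplicate metabolite id(s): {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise SchemaError(f"duplicate reaction id(s): {dup}")
        known = set(met_ids)
        for r in self.reactions:
            for m in (r.substrate, r.product):
                if m not in known:
                    raise SchemaError(
                        f"reaction {r.id} references unknown metabolite {m}"
                    )
            for g in r.enzymes:
                if g not in self.gene_families:
                    raise SchemaError(f"reaction {r.id} references unknown gene {g}")
        for inh in self.inhibitions:
            if inh.inhibitor not in known:
                raise SchemaError(
                    f"inhibition of reaction {inh.reaction} references unknown "
                    f"metabolite {inh.inhibitor}"
                )
            if inh.reaction not in set(rxn_ids):
                raise SchemaError(
                    f"inhibition by metabolite {inh.inhibitor} references unknown "
                    f"reaction {inh.reaction}"
                )
            if inh.mechanism not in _MECHANISMS:
                raise SchemaError(
                    f"inhibition ({inh.inhibitor} -| {inh.reaction}): unknown "
                    f"mechanism {inh.mechanism!r}"
                )
        sources = [m.id for m in self.metabolites if m.role == "source"]
        if sources != [SOURCE_METABOLITE]:
            raise SchemaError(f"expected unique source metabolite 1, got {sources}")
        sinks = {m.id for m in self.metabolites if m.role == "sink"}
        if sinks != set(SINK_METABOLITES):
            raise SchemaError(f"expected sink metabolites {sorted(SINK_METABOLITES)},"
                              f" got {sorted(sinks)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def metabolite_ids(self) -> tuple[int, ...]:
        return tuple(m.id for m in self.metabolites)

    @property
    def reaction_ids(self) -> tuple[int, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def internal_metabolites(self) -> tuple[int, ...]:
        return tuple(m.id for m in self.metabolites if m.role == "internal")

    @property
    def families(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.gene_families:
            f = self.gene_families[g]
            if f not in seen:
                seen.append(f)
        return tuple(seen)

    def family_members(self, family: str) -> tuple[str, ...]:
        return tuple(g for g, f in self.gene_families.items() if f == family)

    def reaction(self, rid: int) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def to_dict(self) -> dict:
        return {
            "metabolites": [vars(m).copy() for m in self.metabolites],
            "reactions": [
                {"id": r.id, "substrate": r.substrate, "product": r.product,
                 "enzymes": list(r.enzymes), "family": r.family, "active": r.active}
                for r in self.reactions
            ],
            "inhibitions": [vars(i).copy() for i in self.inhibitions],
            "gene_families": dict(self.gene_families),
        }


def build_pathway(source: str | Path | Mapping) -> PathwayDefinition:
    """Parse and validate a pathway-definition document (JSON path or mapping)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = source
    try:
        metabolites = tuple(
            Metabolite(id=int(m["id"]), name=str(m["name"]), role=str(m["role"]))
            for m in doc["metabolites"]
        )
        reactions = tuple(
            Reaction(
                id=int(r["id"]),
                substrate=int(r["substrate"]),
                product=int(r["product"]),
                enzymes=tuple(r["enzymes"]),
                family=str(r["family"]),
                active=bool(r.get("active", True)),
            )
            for r in doc["reactions"]
        )
        inhibitions = tuple(
            Inhibition(
                inhibitor=int(i["inhibitor"]),
                reaction=int(i["reaction"]),
                mechanism=str(i.get("mechanism", "competitive")),
            )
            for i in doc.get("inhibitions", [])
        )
        gene_families = dict(doc["gene_families"])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed pathway document: {exc}") from exc
    return PathwayDefinition(metabolites, reactions, inhibitions, gene_families)


# ---------------------------------------------------------------------------
# Kinetic parameter registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexSpec:
    """The Ptr4CL3/Ptr4CL5 heterotetramer (3:1) acting on reactions 7 and 8.

    ``stoichiometry`` gives monomers per complex; the complex concentration is
    ``min_g(P_g / stoich_g)``.  Leftover monomers keep monomer kinetics when
    ``leftover_active`` (the default).
    """

    stoichiometry: Mapping[str, int]          # e.g. {"Ptr4CL3": 3, "Ptr4CL5": 1}
    reactions: tuple[int, ...]                # affected flux ids
    params: Mapping[int, tuple[float, float]]  # reaction -> (kcat, Km)
    leftover_active: bool = True


@dataclass(frozen=True)
class KineticParameterSet:
    """kcat/Km per (reaction, enzyme), Ki per inhibition, and the 4CL complex."""

    reaction_params: Mapping[tuple[int, str], tuple[float, float]]
    inhibition_params: Mapping[tuple[int, int], float]  # (inhibitor, reaction) -> Ki
    complex_spec: ComplexSpec | None = None

    def validate(self, pathway: PathwayDefinition) -> None:
        for (rid, gene), (kcat, km) in self.reaction_params.items():
            if kcat <= 0 or km <= 0:
                raise SchemaError(
                    f"non-positive kcat/Km for reaction {rid}, enzyme {gene}"
                )
        declared = {(i.inhibitor, i.reaction) for i in pathway.inhibitions}
        for key, ki in self.inhibition_params.items():
            if key not in declared:
                raise SchemaError(f"Ki given for undeclared inhibition {key}")
            if ki <= 0:
                raise SchemaError(f"non-positive Ki for inhibition {key}")
        covered = {rid for (rid, _g) in self.reaction_params}
        if self.complex_spec is not None:
            for rid, (kcat, km) in self.complex_spec.params.items():
                if kcat <= 0 or km <= 0:
                    raise SchemaError(f"non-positive complex kcat/Km, reaction {rid}")
            covered |= set(self.complex_spec.params)
        for r in pathway.reactions:
            if r.active and r.id not in covered:
                raise SchemaError(
                    f"active reaction {r.id} has no kinetic parameters"
                )

    def to_dict(self) -> dict:
        out: dict = {
            "reaction_params": [
                {"reaction": rid, "enzyme": g, "kcat": kc, "km": km}
                for (rid, g), (kc, km) in sorted(self.reaction_params.items())
            ],
            "inhibition_params": [
                {"inhibitor": im, "reaction": rid, "ki": ki}
                for (im, rid), ki in sorted(self.inhibition_params.items())
            ],
        }
        if self.complex_spec is not None:
            cs = self.complex_spec
            out["complex"] = {
                "stoichiometry": dict(cs.stoichiometry),
                "reactions": list(cs.reactions),
                "params": [
                    {"reaction": rid, "kcat": kc, "km": km}
                    for rid, (kc, km) in sorted(cs.params.items())
                ],
                "leftover_active": cs.leftover_active,
            }
        return out

    @classmethod
    def from_dict(cls, doc: Mapping) -> "KineticParameterSet":
        try:
            rp = {
                (int(e["reaction"]), str(e["enzyme"])): (float(e["kcat"]), float(e["km"]))
                for e in doc["reaction_params"]
            }
            ip = {
                (int(e["inhibitor"]), int(e["reaction"])): float(e["ki"])
                for e in doc.get("inhibition_params", [])
            }
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed kinetics document: {exc}") from exc
        cs = None
        if "complex" in doc:
            c = doc["complex"]
            cs = ComplexSpec(
                stoichiometry={str(k): int(v) for k, v in c["stoichiometry"].items()},
                reactions=tuple(int(r) for r in c["reactions"]),
                params={
                    int(e["reaction"]): (float(e["kcat"]), float(e["km"]))
                    for e in c["params"]
                },
                leftover_active=bool(c.get("leftover_active", True)),
            )
        return cls(rp, ip, cs)

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _data_text(name: str) -> str:
    return resources.files("monolignol.data").joinpath(name).read_text()


def load_default_pathway() -> PathwayDefinition:
    """The packaged monolignol grid (24 metabolites, 37 reactions)."""
    return build_pathway(json.loads(_data_text("pathway.json")))


def load_default_kinetics() -> KineticParameterSet:
    """The packaged synthetic kinetic registry, tuned so the wildtype protein
    profile yields S/G = 2.16 at 1.4 µM phenylalanine (see ``data/README``
    note in the registry itself)."""
    return KineticParameterSet.from_dict(json.loads(_data_text("kinetics.json")))
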