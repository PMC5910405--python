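"""Regenerate src/monolignol/data/pathway.json (the packaged grid topology).

The grid: 24 metabolites, 37 reactions over 10 enzyme families, with
reactions 16, 20, 21 and 26 inactive (no measured kinetics) and the three
monolignols (20, 22, 24) as accumulating sinks.  Run from the repo root:

    python scripts/make_pathway_data.py
"""

import json
from pathlib import Path

METABOLITES = [
    (1, "phenylalanine", "source"),
    (2, "cinnamic acid", "internal"),
    (3, "p-coumaric acid", "internal"),
    (4, "caffeic acid", "internal"),
    (5, "ferulic acid", "internal"),
    (6, "5-hydroxyferulic acid", "internal"),
    (7, "sinapic acid", "internal"),
    (8, "p-coumaroyl-CoA", "internal"),
    (9, "caffeoyl-CoA", "internal"),
    (10, "feruloyl-CoA", "internal"),
    (11, "5-hydroxyferuloyl-CoA", "internal"),
    (12, "sinapoyl-CoA", "internal"),
    (13, "p-coumaroyl shikimate", "internal"),
    (14, "caffeoyl shikimate", "internal"),
    (15, "p-coumaraldehyde", "internal"),
    (16, "caffealdehyde", "internal"),
    (17, "coniferaldehyde", "internal"),
    (18, "5-hydroxyconiferaldehyde", "internal"),
    (19, "sinapaldehyde", "internal"),
    (20, "4-coumaryl alcohol", "sink"),
    (21, "caffeyl alcohol", "internal"),
    (22, "coniferyl alcohol", "sink"),
    (23, "5-hydroxyconiferyl alcohol", "internal"),
    (24, "sinapyl alcohol", "sink"),
]

# (flux id, substrate, product, family).  Parallel conversions by different
# families carry distinct flux ids (e.g. 15 vs 31).
REACTIONS = [
    (1, 1, 2, "PAL"),
    (2, 2, 3, "C4H"),
    (3, 3, 4, "C3H"),
    (4, 4, 5, "AldOMT"),
    (5, 5, 6, "CAld5H"),
    (6, 6, 7, "AldOMT"),
    (7, 3, 8, "4CL"),
    (8, 4, 9, "4CL"),
    (9, 5, 10, "4CL"),
    (10, 6, 11, "4CL"),
    (11, 7, 12, "4CL"),
    (12, 8, 13, "HCT"),
    (13, 13, 14, "C3H"),
    (14, 14, 9, "HCT"),
    (15, 9, 10, "CCoAOMT"),
    (16, 10, 11, "CAld5H"),    # inactive
    (17, 11, 12, "CCoAOMT"),
    (18, 8, 15, "CCR"),
    (19, 10, 17, "CCR"),
    (20, 9, 16, "CCR"),        # inactive
    (21, 11, 18, "CCR"),       # inactive
    (22, 12, 19, "CCR"),
    (23, 15, 16, "C3H"),
    (24, 17, 18, "CAld5H"),
    (25, 18, 19, "AldOMT"),
    (26, 16, 17, "AldOMT"),    # inactive
    (27, 15, 20, "CAD"),
    (28, 8, 9, "C3H"),
    (29, 16, 21, "CAD"),
    (30, 21, 22, "AldOMT"),
    (31, 9, 10, "AldOMT"),
    (32, 18, 23, "CAD"),
    (33, 23, 24, "AldOMT"),
    (34, 17, 22, "CAD"),       # coniferyl-alcohol-forming flux (G)
    (35, 19, 24, "CAD"),       # sinapyl-alcohol-forming flux (S)
    (36, 13, 8, "HCT"),
    (37, 9, 14, "HCT"),
]

INACTIVE = {16, 20, 21, 26}

# (inhibitor metabolite, target flux, mechanism)
INHIBITIONS = [
    (4, 7, "competitive"),
    (5, 7, "competitive"),
    (3, 9, "competitive"),
    (7, 9, "competitive"),
    (5, 4, "competitive"),
    (7, 6, "competitive"),
    (14, 12, "competitive"),
    (8, 14, "competitive"),
    (10, 15, "uncompetitive"),
    (12, 17, "competitive"),
    (15, 18, "noncompetitive"),
    (17, 19, "competitive"),
    (19, 24, "competitive"),
    (18, 25, "noncompetitive"),
    (19, 25, "competitive"),
    (17, 27, "competitive"),
    (19, 34, "competitive"),
    (17, 35, "competitive"),
]


def main() -> None:
    import sys
    sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
    from monolignol.pathway import GENE_FAMILIES, build_pathway

    by_family: dict[str, list[str]] = {}
    for gene, fam in GENE_FAMILIES.items():
        by_family.setdefault(fam, []).append(gene)

    doc = {
        "metabolites": [
            {"id": i, "name": n, "role": r} for i, n, r in METABOLITES
        ],
        "reactions": [
            {
                "id": rid,
                "substrate": s,
                "product": p,
                "enzymes": by_family[fam],
                "family": fam,
                "active": rid not in INACTIVE,
            }
            for rid, s, p, fam in REACTIONS
        ],
        "inhibitions": [
            {"inhibitor": m, "reaction": r, "mechanism": mech}
            for m, r, mech in INHIBITIONS
        ],
        "gene_families": dict(GENE_FAMILIES),
    }
    build_pathway(doc)  # validate before writing
    out = Path(__file__).resolve().parents[1] / "src" / "monolignol" / "data" / "pathway.json"
    out.write_text(json.dumps(doc, indent=1) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
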