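"""Table readers/writers, run configuration and provenance.

Canonical table dialect is TSV with '.' decimal separator.  Omics tables
(transcripts, proteins) are tidy: ``line_id, batch, genotype, gene_id,
value``.  Trait tables are wide — a ``line_id`` column plus one column per
trait — with a second header row carrying units.  Models and configs are
JSON.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pathway import GENES
from .traits import TRAITS, TRAIT_NAMES
from .translation import OMICS_COLUMNS

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_table",
    "write_omics_table",
    "write_trait_table",
    "write_provenance",
]


class ValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    """Run-wide configuration (paths, seed, tolerances, search caps)."""

    pathway: str | None = None
    kinetics: str | None = None
    seed: int = 0
    steady_state_tol: float = 1e-6
    calibration_tol: float = 1e-4
    sameness_tol: float = 0.01
    max_terms: int = 5
    n_folds: int = 5
    levels: tuple[float, ...] = (0.05, 10.0)
    max_modified: int = 3
    target_sg: float = 2.16
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("steady_state_tol", "calibration_tol", "sameness_tol"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "levels" in doc:
            doc["levels"] = tuple(float(x) for x in doc["levels"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["levels"] = list(self.levels)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_UNIT_BY_TRAIT = {t.name: t.unit for t in TRAITS}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV table against a named schema.

    Schemas: ``transcripts`` / ``proteins`` (tidy omics tables) and
    ``traits`` (wide, with a units header row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema in ("transcripts", "proteins"):
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in OMICS_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing column(s) {missing}")
        bad = df.index[df["value"] < 0]
        if len(bad):
            raise ValidationError(
                f"{path}: negative abundance at row {int(bad[0]) + 2}"
            )
        unknown = sorted(set(df["gene_id"]) - set(GENES))
        if unknown:
            rows = df.index[df["gene_id"].isin(unknown)]
            raise ValidationError(
                f"{path}: unknown gene id(s) {unknown} (first at row "
                f"{int(rows[0]) + 2})"
            )
        return df
    if schema == "traits":
        head = pd.read_csv(path, sep="\t", nrows=1)
        df = pd.read_csv(path, sep="\t", skiprows=[1])
        if "line_id" not in df.columns:
            raise ValidationError(f"{path}: missing line_id column")
        unknown = [c for c in df.columns if c != "line_id" and c not in TRAIT_NAMES]
        if unknown:
            raise ValidationError(f"{path}: unknown trait column(s) {unknown}")
        return df.set_index("line_id")
    raise ValueError(f"unknown schema {schema!r}")


def write_omics_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_trait_table(traits: pd.DataFrame, path) -> None:
    """Wide trait TSV with a units row under the header."""
    units = [ _UNIT_BY_TRAIT.get(c, "") for c in traits.columns]
    with open(path, "w") as fh:
        fh.write("line_id\t" + "\t".join(traits.columns) + "\n")
        fh.write("unit\t" + "\t".join(units) + "\n")
        traits.to_csv(fh, sep="\t", header=False, float_format="%.12g")


def write_provenance(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Record config hash, seed and versions alongside run outputs."""
    import monolignol

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "versions": {
            "monolignol": getattr(monolignol, "__version__", "unknown"),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        doc.update(extra)
    path = out_dir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path
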