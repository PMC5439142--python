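"""File formats and run configuration.

Everything is plain CSV/YAML with explicit headers: pedigree
(``animal,sire,dam``), records (``animal,cg,...,y``), genotypes
(``animal,snp...`` or PLINK RAW), labelled matrices, the pairwise report, and
``scenario.yaml`` for the simulator.  Every writer round-trips through its
reader exactly (labels/integers) or to 1e-12 (reals).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomic import GenotypeMatrix, write_genotypes_csv
from .mme import VarianceComponents
from .model_design import ModelSpec
from .pedigree import Pedigree, write_pedigree_csv
from .simdata import SimScenario, simulate_genotypes, simulate_pedigree_and_records


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Everything a `connect fit` run needs."""

    pedigree: Path
    records: Path
    model: ModelSpec
    vc: VarianceComponents
    relationship: str = "A"
    genotypes: Path | None = None
    blend_weight: float = 0.95
    out_dir: Path = Path("connect_out")
    dense_pev_limit: int = 5000
    pev_direct: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.relationship not in ("A", "H"):
            raise ConfigError("relationship must be 'A' or 'H'")
        if self.relationship == "H" and self.genotypes is None:
            raise ConfigError("relationship 'H' requires a genotype file")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        try:
            vc = VarianceComponents(**d["variance_components"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad variance_components in {path}: {exc}") from exc
        cfg = cls(
            pedigree=Path(d["pedigree"]),
            records=Path(d["records"]),
            model=ModelSpec.from_dict(d.get("model", {})),
            vc=vc,
            relationship=d.get("relationship", "A"),
            genotypes=Path(d["genotypes"]) if d.get("genotypes") else None,
            blend_weight=float(d.get("blend_weight", 0.95)),
            out_dir=Path(d.get("out_dir", "connect_out")),
            dense_pev_limit=int(d.get("dense_pev_limit", 5000)),
            pev_direct=bool(d.get("pev_direct", True)),
            seed=int(d.get("seed", 0)),
        )
        for p in (cfg.pedigree, cfg.records, cfg.genotypes):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        return cfg


def write_labelled_matrix(values: np.ndarray, labels, path) -> None:
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(path)


def read_labelled_matrix(path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["animal"] = df["animal"].astype(str)
    if "cg" in df.columns:
        df["cg"] = df["cg"].astype(str)
    return df


def write_scenario_yaml(sc: SimScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sc.to_dict(), fh, sort_keys=False)


def read_scenario_yaml(path) -> SimScenario:
    with open(path) as fh:
        return SimScenario.from_dict(yaml.safe_load(fh))


def write_diagnostics_json(bundle_dict: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(bundle_dict, fh, indent=2)


def run_simulate(scenario_file, out_dir) -> Path:
    """Simulate a dataset directory from a scenario file.

    Writes ``pedigree.csv``, ``records.csv``, ``scenario.yaml`` and, when
    markers are requested, ``genotypes.csv``.
    """
    sc = read_scenario_yaml(scenario_file)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped, records = simulate_pedigree_and_records(sc)
    write_pedigree_csv(ped, out / "pedigree.csv")
    write_records_csv(records, out / "records.csv")
    write_scenario_yaml(sc, out / "scenario.yaml")
    if sc.n_markers > 0 and sc.genotyped_fraction > 0:
        geno = simulate_genotypes(ped, sc)
        write_genotypes_csv(geno, out / "genotypes.csv")
    return out
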