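"""File formats, validation and run configuration.

All interchange files are UTF-8, comma-delimited, ``.`` decimal, with a
mandatory header.  Missing yields are encoded as empty fields and are never
imputed; mixed models use available cases.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "IntegrityError",
    "TrialTable",
    "RunConfig",
    "SE_LABELS",
    "read_trials",
    "read_pedigree",
    "read_covariates",
    "read_table",
    "write_results",
    "write_table",
]

#: Managed selection environments at the breeding station.
SE_LABELS = ("B5IR", "F5IR", "B2IR", "FDRT", "BLHT")

TRIAL_COLUMNS = (
    "cycle_year",
    "site_id",
    "group_label",
    "group_kind",
    "replicate",
    "sub_block",
    "genotype_id",
    "is_local_check",
    "grain_yield",
)

TRIAL_KEY = ("site_id", "cycle_year", "replicate", "sub_block", "genotype_id")


class SchemaError(ValueError):
    """A file does not have the required columns/types."""


class IntegrityError(ValueError):
    """A file violates a structural invariant (duplicates, bad references)."""


@dataclass(frozen=True)
class TrialTable:
    """Long-format phenotype records of a trial network.

    One row per plot: trial year, site, TPE/SE group, replicate, alpha-lattice
    sub-block, genotype and grain yield (t/ha, NaN when missing).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_trials(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))

    @property
    def n_missing(self) -> int:
        return int(self.df["grain_yield"].isna().sum())

    def genetic_subset(self, include_checks: bool = False) -> pd.DataFrame:
        """Rows entering across-site genetic analyses.

        Local checks differ between sites and are excluded by default.
        """
        if include_checks:
            return self.df.copy()
        return self.df.loc[~self.df["is_local_check"]].copy()

    def to_csv(self, path: str | Path) -> None:
        write_table(self.df, path)

    @classmethod
    def read_csv(cls, path: str | Path, delimiter: str = ",") -> "TrialTable":
        return read_trials(path, delimiter=delimiter)


def _validate_trials(df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table is missing required column(s): {', '.join(missing)}")
    bad_kind = set(df["group_kind"].unique()) - {"TPE", "SE"}
    if bad_kind:
        raise SchemaError(f"group_kind must be 'TPE' or 'SE'; found {sorted(bad_kind)}")
    dup = df.duplicated(subset=list(TRIAL_KEY), keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, list(TRIAL_KEY)]
            .drop_duplicates()
            .to_dict(orient="records")
        )
        raise IntegrityError(
            f"duplicate (site, year, replicate, sub_block, genotype) rows: {offenders[:10]}"
        )
    if len(df) and (df["grain_yield"].dropna() < 0).any():
        raise IntegrityError("grain_yield must be nonnegative")


def read_trials(path: str | Path, delimiter: str = ",") -> TrialTable:
    """Read, type and validate a phenotype CSV.

    Missing yields (empty fields) are kept as NaN, never dropped.
    """
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(TRIAL_COLUMNS)]
    df = df.astype(
        {
            "cycle_year": np.int64,
            "site_id": str,
            "group_label": str,
            "group_kind": str,
            "replicate": np.int64,
            "sub_block": np.int64,
            "genotype_id": str,
            "is_local_check": bool,
            "grain_yield": float,
        }
    )
    return TrialTable(df)


def read_pedigree(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read a three-column pedigree CSV (id, parent1, parent2; '0' = unknown)."""
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    required = ["id", "parent1", "parent2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df.loc[:, required].fillna("0")
    return df


def read_covariates(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read a long-format covariate CSV (site_id, variable, window, value).

    Window ``0`` denotes a static soil variable.
    """
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    required = ["site_id", "variable", "window", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df.astype({"site_id": str, "variable": str, "window": np.int64, "value": float})


def read_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as comma-delimited UTF-8 text with header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def write_results(obj: Any, path: str | Path) -> Path:
    """Write a pipeline result to delimited or structured text.

    DataFrames and objects exposing ``to_frame()`` become CSV; mappings become
    JSON.  Reading a written table back reproduces it.
    """
    path = Path(path)
    if isinstance(obj, TrialTable):
        return write_table(obj.df, path)
    if isinstance(obj, pd.DataFrame):
        return write_table(obj, path)
    if hasattr(obj, "to_frame"):
        return write_table(obj.to_frame(), path)
    if isinstance(obj, Mapping):
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True), encoding="utf-8")
        return path
    raise TypeError(f"cannot serialise object of type {type(obj).__name__}")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Options shared by the CLI stages.

    The seed is always recorded; every stage writes a manifest containing the
    digest of the configuration it ran under, so outputs are traceable.
    """

    seed: int = 0
    out_dir: str = "results"
    model: str = "eq4"
    reml_tol: float = 1e-8
    gibbs_iterations: int = 12_000
    gibbs_burn_in: int = 2_000
    gibbs_thin: int = 5
    gibbs_chains: int = 2
    window_start: str = "11-23"
    window_days: int = 20
    n_windows: int = 6
    cluster_k: int = 3
    include_local_checks: bool = False
    extra: dict = field(default_factory=dict)

    def digest(self) -> str:
        """Stable SHA-256 digest of the configuration contents."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        return cls(**kwargs)

    def write_manifest(self, out_dir: str | Path, stage: str) -> Path:
        import tpemet

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "stage": stage,
            "seed": self.seed,
            "config_digest": self.digest(),
            "package_version": tpemet.__version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        }
        path = out_dir / f"manifest_{stage}.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
        return path
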