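"""Feature-table data model: container, file IO, schema handling, validation.

A :class:`FeatureDataset` holds one row per participant with a group label,
nuisance covariates (age, sex, total intracranial volume, ...), a grey-matter
morphometry block (e.g. 68 Desikan-Killiany cortical thickness or surface-area
values), a white-matter block (e.g. 48 JHU tract FA values) and cognition
scores. Tables travel as delimited text (CSV/TSV) plus a column→role schema
(YAML/JSON), so the pipeline starts where image preprocessing ends.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    AlignmentError,
    ConfigError,
    ParseError,
    SchemaError,
    ValidationError,
)

ROLES = ("id", "group", "covariate", "gm", "wm", "cognition", "ignore")

MIN_GROUP_SIZE = 4  # Pearson correlation needs at least 4 observations


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis.

    Resampling defaults (10,000 permutations / 10,000 bootstrap iterations)
    match common practice for salience inference at this scale; scale them
    down for interactive work.
    """

    gm_measure: str = "thickness"  # 'thickness' | 'surface_area'
    covariates_rows: Optional[Sequence[str]] = None  # pair with WM (row margin)
    covariates_cols: Optional[Sequence[str]] = None  # pair with GM (column margin)
    include_cov_cov: bool = True
    corr_method: str = "pearson"  # 'pearson' | 'spearman'
    n_permutations: int = 10_000
    n_bootstrap: int = 10_000
    alpha: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0
    permutation_scheme: str = "permute_wm"  # 'permute_wm' | 'permute_gm' | 'both'
    train_fraction: float = 0.8
    n_splits: int = 100
    n_min: int = 10
    n_orderings: int = 10

    def __post_init__(self):
        if self.n_permutations < 1 or self.n_bootstrap < 1:
            raise ConfigError("n_permutations and n_bootstrap must be >= 1")
        if not (0 < self.alpha < 1) or not (0 < self.fdr_q < 1):
            raise ConfigError("alpha and fdr_q must lie in (0, 1)")
        if not (0 < self.train_fraction < 1):
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.gm_measure not in ("thickness", "surface_area"):
            raise ConfigError(f"unknown gm_measure: {self.gm_measure!r}")
        if self.permutation_scheme not in ("permute_wm", "permute_gm", "both"):
            raise ConfigError(f"unknown permutation_scheme: {self.permutation_scheme!r}")
        if self.corr_method not in ("pearson", "spearman"):
            raise ConfigError(f"unknown corr_method: {self.corr_method!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("covariates_rows", "covariates_cols"):
            if d[k] is not None:
                d[k] = list(d[k])
        return d


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class FeatureDataset:
    """Participants × {group, covariates, GM block, WM block, cognition}."""

    participant_id: list
    group: np.ndarray  # string labels, one per participant
    gm: np.ndarray  # n × p
    wm: np.ndarray  # n × q
    covariates: np.ndarray  # n × c (c may be 0)
    cognition: np.ndarray  # n × k (k may be 0)
    gm_names: list
    wm_names: list
    covariate_names: list
    cognition_names: list
    wm_is_fa: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.participant_id)
        self.group = np.asarray(self.group, dtype=object)
        for name in ("gm", "wm", "covariates", "cognition"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 1:
                arr = arr.reshape(n, -1) if arr.size else arr.reshape(n, 0)
            setattr(self, name, arr)
        shapes = {
            "gm": (self.gm, self.gm_names),
            "wm": (self.wm, self.wm_names),
            "covariates": (self.covariates, self.covariate_names),
            "cognition": (self.cognition, self.cognition_names),
        }
        for block, (arr, names) in shapes.items():
            if arr.shape[0] != n:
                raise ValidationError(f"{block} has {arr.shape[0]} rows, expected {n}")
            if arr.shape[1] != len(names):
                raise ValidationError(
                    f"{block} has {arr.shape[1]} columns but {len(names)} names"
                )
        if len(set(self.participant_id)) != n:
            dupes = sorted(
                {x for x in self.participant_id if self.participant_id.count(x) > 1}
            )
            raise ValidationError(f"duplicate participant_id: {dupes}")

    # -- basic introspection ------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.participant_id)

    @property
    def group_labels(self) -> list:
        """Group labels in order of first appearance (defines stacking order)."""
        seen = dict.fromkeys(self.group.tolist())
        return list(seen)

    def group_mask(self, label) -> np.ndarray:
        if label not in self.group_labels:
            raise AlignmentError(
                f"unknown group label {label!r}; known groups: {self.group_labels}"
            )
        return self.group == label

    def group_sizes(self) -> dict:
        return {g: int((self.group == g).sum()) for g in self.group_labels}

    def subset(self, mask: np.ndarray) -> "FeatureDataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return FeatureDataset(
            participant_id=[self.participant_id[i] for i in idx],
            group=self.group[idx],
            gm=self.gm[idx],
            wm=self.wm[idx],
            covariates=self.covariates[idx],
            cognition=self.cognition[idx],
            gm_names=list(self.gm_names),
            wm_names=list(self.wm_names),
            covariate_names=list(self.covariate_names),
            cognition_names=list(self.cognition_names),
            wm_is_fa=self.wm_is_fa,
            provenance=dict(self.provenance),
        )

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {"participant_id": self.participant_id, "group": self.group}
        for names, arr in (
            (self.covariate_names, self.covariates),
            (self.gm_names, self.gm),
            (self.wm_names, self.wm),
            (self.cognition_names, self.cognition),
        ):
            for j, name in enumerate(names):
                cols[name] = arr[:, j]
        return pd.DataFrame(cols)

    def schema(self) -> dict:
        sch = {"participant_id": "id", "group": "group"}
        sch.update({c: "covariate" for c in self.covariate_names})
        sch.update({c: "gm" for c in self.gm_names})
        sch.update({c: "wm" for c in self.wm_names})
        sch.update({c: "cognition" for c in self.cognition_names})
        return sch

    def write(self, path, schema_path=None, sep: str = ","):
        """Write the feature table (CSV/TSV) and, optionally, its schema YAML."""
        self.to_frame().to_csv(path, sep=sep, index=False)
        if schema_path is not None:
            Path(schema_path).write_text(yaml.safe_dump(self.schema(), sort_keys=False))


# ---------------------------------------------------------------------------
# loading


def _read_schema(schema) -> dict:
    if isinstance(schema, dict):
        return dict(schema)
    text = Path(schema).read_text()
    if str(schema).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_feature_table(path, schema, on_missing: str = "error") -> FeatureDataset:
    """Read a delimited feature table into a validated :class:`FeatureDataset`.

    Parameters
    ----------
    path : str or Path
        CSV or TSV file with a header row; the delimiter is sniffed from the
        extension ('.tsv' → tab) or falls back to comma.
    schema : dict or path
        Mapping column name → role, roles in {id, group, covariate, gm, wm,
        cognition, ignore}. May be a YAML/JSON file path.
    on_missing : {'error', 'drop'}
        'error' raises :class:`ParseError` naming the first missing cell;
        'drop' removes participants with any missing brain/covariate value
        (listwise deletion) and records them under
        ``provenance['dropped_participants']``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=object)
    return dataset_from_frame(df, schema, on_missing=on_missing, source=str(path))


def dataset_from_frame(
    df: pd.DataFrame, schema, on_missing: str = "error", source: str = "<frame>"
) -> FeatureDataset:
    """Build a :class:`FeatureDataset` from an in-memory table plus a schema."""
    df = df.astype(object)
    schema = _read_schema(schema)
    bad_roles = {c: r for c, r in schema.items() if r not in ROLES}
    if bad_roles:
        raise SchemaError(f"unknown roles in schema: {bad_roles}")

    missing_cols = [c for c in schema if schema[c] != "ignore" and c not in df.columns]
    if missing_cols:
        raise SchemaError(f"schema columns missing from table: {missing_cols}")

    by_role: dict = {r: [] for r in ROLES}
    for col in df.columns:  # preserve file column order within each block
        role = schema.get(col)
        if role is None:
            raise SchemaError(f"column {col!r} present in table but not in schema")
        by_role[role].append(col)

    if len(by_role["id"]) != 1:
        raise SchemaError(f"schema must map exactly one 'id' column, got {by_role['id']}")
    if len(by_role["group"]) != 1:
        raise SchemaError(
            f"schema must map exactly one 'group' column, got {by_role['group']}"
        )

    id_col, group_col = by_role["id"][0], by_role["group"][0]
    ids = df[id_col].astype(str).tolist()
    groups = df[group_col].astype(str).to_numpy(dtype=object)

    sex_codings: dict = {}

    def numeric_block(cols: list) -> np.ndarray:
        out = np.empty((len(df), len(cols)), dtype=float)
        for j, col in enumerate(cols):
            raw = df[col]
            # categorical covariates with two levels (e.g. sex) → 0/1 by
            # lexicographic label order, deterministically
            values = pd.to_numeric(raw, errors="coerce")
            nonnum = raw.notna() & values.isna()
            if nonnum.any():
                levels = sorted(raw.dropna().unique())
                if schema[col] == "covariate" and len(levels) == 2:
                    values = raw.map({levels[0]: 0.0, levels[1]: 1.0})
                    sex_codings[col] = {levels[0]: 0, levels[1]: 1}
                else:
                    row = int(np.flatnonzero(nonnum)[0])
                    raise ParseError(
                        f"non-numeric value {raw.iloc[row]!r} in column {col!r}, "
                        f"row {row + 2} (1-based, incl. header)"
                    )
            out[:, j] = values.to_numpy(dtype=float)
        return out

    blocks = {r: numeric_block(by_role[r]) for r in ("covariate", "gm", "wm", "cognition")}

    dropped = []
    na_mask = np.zeros(len(df), dtype=bool)
    for role in ("covariate", "gm", "wm"):
        na_mask |= np.isnan(blocks[role]).any(axis=1)
    if na_mask.any():
        if on_missing == "drop":
            dropped = [ids[i] for i in np.flatnonzero(na_mask)]
            keep = ~na_mask
            ids = [x for x, k in zip(ids, keep) if k]
            groups = groups[keep]
            blocks = {r: b[keep] for r, b in blocks.items()}
        else:
            for role in ("covariate", "gm", "wm"):
                nan_at = np.argwhere(np.isnan(blocks[role]))
                if nan_at.size:
                    i, j = nan_at[0]
                    raise ParseError(
                        f"missing value in column {by_role[role][j]!r}, "
                        f"row {i + 2} (1-based, incl. header)"
                    )

    ds = FeatureDataset(
        participant_id=ids,
        group=groups,
        gm=blocks["gm"],
        wm=blocks["wm"],
        covariates=blocks["covariate"],
        cognition=blocks["cognition"],
        gm_names=by_role["gm"],
        wm_names=by_role["wm"],
        covariate_names=by_role["covariate"],
        cognition_names=by_role["cognition"],
        provenance={
            "source": source,
            "dropped_participants": dropped,
            "sex_codings": sex_codings,
        },
    )
    return ds


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Findings from :func:`validate_dataset`; fatal findings block analysis."""

    group_sizes: dict
    fatal: list
    warnings: list

    @property
    def passed(self) -> bool:
        return not self.fatal

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "group_sizes": self.group_sizes,
                "fatal": self.fatal,
                "warnings": self.warnings,
            },
            indent=2,
        )


def validate_dataset(ds: FeatureDataset, config: Optional[AnalysisConfig] = None) -> ValidationReport:
    """Check a dataset against analysis preconditions. Side-effect free.

    Fatal: any group smaller than 4 (correlation undefined), zero-variance
    columns within a group, non-finite values. Out-of-range FA values are
    reported as warnings.
    """
    fatal, warnings = [], []
    sizes = ds.group_sizes()
    for g, n in sizes.items():
        if n < MIN_GROUP_SIZE:
            fatal.append(f"group {g!r} too small: n={n} < {MIN_GROUP_SIZE}")

    for block_name, arr, names in (
        ("gm", ds.gm, ds.gm_names),
        ("wm", ds.wm, ds.wm_names),
        ("covariate", ds.covariates, ds.covariate_names),
    ):
        if not np.isfinite(arr).all():
            fatal.append(f"non-finite values in {block_name} block")
            continue
        for g in ds.group_labels:
            sub = arr[ds.group == g]
            if sub.shape[0] < 2:
                continue
            sd = sub.std(axis=0, ddof=1)
            for j in np.flatnonzero(sd == 0):
                fatal.append(
                    f"zero-variance column {names[j]!r} ({block_name}) in group {g!r}"
                )

    if ds.wm_is_fa and ds.wm.size:
        out = (ds.wm < 0) | (ds.wm > 1)
        if out.any():
            i, j = np.argwhere(out)[0]
            warnings.append(
                f"{int(out.sum())} FA values outside [0, 1] "
                f"(first: {ds.wm_names[j]!r}, participant {ds.participant_id[i]!r})"
            )

    if ds.cognition.size and np.isnan(ds.cognition).any():
        warnings.append("missing values in cognition block (pairs dropped per test)")

    return ValidationReport(group_sizes=sizes, fatal=fatal, warnings=warnings)
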