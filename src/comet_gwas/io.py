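"""File formats and run configuration.

All inputs and outputs are delimited text.  Inputs accept tab or
whitespace delimiters and ``#`` comment lines; outputs are tab-delimited
with floats at 6 significant digits.

* summary statistics: header with required columns ``snp beta se`` and
  optional ``chr pos p n`` (coordinates, when present, are 1-based and
  carried through; all computation is keyed on variant id);
* annotations: wide (``snp`` plus one 0/1 column per category) or long
  (``snp category``) — auto-detected;
* LD: three columns ``snp_a snp_b r2``; pairs absent are independent;
* MAF: two columns ``snp maf``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import InvalidInputError

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """Raised when an input file does not match its format contract."""


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=r"\s+", comment="#", dtype={"snp": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file or missing header") from exc


def read_summary_stats(path) -> pd.DataFrame:
    """Read and validate a per-trait summary-statistic table.

    Rows with non-numeric, missing or non-positive ``se`` (or non-numeric
    ``beta``) are rejected with a logged count; duplicate variant ids are
    an error.  An empty table (header only) is returned with a warning.
    """
    df = _read_table(path)
    for col in ("snp", "beta", "se"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        logger.warning("%s: no data rows after header", path)
        return df
    if df["snp"].duplicated().any():
        dups = df.loc[df["snp"].duplicated(), "snp"].head(3).tolist()
        raise FormatError(f"{path}: duplicated variant ids (e.g. {dups})")
    df["beta"] = pd.to_numeric(df["beta"], errors="coerce")
    df["se"] = pd.to_numeric(df["se"], errors="coerce")
    bad = df["beta"].isna() | df["se"].isna() | ~(df["se"] > 0)
    if bad.any():
        logger.warning("%s: rejected %d rows with invalid beta/se",
                       path, int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    return df


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_annotations(path) -> pd.DataFrame:
    """Read a binary annotation matrix, wide or long format.

    Returns a 0/1 DataFrame indexed by variant id with one column per
    category.  Long format (exactly two columns ``snp category``) is
    pivoted to wide; in wide format, non-0/1 entries are a format error.
    """
    df = _read_table(path)
    if "snp" not in df.columns:
        raise FormatError(f"{path}: missing required column 'snp'")
    other = [c for c in df.columns if c != "snp"]
    if other == ["category"]:
        wide = pd.crosstab(df["snp"], df["category"]).clip(upper=1)
        wide.index.name = "snp"
        wide.columns.name = None
        return wide.astype(int)
    mat = df.set_index("snp")[other]
    vals = mat.to_numpy()
    try:
        ok = np.isin(vals.astype(float), (0.0, 1.0)).all()
    except (TypeError, ValueError):
        ok = False
    if not ok:
        raise FormatError(f"{path}: annotation entries must be 0/1")
    if mat.index.duplicated().any():
        raise FormatError(f"{path}: duplicated variant ids")
    return mat.astype(int)


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="snp")


def align_annotations(ann: pd.DataFrame, snp_ids) -> pd.DataFrame:
    """Align an annotation matrix to a variant ordering.

    Variants absent from the annotation file get all-zero rows; unknown
    variants in the annotation file are ignored.  Both are logged.
    """
    snp_ids = pd.Index(snp_ids)
    n_unknown = len(ann.index.difference(snp_ids))
    if n_unknown:
        logger.warning("%d annotated variants not in the analysis set ignored",
                       n_unknown)
    out = ann.reindex(snp_ids)
    n_missing = int(out.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%d variants without annotations assigned all-zero rows",
                       n_missing)
        out = out.fillna(0)
    return out.astype(int)


def read_ld(path) -> pd.DataFrame:
    """Read a sparse pairwise-r^2 table (snp_a, snp_b, r2)."""
    df = _read_table(path)
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df["r2"] = pd.to_numeric(df["r2"], errors="coerce")
    if df["r2"].isna().any() or ((df["r2"] < 0) | (df["r2"] > 1)).any():
        raise FormatError(f"{path}: r2 values must be numeric in [0, 1]")
    return df[["snp_a", "snp_b", "r2"]].astype({"snp_a": str, "snp_b": str})


def read_maf(path) -> pd.Series:
    """Read a per-variant MAF table (snp, maf)."""
    df = _read_table(path)
    for col in ("snp", "maf"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    maf = pd.to_numeric(df["maf"], errors="coerce")
    if maf.isna().any() or ((maf < 0) | (maf > 0.5)).any():
        raise FormatError(f"{path}: maf values must be numeric in [0, 0.5]")
    return pd.Series(maf.to_numpy(), index=pd.Index(df["snp"].astype(str),
                                                    name="snp"), name="maf")


def write_results_long(table: pd.DataFrame, path) -> None:
    """Write the long-format results table (machine-readable contract)."""
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def format_results_pretty(table: pd.DataFrame,
                          use_one_sided: bool = True) -> str:
    """Render results as a wide per-model table.

    One row block per model; per covariate the p-value, estimate, SE and
    count are stacked, mirroring the conventional presentation of
    enrichment results.  Intercept p-values are two-sided.
    """
    lines = []
    for model, sub in table.groupby("model", sort=False):
        sub = sub.set_index("covariate")
        covs = list(sub.index)
        lines.append(f"## {model}")
        header = ["quantity"] + covs
        rows = {"p_value": [], "estimate": [], "std_error": [], "count": []}
        for c in covs:
            r = sub.loc[c]
            if c == "(Intercept)" or not use_one_sided:
                p = r["p_two_sided"]
            else:
                p = r["p_one_sided"]
            rows["p_value"].append("NA" if pd.isna(p) else FLOAT_FMT % p)
            rows["estimate"].append(FLOAT_FMT % r["estimate"])
            rows["std_error"].append(
                "NA" if pd.isna(r["se"]) else FLOAT_FMT % r["se"])
            rows["count"].append(str(int(r["count"])))
        widths = [max(len(header[i]),
                      *(len(rows[q][i - 1]) for q in rows)) if i else 9
                  for i in range(len(header))]
        lines.append("\t".join(header))
        for q, vals in rows.items():
            lines.append("\t".join([q] + vals))
        lines.append("")
    return "\n".join(lines)


@dataclass
class RunConfig:
    """Declarative configuration of a full COMET run.

    Mirrors the CLI options; loadable from YAML with the same keys.
    """

    trait_files: dict = field(default_factory=dict)
    annotations: str | None = None
    ld: str | None = None
    maf: str | None = None
    R: float = 20.0
    pi0: float = 0.99
    prior_sd: float = 0.2
    r2_max: float = 0.1
    maf_min: float = 0.05
    min_category_prop: float = 0.00025
    alpha: float = 0.05
    no_offset: bool = False
    two_sided_large_categories: bool = False
    jackknife: bool = False
    seed: int | None = None
    out_dir: str = "comet_out"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InvalidInputError("alpha must lie strictly in (0, 1)")
        if not (0.0 <= self.r2_max <= 1.0):
            raise InvalidInputError("r2_max must lie in [0, 1]")
        if not (0.0 <= self.maf_min < 0.5):
            raise InvalidInputError("maf_min must lie in [0, 0.5)")
        if not (0.0 <= self.min_category_prop < 1.0):
            raise InvalidInputError("min_category_prop must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
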