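"""Table readers/writers and configuration files.

Count tables are TSV with columns ``position``, ``wt_aa``, ``alt_aa`` followed
by one integer column per sample named ``condition_replicate``.  Score tables
are TSV with the standard differential-abundance column names so externally
exported results ingest interchangeably.  Floats round-trip to 12 significant
digits; malformed rows are rejected with their 1-based data row number.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError
from .simulate import SimConfig
from .variants import Variant

FLOAT_FORMAT = "%.12g"

SCORE_COLUMNS = [
    "position", "wt_aa", "alt_aa", "baseMean", "log2FoldChange",
    "lfcSE", "pvalue", "padj",
]


def _variant_columns(frame_index) -> pd.DataFrame:
    from .variants import parse_variant

    parsed = [parse_variant(v) for v in frame_index]
    return pd.DataFrame(
        {
            "position": [v.position for v in parsed],
            "wt_aa": [v.wt_aa for v in parsed],
            "alt_aa": [v.alt_aa for v in parsed],
        },
        index=frame_index,
    )


def write_count_table(counts: pd.DataFrame, path) -> None:
    """Write a variant x sample count table as TSV."""
    out = pd.concat([_variant_columns(counts.index), counts], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_count_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a count TSV; returns (counts, samples metadata).

    Sample conditions/replicates are parsed from column names
    (``condition_replicate``).  Raises :class:`ParseError` with the offending
    1-based data row for negative or non-integer counts and malformed
    variants.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"count table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("position", "wt_aa", "alt_aa"):
        if col not in df.columns:
            raise ParseError(f"count table missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("position", "wt_aa", "alt_aa")]
    if not sample_cols:
        raise ParseError("count table has no sample columns")
    names = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            v = Variant(int(row.position), str(row.wt_aa), str(row.alt_aa))
        except (ParseError, ValueError) as exc:
            raise ParseError(f"bad variant: {exc}", row=i) from None
        names.append(str(v))
    counts = df[sample_cols].copy()
    arr = counts.to_numpy()
    bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) < 0) \
        | (arr.astype(float) != np.floor(arr.astype(float)))
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0][0]) + 1
        raise ParseError("counts must be nonnegative integers", row=row)
    counts = counts.astype(np.int64)
    counts.index = pd.Index(names, name="variant")
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ParseError(f"duplicate variant key {dup!r}")
    rows = []
    for c in sample_cols:
        cond, _, rep = c.rpartition("_")
        if not cond or not rep.isdigit():
            raise ParseError(f"sample column {c!r} is not condition_replicate")
        rows.append({"sample": c, "condition": cond, "replicate": int(rep)})
    samples = pd.DataFrame(rows).set_index("sample")
    return counts, samples


def write_scores(frame: pd.DataFrame, path) -> None:
    """Write an enrichment record table as TSV (DESeq2-style column names)."""
    cols = [c for c in SCORE_COLUMNS if c in frame.columns] + [
        c for c in frame.columns if c not in SCORE_COLUMNS
    ]
    frame[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_scores(path) -> pd.DataFrame:
    """Read an enrichment record table written by :func:`write_scores`
    (or exported from another tool with the same column names)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"score table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("position", "wt_aa", "alt_aa", "log2FoldChange"):
        if col not in df.columns:
            raise ParseError(f"score table missing column {col!r}")
    names = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            names.append(str(Variant(int(row.position), row.wt_aa, row.alt_aa)))
        except (ParseError, ValueError) as exc:
            raise ParseError(f"bad variant: {exc}", row=i) from None
    df.index = pd.Index(names, name="variant")
    return df


def read_variant_table(
    path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a generic per-variant score table (CSV/TSV).

    ``column_map`` maps canonical names (``position``, ``wt_aa``, ``alt_aa``,
    ``variant``, ``score``, ``ddg_active``, ``ddg_latent``) to the file's
    column names.  Either a ``variant`` column (notation ``A123G`` or
    ``Ala123Gly``) or the three identity columns must be resolvable.
    """
    from .variants import parse_variant

    path = Path(path)
    if not path.exists():
        raise ParseError(f"variant table not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cmap = column_map or {}
    col = lambda name: cmap.get(name, name)
    if col("variant") in df.columns:
        names = []
        for i, s in enumerate(df[col("variant")], start=1):
            try:
                names.append(str(parse_variant(s)))
            except ParseError as exc:
                raise ParseError(f"bad variant: {exc}", row=i) from None
    elif all(col(c) in df.columns for c in ("position", "wt_aa", "alt_aa")):
        names = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                names.append(
                    str(
                        Variant(
                            int(getattr(row, col("position"))),
                            getattr(row, col("wt_aa")),
                            getattr(row, col("alt_aa")),
                        )
                    )
                )
            except (ParseError, ValueError) as exc:
                raise ParseError(f"bad variant: {exc}", row=i) from None
    else:
        raise ParseError(
            "variant table needs a 'variant' column or position/wt_aa/alt_aa"
        )
    out = df.rename(columns={v: k for k, v in cmap.items()})
    out.index = pd.Index(names, name="variant")
    return out


def read_conservation(path, column_map: dict[str, str] | None = None) -> pd.Series:
    """Read a per-position conservation CSV (columns position, score)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"conservation table not found: {path}")
    cmap = column_map or {}
    df = pd.read_csv(path)
    pos_col = cmap.get("position", "position")
    score_col = cmap.get("score", df.columns[1] if "score" not in df.columns else "score")
    if pos_col not in df.columns or score_col not in df.columns:
        raise ParseError("conservation table needs position and score columns")
    s = pd.Series(
        df[score_col].to_numpy(dtype=float),
        index=pd.Index(df[pos_col].astype(int), name="position"),
        name="conservation",
    )
    if s.index.has_duplicates:
        raise ParseError("duplicate positions in conservation table")
    return s.sort_index()


def write_series_csv(series: pd.Series, path) -> None:
    series.to_frame().to_csv(path, float_format=FLOAT_FORMAT)


def write_frame_csv(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, float_format=FLOAT_FORMAT, index=index)


def write_regions_bed(regions: dict[str, list[tuple[int, int]]], path,
                      chrom: str = "protein") -> None:
    """Export called regions as BED (0-based, half-open) — the single
    0-based surface of the package."""
    with open(path, "w") as fh:
        for cls, intervals in regions.items():
            for start, end in intervals:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{cls}\n")


def sim_config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    # tuples -> lists for YAML/JSON friendliness
    return json.loads(json.dumps(d))


def sim_config_from_dict(d: dict) -> SimConfig:
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ConfigurationError(f"unknown simulation config fields: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("incubation_times", "wt_half_life_range",
                "functional_activity_range", "nonfunctional_activity_range",
                "tol0_beta_params"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    if "spike_ins" in kwargs:
        kwargs["spike_ins"] = tuple((str(n), float(f)) for n, f in kwargs["spike_ins"])
    if "planted_regions" in kwargs:
        kwargs["planted_regions"] = tuple(
            (int(a), int(b)) for a, b in kwargs["planted_regions"]
        )
    return SimConfig(**kwargs)


def load_config_file(path) -> dict:
    """Load a YAML (or JSON) mapping."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must hold a mapping")
    return data
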