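"""Readers and writers for the tab-separated interchange formats.

All tabular artifacts are TSV (UTF-8, ``NA`` for flagged-missing values,
floats at 17 significant digits so round trips are lossless):

* matrices (genotype/phenotype/covariate): header row of column ids, first
  column of sample ids;
* per-feature summary statistics: ``variant_id beta se t_stat p_value n df``,
  one file per feature plus a ``manifest.tsv`` mapping feature id to path;
* partial covariance: labelled square matrix with feature ids on both axes,
  with the normalization divisor recorded in a ``# normalization=<d>``
  comment on the first line;
* projections: one row per projection (index = projection id), one column
  per feature id.

An optional column dialect maps external summary-statistic headers onto the
native layout; a mapping for the PLINK 2 ``.glm.linear`` format is bundled.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GWAS_COLUMNS, FeatureGwasTable, PartialCovariance

FLOAT_FORMAT = "%.17g"
NA_REP = "NA"

#: Column-name mappings from external headers to the native layout.
STATS_DIALECTS: dict[str, dict[str, str]] = {
    "native": {c: c for c in GWAS_COLUMNS},
    # PLINK 2 --glm linear output ("ADD" rows)
    "plink2": {
        "ID": "variant_id",
        "BETA": "beta",
        "SE": "se",
        "T_STAT": "t_stat",
        "P": "p_value",
        "OBS_CT": "n",
    },
}


def read_matrix(path, kind: str = "generic") -> pd.DataFrame:
    """Read a samples-x-columns TSV matrix.

    ``kind`` in {"genotype", "phenotype", "covariate", "binary", "generic"}
    selects extra validation: binary matrices must contain only {0, 1};
    covariate matrices must start with an all-ones intercept column.
    Duplicate ids and non-numeric cells raise with the offending line
    number (1-based, header = line 1).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = int(np.where(df.index == dup)[0][-1]) + 2
        raise ValueError(f"{path}: duplicate sample id {dup!r} at line {line}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column id {dup!r}")
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError:
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} in column "
                        f"{df.columns[j]!r} at line {i + 2}"
                    ) from None
        raise
    out = pd.DataFrame(vals, index=df.index, columns=df.columns)
    if kind == "binary":
        bad = ~np.isin(vals, (0.0, 1.0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"{path}: non-binary value {vals[i, j]!r} in column "
                f"{df.columns[j]!r} at line {i + 2}"
            )
    if kind == "covariate" and not np.allclose(vals[:, 0], 1.0):
        raise ValueError(f"{path}: first covariate column must be an all-ones intercept")
    return out


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=NA_REP,
              index_label="sample_id")


def write_stats(table: pd.DataFrame, path) -> None:
    """Write one scan-result table in the native layout."""
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
                 na_rep=NA_REP)


def read_stats(path, dialect: str = "native", n_covariates: int | None = None) -> pd.DataFrame:
    """Read a per-variant summary-statistic table, normalizing external
    column dialects onto the native layout.

    When the dialect lacks a ``df`` column it is inferred as
    ``n - n_covariates - 2`` (covariates excluding the intercept; one df
    each for intercept and genotype)."""
    if dialect not in STATS_DIALECTS:
        raise ValueError(
            f"unknown stats dialect {dialect!r}; known: {sorted(STATS_DIALECTS)}"
        )
    mapping = STATS_DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], float_precision="round_trip")
    df.columns = [c.lstrip("#") for c in df.columns]
    present = {src: dst for src, dst in mapping.items() if src in df.columns}
    out = df[list(present)].rename(columns=present)
    mandatory = ["variant_id", "beta", "se", "n"]
    absent = [c for c in mandatory if c not in out.columns]
    if absent:
        raise ValueError(f"{path}: missing mandatory column(s) {absent}")
    if "df" not in out.columns:
        if n_covariates is None:
            raise ValueError(
                f"{path}: dialect {dialect!r} lacks a df column; pass n_covariates"
            )
        out["df"] = out["n"].astype(int) - n_covariates - 2
    if "t_stat" not in out.columns:
        out["t_stat"] = out["beta"] / out["se"]
    if "p_value" not in out.columns:
        from scipy import stats as sps

        out["p_value"] = 2.0 * sps.t.sf(np.abs(out["t_stat"]), out["df"])
    return out[GWAS_COLUMNS]


def write_feature_stats_dir(table: FeatureGwasTable, out_dir) -> None:
    """One native-layout TSV per feature plus a manifest mapping feature id
    to file path (mirrors the many-input-files deployment model)."""
    from .direct import feature_gwas_rows

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for fid in table.feature_ids:
        fname = f"{fid}.gwas.tsv"
        write_stats(feature_gwas_rows(table, fid), out_dir / fname)
        manifest.append({"feature_id": fid, "path": fname})
    pd.DataFrame(manifest).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)


def read_feature_stats_dir(stats_dir, dialect: str = "native",
                           n_covariates: int | None = None) -> FeatureGwasTable:
    """Assemble a :class:`FeatureGwasTable` from a directory of per-feature
    summary-statistic files listed in ``manifest.tsv``."""
    stats_dir = Path(stats_dir)
    manifest = pd.read_csv(stats_dir / "manifest.tsv", sep="\t")
    betas, ses, ns = {}, {}, {}
    df_val = None
    variant_index = None
    for row in manifest.itertuples(index=False):
        tab = read_stats(stats_dir / row.path, dialect=dialect,
                         n_covariates=n_covariates)
        if variant_index is None:
            variant_index = pd.Index(tab["variant_id"])
        elif not variant_index.equals(pd.Index(tab["variant_id"])):
            raise ValueError(
                f"{row.path}: variant ids/order differ from the first feature file"
            )
        betas[row.feature_id] = tab["beta"].to_numpy()
        ses[row.feature_id] = tab["se"].to_numpy()
        ns[row.feature_id] = int(tab["n"].iloc[0])
        this_df = int(tab["df"].iloc[0])
        if df_val is None:
            df_val = this_df
        elif df_val != this_df:
            raise ValueError("features disagree on degrees of freedom")
    return FeatureGwasTable(
        beta=pd.DataFrame(betas, index=variant_index),
        se=pd.DataFrame(ses, index=variant_index),
        n=pd.Series(ns),
        df=df_val,
    )


def write_covariance(cov: PartialCovariance, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# normalization={cov.normalization}\n")
        cov.values.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT,
                          index_label="feature_id")


def read_covariance(path) -> PartialCovariance:
    norm = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# normalization="):
            norm = int(first.split("=", 1)[1])
            values = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
        else:
            fh.seek(0)
            values = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    if norm is None:
        raise ValueError(f"{path}: missing '# normalization=<d>' header line")
    return PartialCovariance(values=values, normalization=norm)


def write_projections(projections: list[pd.Series] | pd.DataFrame, path) -> None:
    if isinstance(projections, list):
        projections = pd.DataFrame(
            {f"proj{j:04d}": p for j, p in enumerate(projections)}
        ).T
    projections.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                       index_label="projection_id")


def read_projections(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_truth(truth, path) -> None:
    """SimulatedTruth as JSON (effect sizes and errors as column maps)."""
    payload = {
        "causal_variant_ids": list(truth.causal_variant_ids),
        "effect_sizes": None
        if truth.effect_sizes is None
        else truth.effect_sizes.to_dict(orient="split"),
        "errors": None if truth.errors is None else truth.errors.to_dict(orient="split"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
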