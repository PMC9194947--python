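"""Delimited readers/writers and fit serialization.

Expression data are plain delimited text (comma or tab, auto-detected)
with one header row of feature (or sample) identifiers and one leading
id column.  Loaders reject — they never silently coerce: duplicate ids,
non-numeric cells and missing values are reported with their location.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SuffPCRResults

__all__ = [
    "ExpressionTable",
    "LoadedFit",
    "FIT_SCHEMA_VERSION",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "align_phenotype",
    "write_fit",
    "read_fit",
    "write_gene_list",
]

FIT_SCHEMA_VERSION = 1


@dataclass
class ExpressionTable:
    """An expression matrix held samples-by-features in memory,
    whatever the on-disk orientation was."""

    sample_ids: list
    feature_ids: list
    values: np.ndarray
    orientation: str  # layout of the file this was read from / written to

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _check_header(path, sep: str) -> None:
    """Duplicate column ids must be caught before pandas mangles them
    into unique names."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_ids(header[1:], "column")


def _check_ids(ids, what: str) -> list:
    ids = [str(i) for i in ids]
    seen: dict = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = True
    if dups:
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))[:10]}")
    return ids


def _reject_bad_cells(df: pd.DataFrame, path) -> np.ndarray:
    """Coerce to float, reporting the (row id, column id) of every
    non-numeric or missing cell."""
    raw_na = df.isna()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    problems = []
    for r, c in zip(*np.nonzero(bad.to_numpy())):
        kind = "missing" if raw_na.iat[r, c] else "non-numeric"
        problems.append(f"{kind} cell at row {df.index[r]!r}, "
                        f"column {df.columns[c]!r}")
    if problems:
        head = "; ".join(problems[:10])
        raise ValueError(f"{path}: {len(problems)} bad cell(s): {head}")
    return numeric.to_numpy(dtype=float)


def read_expression(
    path, orientation: str = "samples_by_features", delimiter: str | None = None
) -> ExpressionTable:
    """Read a delimited expression matrix.

    ``orientation`` states the on-disk layout; the returned table is
    always samples x features in memory.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = delimiter or _sniff_delimiter(path)
    _check_header(path, sep)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: ragged or malformed rows ({err})") from err
    values = _reject_bad_cells(df, path)
    row_ids = _check_ids(df.index, "row")
    col_ids = _check_ids(df.columns, "column")
    if orientation == "features_by_samples":
        values = values.T
        sample_ids, feature_ids = col_ids, row_ids
    else:
        sample_ids, feature_ids = row_ids, col_ids
    return ExpressionTable(sample_ids=sample_ids, feature_ids=feature_ids,
                           values=values, orientation=orientation)


def write_expression(
    table: ExpressionTable, path,
    orientation: str = "samples_by_features", delimiter: str = ","
) -> None:
    df = table.to_frame()
    if orientation == "features_by_samples":
        df = df.T
    elif orientation != "samples_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=delimiter)


def read_phenotype(path, log1p: bool = False,
                   delimiter: str | None = None) -> pd.Series:
    """Read a one-column phenotype file (id column + value column).

    ``log1p=True`` applies ``log(Y + 1)`` — opt-in, intended for
    non-negative right-censored survival times; never automatic.
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one value column, "
                         f"got {df.shape[1]}")
    values = _reject_bad_cells(df, path).ravel()
    ids = _check_ids(df.index, "sample")
    if log1p:
        if (values < 0).any():
            raise ValueError("log(Y+1) requires nonnegative phenotypes")
        values = np.log1p(values)
    return pd.Series(values, index=ids, name=df.columns[0])


def align_phenotype(table: ExpressionTable, pheno: pd.Series) -> np.ndarray:
    """Join the phenotype to the expression table by sample id
    (order-insensitive); unmatched ids on either side are an error."""
    missing = [s for s in table.sample_ids if s not in pheno.index]
    if missing:
        raise ValueError(f"phenotype missing for sample(s): {missing[:10]}")
    extra = [s for s in pheno.index if s not in set(table.sample_ids)]
    if extra:
        raise ValueError(f"phenotype has unmatched sample id(s): {extra[:10]}")
    return pheno.loc[table.sample_ids].to_numpy(dtype=float)


def write_fit(res: SuffPCRResults, path, seed: int | None = None) -> None:
    """Serialize a fitted model to JSON (documented key-value schema)."""
    from . import __version__

    m = res.model
    std = m._std
    names = m.feature_names or [f"feature_{j}" for j in range(m.p)]
    sup = res.support  # original indices
    pos = res.V_hat.support  # positions within retained columns
    payload = {
        "schema_version": FIT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "family": m.family,
        "n": m.n,
        "p": m.p,
        "d": m.d,
        "lam": res.lam,
        "t": res.t,
        "flags": list(res.flags),
        "feature_names": names,
        "dropped_features": [names[j] for j in std.dropped],
        "intercept": res.intercept,
        "response_center": std.response_center,
        "support": {
            names[j]: {
                "beta_std": float(res.beta_std[k]),
                "beta_original": float(res.beta_original[j]),
                "mean": float(std.feature_means[k]),
                "scale": float(std.feature_scales[k]),
                "v_row": [float(v) for v in res.V_hat.V[k]],
            }
            for j, k in zip(sup, pos)
        },
        "gamma": [float(g) for g in res.gamma],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


@dataclass
class LoadedFit:
    """A deserialized fit: enough to predict and to export gene lists."""

    family: str
    d: int
    lam: float
    t: float
    flags: list
    feature_names: list
    intercept: float
    support_names: list
    beta_by_name: dict
    mean_by_name: dict
    scale_by_name: dict
    gamma: np.ndarray
    seed: int | None = None

    @property
    def n_selected(self) -> int:
        return len(self.support_names)

    def predict(self, X) -> np.ndarray:
        """Predict from an :class:`ExpressionTable`, DataFrame or array
        carrying the full training feature set."""
        if isinstance(X, ExpressionTable):
            df = X.to_frame()
        elif isinstance(X, pd.DataFrame):
            df = X
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
            if arr.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features, "
                    f"got {arr.shape[1]}"
                )
            df = pd.DataFrame(arr, columns=self.feature_names)
        missing = [f for f in self.support_names if f not in df.columns]
        if missing:
            raise ValueError(f"new data missing feature(s): {missing[:10]}")
        eta = np.full(len(df), self.intercept)
        for name in self.support_names:
            x = df[name].to_numpy(dtype=float)
            eta += (x - self.mean_by_name[name]) / self.scale_by_name[name] \
                * self.beta_by_name[name]
        if self.family == "gaussian":
            return eta
        return 1.0 / (1.0 + np.exp(-eta))


def read_fit(path) -> LoadedFit:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != FIT_SCHEMA_VERSION:
        raise ValueError(
            f"fit file schema version {version!r} is not supported "
            f"(this package reads version {FIT_SCHEMA_VERSION})"
        )
    sup = payload["support"]
    return LoadedFit(
        family=payload["family"],
        d=payload["d"],
        lam=payload["lam"],
        t=payload["t"],
        flags=payload["flags"],
        feature_names=payload["feature_names"],
        intercept=payload["intercept"],
        support_names=list(sup.keys()),
        beta_by_name={k: v["beta_std"] for k, v in sup.items()},
        mean_by_name={k: v["mean"] for k, v in sup.items()},
        scale_by_name={k: v["scale"] for k, v in sup.items()},
        gamma=np.asarray(payload["gamma"], dtype=float),
        seed=payload.get("seed"),
    )


def write_gene_list(fit, path, with_beta: bool = False) -> None:
    """One selected feature id per line; with ``with_beta`` a two-column
    (id, beta) table on the original scale."""
    if isinstance(fit, SuffPCRResults):
        names = fit.support_names
        betas = fit.beta_original[fit.support]
    else:
        names = fit.support_names
        betas = [fit.beta_by_name[n] / fit.scale_by_name[n] for n in names]
    with open(path, "w", encoding="utf-8") as fh:
        for name, b in zip(names, betas):
            if with_beta:
                fh.write(f"{name}\t{float(b)!r}\n")
            else:
                fh.write(f"{name}\n")
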