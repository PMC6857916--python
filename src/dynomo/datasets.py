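"""Dataset IO: CSV + sidecar reading, and the four classic worked-example
datasets (Titanic passengers, horseshoe crabs, ragweed pollen, advanced
lung cancer).

``read_dataset`` loads any CSV with an optional YAML/JSON sidecar that
declares column roles (covariate / factor / time / status) and, for
factors, an explicit level order.  ``fetch_example`` materialises the
worked-example data: the lung-cancer and Titanic tables are extracted
from locally installed statistical libraries (lifelines' bundled copy of
the North Central Cancer Treatment Group lung data; the R ``carData``
package's per-passenger Titanic table), while the horseshoe-crab and
ragweed tables are downloaded from pinned archive URLs.  Everything is
cached as plain CSV; with a warm cache no network or R is touched.
"""

from __future__ import annotations

import hashlib
import os
import shutil
import subprocess
import urllib.request
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .formula import VariableSpec
from .synthetic import DatasetBundle

__all__ = [
    "read_dataset",
    "write_dataset",
    "fetch_example",
    "specs_from_table",
    "DatasetUnavailableError",
    "EXAMPLES",
]


class DatasetUnavailableError(RuntimeError):
    """The example dataset could not be materialised on this machine.

    Tests and analyses that need one of the classic datasets are optional
    extras: everything else in the package runs on synthetic data.
    """


def default_cache_dir() -> Path:
    env = os.environ.get("DYNOMO_CACHE")
    if env:
        return Path(env)
    return Path.home() / ".cache" / "dynomo"


def specs_from_table(df: pd.DataFrame, roles: dict[str, str],
                     level_orders: dict[str, list[str]] | None = None,
                     ) -> dict[str, VariableSpec]:
    """Variable metadata (range/mean for covariates, levels/mode for
    factors) for the given columns; level order defaults to lexicographic."""
    level_orders = level_orders or {}
    specs: dict[str, VariableSpec] = {}
    for name, role in roles.items():
        col = df[name]
        if role == "factor":
            observed = col.dropna().astype(str)
            levels = level_orders.get(name) or sorted(observed.unique())
            counts = observed.value_counts()
            top = counts[counts == counts.max()].index
            specs[name] = VariableSpec(name=name, role="factor",
                                       levels=tuple(levels), mode=sorted(top)[0])
        elif role == "covariate":
            vals = pd.to_numeric(col, errors="raise").dropna()
            specs[name] = VariableSpec(
                name=name, role="covariate",
                observed_min=float(vals.min()), observed_max=float(vals.max()),
                mean=float(vals.mean()),
            )
        else:  # time / status carry no layout metadata
            specs[name] = VariableSpec(name=name, role=role)
    return specs


def read_dataset(csv_path, sidecar=None) -> DatasetBundle:
    """Load a CSV (header required) with an optional role sidecar.

    The sidecar (YAML or JSON) has the schema::

        columns:
          age:   {role: covariate}
          sex:   {role: factor, levels: [female, male]}
          time:  {role: time}
          status: {role: status}
        response: survived     # optional

    Columns not named in the sidecar get a role inferred from dtype
    (numeric → covariate, anything else → factor).
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    cfg: dict = {}
    if sidecar is not None:
        cfg = yaml.safe_load(Path(sidecar).read_text()) or {}
    col_cfg = cfg.get("columns", {})
    roles: dict[str, str] = {}
    level_orders: dict[str, list[str]] = {}
    for name in df.columns:
        if name in col_cfg:
            entry = col_cfg[name]
            roles[name] = entry.get("role", "covariate")
            if "levels" in entry:
                level_orders[name] = [str(l) for l in entry["levels"]]
        else:
            roles[name] = (
                "covariate" if pd.api.types.is_numeric_dtype(df[name]) else "factor"
            )
    for name, role in roles.items():
        if role == "factor":
            df[name] = df[name].astype("string").astype(object)
    specs = specs_from_table(df, roles, level_orders)
    return DatasetBundle(
        table=df, variable_specs=specs, provenance="user",
        response=cfg.get("response"), time=cfg.get("time"),
        status=cfg.get("status"), roles=roles,
    )


def write_dataset(bundle: DatasetBundle, csv_path, sidecar_path=None) -> None:
    bundle.table.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        cfg = {
            "columns": {
                name: (
                    {"role": "factor", "levels": list(s.levels)}
                    if s.role == "factor"
                    else {"role": s.role}
                )
                for name, s in bundle.variable_specs.items()
            },
            "response": bundle.response,
            "time": bundle.time,
            "status": bundle.status,
        }
        Path(sidecar_path).write_text(yaml.safe_dump(cfg, sort_keys=True))


# --------------------------------------------------------------------------
# worked-example datasets

#: name → (row count, role map) for the four classics
EXAMPLES: dict[str, dict] = {
    "titanic": {
        "n_rows": 1309,
        "roles": {"age": "covariate", "pclass": "factor", "sex": "factor"},
        "response": "survived",
    },
    "lung": {
        "n_rows": 228,
        "roles": {"age": "covariate", "wt.loss": "covariate",
                  "ph.ecog": "covariate", "sex": "factor"},
        "time": "time",
        "status": "status",
    },
    "crabs": {
        "n_rows": 173,
        "roles": {"Width": "covariate", "Dark": "factor"},
        "response": "Satellites",
    },
    "ragweed": {
        "n_rows": 335,
        "roles": {"rain": "factor", "temperature": "covariate",
                  "wind.speed": "covariate", "day.in.seas": "covariate"},
        "response": "sqrtragweed",
    },
}

# Pinned source URLs for datasets that must be downloaded.  sha256 values
# are recorded once a download has been possible; None means
# verify-on-first-fetch (the digest is then written next to the cache).
_DOWNLOAD_SOURCES: dict[str, dict] = {
    "crabs": {
        "url": "https://raw.githubusercontent.com/cran/glm2/master/data/crabs.RData",
        "sha256": None,
        "rdata_object": "crabs",
    },
    "ragweed": {
        "url": "https://raw.githubusercontent.com/cran/SemiPar/master/data/ragweed.RData",
        "sha256": None,
        "rdata_object": "ragweed",
    },
}


def _rscript(code: str, what: str) -> None:
    rs = shutil.which("Rscript")
    if rs is None:
        raise DatasetUnavailableError(
            f"{what}: Rscript is not on PATH (needed to extract this dataset)"
        )
    proc = subprocess.run([rs, "-e", code], capture_output=True, text=True,
                          timeout=120)
    if proc.returncode != 0:
        raise DatasetUnavailableError(f"{what}: Rscript failed:\n{proc.stderr}")


def _materialise_lung(csv_path: Path) -> None:
    try:
        from lifelines.datasets import load_lung
    except Exception as exc:  # pragma: no cover
        raise DatasetUnavailableError(f"lung: lifelines not importable ({exc})")
    df = load_lung()[["time", "status", "age", "sex", "ph.ecog", "wt.loss"]].copy()
    # lifelines ships the NCCTG table with status already recoded to 0/1
    df["sex"] = np.where(df["sex"] == 2, "female", "male")
    df.to_csv(csv_path, index=False)


def _materialise_titanic(csv_path: Path) -> None:
    code = (
        f'library(carData); data(TitanicSurvival); '
        f'd <- TitanicSurvival; '
        f'd$survived <- as.integer(d$survived == "yes"); '
        f'names(d)[names(d) == "passengerClass"] <- "pclass"; '
        f'write.csv(d[, c("survived", "sex", "age", "pclass")], '
        f'"{csv_path.as_posix()}", row.names = FALSE)'
    )
    _rscript(code, "titanic")


def _materialise_download(name: str, csv_path: Path) -> None:
    src = _DOWNLOAD_SOURCES[name]
    raw = csv_path.with_suffix(".RData")
    try:
        urllib.request.urlretrieve(src["url"], raw)  # noqa: S310 — pinned URL
    except Exception as exc:
        raise DatasetUnavailableError(
            f"{name}: could not download {src['url']} ({exc}); this example "
            "dataset is optional — synthetic fixtures cover the same code paths"
        )
    digest = hashlib.sha256(raw.read_bytes()).hexdigest()
    if src["sha256"] is not None and digest != src["sha256"]:
        raw.unlink()
        raise DatasetUnavailableError(
            f"{name}: checksum mismatch (got {digest}, expected {src['sha256']})"
        )
    csv_path.with_suffix(".sha256").write_text(digest + "\n")
    obj = src["rdata_object"]
    post = ""
    if name == "ragweed":
        post = "d$sqrtragweed <- sqrt(d$ragweed); "
    code = (
        f'load("{raw.as_posix()}"); d <- {obj}; {post}'
        f'write.csv(d, "{csv_path.as_posix()}", row.names = FALSE)'
    )
    _rscript(code, name)
    raw.unlink()


def fetch_example(name: str, cache_dir=None) -> DatasetBundle:
    """Materialise one of the classic example datasets, caching as CSV.

    A warm cache is returned directly (no network, no R).  Raises
    :class:`DatasetUnavailableError` with a clear message when the data
    cannot be obtained on this machine.
    """
    if name not in EXAMPLES:
        raise KeyError(f"unknown example {name!r}; choose from {sorted(EXAMPLES)}")
    meta = EXAMPLES[name]
    cache = Path(cache_dir) if cache_dir is not None else default_cache_dir()
    cache.mkdir(parents=True, exist_ok=True)
    csv_path = cache / f"{name}.csv"
    if not csv_path.exists():
        if name == "lung":
            _materialise_lung(csv_path)
        elif name == "titanic":
            _materialise_titanic(csv_path)
        else:
            _materialise_download(name, csv_path)

    df = pd.read_csv(csv_path)
    if len(df) != meta["n_rows"]:
        raise DatasetUnavailableError(
            f"{name}: cached table has {len(df)} rows, expected {meta['n_rows']}"
        )
    roles = dict(meta["roles"])
    for col, role in roles.items():
        if role == "factor":
            df[col] = df[col].astype("string").astype(object)
    specs = specs_from_table(df, roles)
    return DatasetBundle(
        table=df, variable_specs=specs, provenance="fetched",
        response=meta.get("response"), time=meta.get("time"),
        status=meta.get("status"), roles=roles,
    )
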