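"""CSV/JSON readers and writers with validation at the boundary.

All files use 1-based item/category/dimension labels; conversion to 0-based
arrays happens here only.  Every writer drops a JSON manifest sidecar
(``<path>.manifest.json``) recording the file role, schema version and any
seed/condition metadata needed to regenerate the artifact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .model import IdentificationPattern, ModelParameters, ResponseMatrix

__all__ = [
    "read_responses",
    "write_responses",
    "read_parameters",
    "write_parameters",
    "read_draws",
    "write_draws",
    "write_manifest",
]

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.17g"  # lossless for IEEE doubles


def write_manifest(path: str | Path, role: str, metadata: dict | None = None) -> Path:
    manifest = {
        "role": role,
        "schema_version": SCHEMA_VERSION,
        "file": Path(path).name,
        "metadata": metadata or {},
    }
    out = Path(str(path) + ".manifest.json")
    out.write_text(json.dumps(manifest, indent=1, default=str))
    return out


# ---------------------------------------------------------------------------
# response matrices


def read_responses(path: str | Path, K: int | None = None,
                   header: bool | None = None) -> ResponseMatrix:
    """Read a response CSV (one row per person, one integer column per item).

    A header row of item names is auto-detected (any non-numeric first row).
    K is inferred as the maximum observed code unless declared.
    """
    path = Path(path)
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = header if header is not None else not np.issubdtype(
        first.to_numpy().dtype, np.number
    )
    frame = pd.read_csv(path, header=0 if has_header else None)
    names = list(map(str, frame.columns)) if has_header else None
    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric response cells")
    f = values.astype(float)
    if np.any(f != np.round(f)):
        r, c = np.argwhere(f != np.round(f))[0]
        raise ValueError(f"{path}: non-integer response at row {r + 1}, column {c + 1}")
    return ResponseMatrix(f.astype(int), K=K, item_names=names)


def write_responses(X: ResponseMatrix, path: str | Path,
                    metadata: dict | None = None) -> Path:
    path = Path(path)
    names = X.item_names or [f"item{j + 1}" for j in range(X.J)]
    pd.DataFrame(X.values, columns=names).to_csv(path, index=False)
    write_manifest(path, "responses", {"N": X.N, "J": X.J, "K": X.K, **(metadata or {})})
    return path


# ---------------------------------------------------------------------------
# parameter tables


def read_parameters(path: str | Path) -> ModelParameters:
    """Read a parameter table (CSV or JSON) with columns item, category, c, a1..aD.

    Rows may appear in any order; each (item, category) must appear exactly
    once and categories 1..K must be complete for every item.  All-zero
    reference rows are accepted and flagged as the reference category.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
    required = {"item", "category", "c"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: missing required columns {required - set(frame.columns)}")
    slope_cols = sorted(
        (c for c in frame.columns if c.startswith("a") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not slope_cols:
        raise ValueError(f"{path}: no slope columns a1..aD found")
    if [int(c[1:]) for c in slope_cols] != list(range(1, len(slope_cols) + 1)):
        raise ValueError(f"{path}: slope columns must be consecutive a1..aD, got {slope_cols}")

    dup = frame.duplicated(subset=["item", "category"])
    if dup.any():
        r = frame[dup].iloc[0]
        raise ValueError(f"{path}: duplicated row for item {r['item']} category {r['category']}")
    items = np.sort(frame["item"].unique())
    cats = np.sort(frame["category"].unique())
    J, K, D = len(items), len(cats), len(slope_cols)
    if not np.array_equal(items, np.arange(1, J + 1)) or not np.array_equal(
        cats, np.arange(1, K + 1)
    ):
        raise ValueError(f"{path}: items/categories must be labelled 1..J and 1..K")
    expected = {(i, k) for i in items for k in cats}
    seen = set(zip(frame["item"].astype(int), frame["category"].astype(int)))
    if expected - seen:
        i, k = sorted(expected - seen)[0]
        raise ValueError(f"{path}: missing row for item {i} category {k}")

    frame = frame.sort_values(["item", "category"])
    c = frame["c"].to_numpy(dtype=float).reshape(J, K)
    a = frame[slope_cols].to_numpy(dtype=float).reshape(J, K, D)

    zero_rows = (c == 0).all(axis=0) & (a == 0).all(axis=(0, 2))
    if zero_rows.any():
        ref = int(np.argwhere(zero_rows)[-1][0]) + 1
        return ModelParameters(c, a, "simple", reference_category=ref)
    if np.max(np.abs(c.sum(axis=1))) < 1e-8 and np.max(np.abs(a.sum(axis=1))) < 1e-8:
        return ModelParameters(c, a, "deviation")
    raise ValueError(
        f"{path}: parameters satisfy neither simple (an all-zero reference "
        "category) nor deviation (sum-to-zero) constraints"
    )


def write_parameters(params: ModelParameters, path: str | Path,
                     metadata: dict | None = None) -> Path:
    path = Path(path)
    J, K, D = params.J, params.K, params.D
    rows = []
    for j in range(J):
        for k in range(K):
            row = {"item": j + 1, "category": k + 1, "c": params.intercepts[j, k]}
            for d in range(D):
                row[f"a{d + 1}"] = params.slopes[j, k, d]
            rows.append(row)
    frame = pd.DataFrame(rows)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    write_manifest(
        path,
        "parameters",
        {"J": J, "K": K, "D": D, "parameterization": params.parameterization,
         **(metadata or {})},
    )
    return path


# ---------------------------------------------------------------------------
# posterior draws (long CSV + JSON metadata)


def _draw_frame(draws: PosteriorDraws) -> pd.DataFrame:
    frame = draws.free_parameter_frame(include_theta=True)
    n_chains = draws.n_chains()
    per_chain = draws.L // n_chains
    long = frame.melt(var_name="parameter", value_name="value")
    long["chain"] = np.tile(draws.chain, frame.shape[1])
    long["iteration"] = np.tile(np.tile(np.arange(per_chain), n_chains), frame.shape[1])
    return long[["chain", "iteration", "parameter", "value"]]


def write_draws(draws: PosteriorDraws, path: str | Path,
                metadata: dict | None = None) -> Path:
    """Write draws as long CSV (chain, iteration, parameter, value) + metadata."""
    path = Path(path)
    _draw_frame(draws).to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "shape": {"L": draws.L, "J": draws.J, "K": draws.K, "D": draws.D, "N": draws.N},
        "reference_category": draws.pattern.reference_category,
        "fixed_zero": np.argwhere(draws.pattern.fixed_zero).tolist(),
        "fixed_one": np.argwhere(draws.pattern.fixed_one).tolist(),
        "sampler": draws.meta,
        **(metadata or {}),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1, default=str))
    write_manifest(path, "draws", draws.meta)
    return path


def _parse_name(name: str) -> tuple[str, tuple[int, ...]]:
    base, _, rest = name.partition("[")
    idx = tuple(int(t) for t in rest.rstrip("]").split(",")) if rest else ()
    return base, idx


def read_draws(path: str | Path) -> PosteriorDraws:
    """Round-trip reader for :func:`write_draws` output."""
    path = Path(path)
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing draws metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    shape = meta["shape"]
    L, J, K, D, N = (shape[k] for k in ("L", "J", "K", "D", "N"))
    long = pd.read_csv(path, float_precision="round_trip")
    if set(long.columns) != {"chain", "iteration", "parameter", "value"}:
        raise ValueError(f"{path}: unexpected draw file columns {list(long.columns)}")

    fixed_zero = np.zeros((J, K, D), dtype=bool)
    for j, k, d in meta["fixed_zero"]:
        fixed_zero[j, k, d] = True
    fixed_one = np.zeros((J, K, D), dtype=bool)
    for j, k, d in meta["fixed_one"]:
        fixed_one[j, k, d] = True
    pattern = IdentificationPattern(fixed_zero, fixed_one, meta["reference_category"])

    intercepts = np.zeros((L, J, K))
    slopes = np.broadcast_to(pattern.fixed_values(), (L, J, K, D)).copy()
    sigma = np.zeros((L, D))
    theta = np.zeros((L, N, D))
    chain = None
    counts = long.groupby("parameter").size()
    if (counts != L).any():
        bad = counts[counts != L].index[0]
        raise ValueError(
            f"{path}: truncated or inconsistent file — parameter {bad!r} has "
            f"{counts[bad]} rows, expected {L}"
        )
    for name, grp in long.groupby("parameter", sort=False):
        base, idx = _parse_name(str(name))
        vals = grp["value"].to_numpy()
        if chain is None:
            chain = grp["chain"].to_numpy(dtype=int)
        if base == "c":
            intercepts[:, idx[0] - 1, idx[1] - 1] = vals
        elif base == "a":
            slopes[:, idx[0] - 1, idx[1] - 1, idx[2] - 1] = vals
        elif base == "sigma":
            sigma[:, idx[0] - 1] = vals
        elif base == "theta":
            theta[:, idx[0] - 1, idx[1] - 1] = vals
        else:
            raise ValueError(f"{path}: unknown parameter name {name!r}")
    return PosteriorDraws(intercepts, slopes, sigma, theta, chain, pattern,
                          meta.get("sampler", {}))
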