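"""Readers, writers, and run configuration.

Long (tidy) CSV is the single interchange format: one row per response with
person and item labels, plus either raw 0-100 integer columns
(``x_raw`` / ``yl_raw``, ``yu_raw``) or unit-interval columns
(``x`` / ``yl``, ``yu``).  Raw integers are transformed on read via the
rescaling maps; unit-interval values must already be strictly interior.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .model_core import rescale_rs1, rescale_rs2

__all__ = ["ResponseTable", "RunConfig", "read_responses", "write_fit", "read_fit"]


@dataclass
class ResponseTable:
    """A validated long-format response table.

    ``data`` always carries unit-interval columns (``x`` for rs1; ``yl``,
    ``yu`` for rs2) alongside the original person/item labels; raw integer
    columns are preserved if present in the source.
    """

    data: pd.DataFrame
    format: str  # "rs1" | "rs2"
    scale: str  # "raw-integer" | "unit-interval"


@dataclass
class RunConfig:
    """Serializable description of one model run."""

    model: str = "ddrm"
    preset: str = "simulation"
    n_chains: int = 4
    n_warmup: int = 500
    n_sampling: int = 3500
    thinning: int = 1
    seed: int = 0
    input_path: str | None = None
    output_path: str | None = None
    discretize: bool = False
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _fail_rows(mask: np.ndarray, reason: str) -> None:
    bad = np.flatnonzero(mask)
    raise ValueError(f"invalid rows {bad[:10].tolist()}: {reason}")


def read_responses(path: str | Path, format: str) -> ResponseTable:
    """Read and validate a response CSV.

    Raw integer responses are auto-transformed to the interior unit scale;
    unit-interval inputs are checked for strict interiority.  Duplicate
    (person, item) pairs, reversed intervals, and out-of-range values are
    rejected with the offending row indices.
    """
    if format not in ("rs1", "rs2"):
        raise ValueError("format must be 'rs1' or 'rs2'")
    df = pd.read_csv(path)
    required = {"person", "item"}
    if not required <= set(df.columns):
        raise ValueError(f"missing required columns {sorted(required - set(df.columns))}")
    dup = df.duplicated(subset=["person", "item"])
    if dup.any():
        _fail_rows(dup.to_numpy(), "duplicate (person, item) pair")

    if format == "rs1":
        if "x_raw" in df.columns:
            df = df.copy()
            df["x"] = rescale_rs1(df["x_raw"].to_numpy())
            scale = "raw-integer"
        elif "x" in df.columns:
            x = df["x"].to_numpy(dtype=float)
            bad = (x <= 0) | (x >= 1)
            if bad.any():
                _fail_rows(bad, "rs1 responses must be strictly inside (0,1); "
                                "raw 0-100 responses belong in an x_raw column")
            scale = "unit-interval"
        else:
            raise ValueError("rs1 table needs an 'x' or 'x_raw' column")
    else:
        if "yl_raw" in df.columns:
            lr = df["yl_raw"].to_numpy()
            ur = df["yu_raw"].to_numpy()
            bad = lr > ur
            if bad.any():
                _fail_rows(bad, "lower bound exceeds upper bound")
            df = df.copy()
            df["yl"], df["yu"] = rescale_rs2(lr, ur)
            scale = "raw-integer"
        elif "yl" in df.columns:
            yl = df["yl"].to_numpy(dtype=float)
            yu = df["yu"].to_numpy(dtype=float)
            bad = (yl <= 0) | (yu >= 1) | (yl >= yu)
            if bad.any():
                _fail_rows(bad, "rs2 responses must satisfy 0 < yl < yu < 1 "
                                "(interior support); raw 0-100 bounds belong in "
                                "yl_raw/yu_raw columns")
            scale = "unit-interval"
        else:
            raise ValueError("rs2 table needs 'yl'/'yu' or 'yl_raw'/'yu_raw' columns")
    return ResponseTable(data=df, format=format, scale=scale)


def write_fit(
    draws: PosteriorDraws,
    diagnostics: dict,
    path: str | Path,
    force: bool = False,
) -> dict[str, Path]:
    """Write a fit bundle: draws (NetCDF + long CSV) and diagnostics JSON.

    ``path`` is a stem; files ``<stem>.nc``, ``<stem>.draws.csv`` and
    ``<stem>.diagnostics.json`` are created.  Existing bundles are not
    overwritten unless ``force`` is set.
    """
    stem = Path(path)
    paths = {
        "netcdf": stem.with_suffix(".nc"),
        "csv": stem.with_suffix(".draws.csv"),
        "diagnostics": stem.with_suffix(".diagnostics.json"),
    }
    for p in paths.values():
        if p.exists():
            if not force:
                raise FileExistsError(f"{p} exists; pass force=True to overwrite")
            # replace rather than truncate: a reader may still hold the old file
            p.unlink()
    stem.parent.mkdir(parents=True, exist_ok=True)
    idata = draws.to_inference_data()
    idata.to_netcdf(str(paths["netcdf"]))
    _draws_to_long_csv(draws, paths["csv"])
    paths["diagnostics"].write_text(json.dumps(diagnostics, indent=1, default=_json_default))
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _draws_to_long_csv(draws: PosteriorDraws, path: Path) -> None:
    frames = []
    for name, arr in draws.posterior.items():
        n_chain, n_draw = arr.shape[:2]
        flat = arr.reshape(n_chain, n_draw, -1)
        for k in range(flat.shape[2]):
            label = name if flat.shape[2] == 1 else f"{name}[{k}]"
            chain_idx, draw_idx = np.meshgrid(
                np.arange(n_chain), np.arange(n_draw), indexing="ij"
            )
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": label,
                        "chain": chain_idx.ravel(),
                        "draw": draw_idx.ravel(),
                        "value": flat[:, :, k].ravel(),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_fit(path: str | Path):
    """Read back the NetCDF part of a fit bundle as an arviz InferenceData."""
    import arviz as az

    idata = az.from_netcdf(str(Path(path).with_suffix(".nc")))
    idata.load()  # detach from the file so the bundle can be overwritten
    idata.close()
    return idata
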