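"""Tab-separated dataset readers/writers and structured run configuration.

Canonical layouts (all tab-separated text with a header row):

* single_exposure — columns ``Y, X, Z1..ZJ`` plus optional ``W`` and ``U``;
* mediation — columns ``Y, X1, X2, I1_1..I1_J1, I2_1..I2_J2``;
* summary — columns ``variant_id, beta_X, se_X, beta_Y, se_Y``
  (two-sample-style input, accepted by the frequentist estimators only).

Dose columns are validated to contain only {0, 1, 2}; malformed cells are
reported with their row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .frequentist import InstrumentSummary, read_summary, write_summary
from .scenarios import MediationData, ObservedData

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_mediation_dataset",
    "load_config",
    "save_config",
    "write_draws",
]


def _read_numeric_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"malformed numeric cell at row {row + 1}, column {col!r}: {raw[col].iloc[row]!r}"
            )
        out[col] = converted
    return pd.DataFrame(out)


def _validate_doses(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    Z = df[cols].to_numpy()
    bad = ~np.isin(Z, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"dose outside {{0,1,2}} at row {i + 1}, column {cols[j]!r}: {Z[i, j]!r}"
        )
    return Z.astype(np.int64)


def write_dataset(data: ObservedData, path) -> None:
    """Write a single-exposure dataset: Y, X, Z1..ZJ[, W][, U]."""
    cols = {"Y": data.Y, "X": data.X}
    for j in range(data.J):
        cols[f"Z{j + 1}"] = data.Z[:, j]
    if data.W is not None:
        cols["W"] = data.W
    if data.U is not None:
        cols["U"] = data.U
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_mediation_dataset(data: MediationData, path) -> None:
    """Write a mediation dataset: Y, X1, X2, I1_*, I2_*."""
    cols = {"Y": data.Y, "X1": data.X1, "X2": data.X2}
    for j in range(data.J1):
        cols[f"I1_{j + 1}"] = data.I1[:, j]
    for j in range(data.J2):
        cols[f"I2_{j + 1}"] = data.I2[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_dataset(
    path, layout: str = "single_exposure"
) -> ObservedData | MediationData | InstrumentSummary:
    """Read a dataset in one of the canonical layouts into its typed container."""
    if layout == "summary":
        return read_summary(path)
    df = _read_numeric_table(path)
    if layout == "single_exposure":
        z_cols = [c for c in df.columns if c.startswith("Z")]
        missing = [c for c in ("Y", "X") if c not in df.columns]
        if missing or not z_cols:
            raise ValueError(
                f"single_exposure layout needs Y, X and Z1..ZJ columns; missing {missing or 'Z*'}"
            )
        z_cols = sorted(z_cols, key=lambda c: int(c[1:]))
        return ObservedData(
            Y=df["Y"].to_numpy(),
            X=df["X"].to_numpy(),
            Z=_validate_doses(df, z_cols),
            W=df["W"].to_numpy().astype(np.int64) if "W" in df.columns else None,
            U=df["U"].to_numpy() if "U" in df.columns else None,
        )
    if layout == "mediation":
        i1_cols = sorted(
            [c for c in df.columns if c.startswith("I1_")], key=lambda c: int(c.split("_")[1])
        )
        i2_cols = sorted(
            [c for c in df.columns if c.startswith("I2_")], key=lambda c: int(c.split("_")[1])
        )
        missing = [c for c in ("Y", "X1", "X2") if c not in df.columns]
        if missing or not i1_cols or not i2_cols:
            raise ValueError("mediation layout needs Y, X1, X2, I1_* and I2_* columns")
        return MediationData(
            Y=df["Y"].to_numpy(),
            X1=df["X1"].to_numpy(),
            X2=df["X2"].to_numpy(),
            I1=_validate_doses(df, i1_cols),
            I2=_validate_doses(df, i2_cols),
        )
    raise ValueError(f"unknown layout {layout!r}")


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    """Persist the fully materialized effective configuration as JSON."""
    Path(path).write_text(json.dumps(cfg, indent=2, sort_keys=True, default=str) + "\n")


def write_draws(samples, path) -> None:
    """Persist posterior draws as columnar TSV with chain/iteration columns."""
    cols: dict[str, np.ndarray] = {}
    chains, n_draws = samples.chains, samples.n_draws
    cols["chain"] = np.repeat(np.arange(chains), n_draws)
    cols["iteration"] = np.tile(np.arange(n_draws), chains)
    for name in samples.names():
        v = samples.draws[name]
        if v.ndim == 2:
            cols[name] = v.reshape(-1)
        else:
            for j in range(v.shape[2]):
                cols[f"{name}_{j + 1}"] = v[..., j].reshape(-1)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
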