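"""Serialization: item-bank CSV, result tables, flat config files and
test fixtures."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .irt import ItemBank
from .study import generate_bank, generate_examinees

__all__ = [
    "BankFormatError",
    "read_bank",
    "write_bank",
    "write_results",
    "read_results",
    "load_config",
    "fixture_generator",
]

BANK_COLUMNS = ("item_id", "dimension", "a", "b", "c")


class BankFormatError(ValueError):
    """Raised when a bank CSV violates the schema."""


def read_bank(path: str | os.PathLike) -> ItemBank:
    """Read an item bank from CSV (columns item_id, dimension, a, b, c).

    Errors name the offending column or row (1-based data rows).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise BankFormatError(
            f"{path}: empty file, missing header {','.join(BANK_COLUMNS)}"
        ) from None
    missing = [col for col in BANK_COLUMNS if col not in df.columns]
    if missing:
        raise BankFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise BankFormatError(f"{path}: no item rows")
    for col in BANK_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise BankFormatError(
                f"{path}: non-numeric value in column '{col}' at row {bad[0] + 1}"
            )
    ids = df["item_id"].to_numpy()
    dup = pd.Series(ids).duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise BankFormatError(
            f"{path}: duplicate item_id {ids[row]} at row {row + 1}"
        )
    a = df["a"].to_numpy(float)
    c = df["c"].to_numpy(float)
    if np.any(a <= 0):
        row = int(np.flatnonzero(a <= 0)[0])
        raise BankFormatError(f"{path}: a must be > 0 at row {row + 1}")
    if np.any((c < 0) | (c >= 1)):
        row = int(np.flatnonzero((c < 0) | (c >= 1))[0])
        raise BankFormatError(f"{path}: c must be in [0, 1) at row {row + 1}")
    try:
        return ItemBank(
            df["item_id"].to_numpy(np.int64),
            df["dimension"].to_numpy(np.int64),
            a,
            df["b"].to_numpy(float),
            c,
        )
    except ValueError as exc:
        raise BankFormatError(f"{path}: {exc}") from exc


def write_bank(bank: ItemBank, path: str | os.PathLike) -> None:
    """Write a bank as CSV; floats use repr so read/write round-trips
    at full precision."""
    df = pd.DataFrame(
        {
            "item_id": bank.item_id,
            "dimension": bank.dimension,
            "a": bank.a,
            "b": bank.b,
            "c": bank.c,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_results(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | os.PathLike) -> dict:
    """Load a flat key/value config file (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    return cfg


_FIXTURE_SIZES = {
    # items_per_dim, n_examinees
    "tiny": (20, 50),
    "paper": (300, 5000),
}


def fixture_generator(
    size: str = "tiny",
    rho: float = 0.5,
    bank_seed: int = 11,
    examinee_seed: int = 12,
) -> tuple[ItemBank, np.ndarray]:
    """Deterministic (bank, examinee-trait) fixtures.

    ``tiny`` (20 items/dimension, 50 examinees) keeps tests fast;
    ``paper`` matches the full study design (300/dimension, 5000).
    """
    try:
        items_per_dim, n = _FIXTURE_SIZES[size]
    except KeyError:
        raise ValueError(f"size must be one of {sorted(_FIXTURE_SIZES)}") from None
    bank = generate_bank(np.random.default_rng(bank_seed), items_per_dim)
    examinees = generate_examinees(n, rho, np.random.default_rng(examinee_seed))
    return bank, examinees
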