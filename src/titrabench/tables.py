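"""Abundance tables: per-sample, per-replicate transcript or gene values.

An :class:`AbundanceTable` wraps a wide pandas DataFrame (rows = transcript or
gene ids, columns = a (sample, replicate) MultiIndex) together with a declared
unit:

- ``molar_per_unit_mass`` — concentrations in molecule space; mass mixing is
  linear here, which is what makes the titration fold-change model exact.
- ``count`` — integer read counts.
- ``count_scale`` — real-valued estimated counts (length-scaled TPM sums
  rescaled to a library size, the transcript-to-gene aggregation output).
- ``TPM`` — transcripts per million; every column sums to 1e6.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

UNITS = ("molar_per_unit_mass", "count", "count_scale", "TPM")

_TPM_TOTAL = 1e6
_TPM_RTOL = 1e-6


class AbundanceTable:
    """Wide abundance matrix with a declared unit.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by transcript or gene id; columns a 2-level MultiIndex
        ``(sample, replicate)`` with samples in {A, B, C, D}.
    unit : str
        One of :data:`UNITS`.
    level : str
        ``"transcript"`` or ``"gene"`` — which id the rows carry.
    """

    def __init__(self, values: pd.DataFrame, unit: str, level: str = "transcript"):
        if unit not in UNITS:
            raise ValueError(f"unknown unit {unit!r}; expected one of {UNITS}")
        if level not in ("transcript", "gene"):
            raise ValueError("level must be 'transcript' or 'gene'")
        if not isinstance(values.columns, pd.MultiIndex) or values.columns.nlevels != 2:
            raise ValueError("columns must be a (sample, replicate) MultiIndex")
        vals = values.to_numpy()
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("abundances must be finite and nonnegative")
        if unit == "count" and not np.allclose(vals, np.round(vals)):
            raise ValueError("count tables must hold nonnegative integers")
        if unit == "TPM":
            sums = vals.sum(axis=0)
            if not np.allclose(sums, _TPM_TOTAL, rtol=_TPM_RTOL):
                raise ValueError("TPM columns must each sum to 1e6")
        values = values.copy()
        values.columns = pd.MultiIndex.from_tuples(
            [(str(s), int(r)) for s, r in values.columns], names=["sample", "replicate"]
        )
        self.values = values
        self.unit = unit
        self.level = level

    # -- convenience -----------------------------------------------------
    @property
    def ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.values.columns.get_level_values("sample")))

    def column(self, sample: str, replicate: int = 1) -> pd.Series:
        return self.values[(sample, replicate)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbundanceTable(unit={self.unit!r}, level={self.level!r}, "
            f"shape={self.values.shape})"
        )

    # -- long-format TSV I/O ---------------------------------------------
    def to_long(self) -> pd.DataFrame:
        id_col = f"{self.level}_id"
        long = (
            self.values.stack(["sample", "replicate"], future_stack=True)
            .rename("value")
            .reset_index()
        )
        long.columns = [id_col, "sample", "replicate", "value"]
        return long[["sample", "replicate", id_col, "value"]]

    def write_tsv(self, path: str | Path) -> None:
        long = self.to_long().sort_values(
            ["sample", "replicate", f"{self.level}_id"], kind="mergesort"
        )
        long.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path, unit: str, level: str = "transcript") -> "AbundanceTable":
        long = pd.read_csv(path, sep="\t")
        id_col = f"{level}_id"
        wide = long.pivot_table(
            index=id_col, columns=["sample", "replicate"], values="value", aggfunc="first"
        ).astype(float)
        return cls(wide, unit=unit, level=level)


def to_tpm(
    table: AbundanceTable,
    lengths: pd.Series | dict | None = None,
    read_length: int = 50,
) -> AbundanceTable:
    """Convert a molar or count table to TPM (columns normalized to sum 1e6).

    Counts are first divided by the effective length
    ``max(L - read_length + 1, 1)``; molar values are already proportional to
    molecule numbers and are only rescaled. Raises on an all-zero column
    (nothing to normalize).
    """
    if table.unit == "TPM":
        return table
    vals = table.values.astype(float)
    if table.unit in ("count", "count_scale"):
        if lengths is None:
            raise ValueError("converting counts to TPM requires transcript/gene lengths")
        lens = pd.Series(lengths).reindex(vals.index)
        if lens.isna().any():
            missing = list(vals.index[lens.isna()])[:3]
            raise KeyError(f"missing lengths for {missing}")
        eff = np.maximum(lens.to_numpy(float) - read_length + 1, 1.0)
        vals = vals.div(eff, axis=0)
    sums = vals.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"cannot normalize all-zero column(s): {bad}")
    tpm = vals.div(sums, axis=1) * _TPM_TOTAL
    return AbundanceTable(tpm, unit="TPM", level=table.level)
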