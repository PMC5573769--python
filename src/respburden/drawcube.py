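"""Multi-key containers of posterior draws.

A :class:`DrawCube` holds a vector of posterior draws for every cell of a
keyed table (cause, location, year, age, sex, ...).  All burden accounting
is draw-aligned: arithmetic between cubes is performed draw-by-draw on
identically keyed cells, so correlation between quantities estimated from
the same posterior is preserved through sums, products, and ratios.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["DrawCube"]


class DrawCubeError(ValueError):
    """Raised on misaligned or malformed draw cubes."""


class DrawCube:
    """A keyed array of posterior draws.

    Parameters
    ----------
    keys
        DataFrame of key columns, one row per cell.  Key order is preserved.
    values
        Array of shape ``(n_cells, n_draws)``.
    """

    def __init__(self, keys: pd.DataFrame, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if len(keys) != values.shape[0]:
            raise DrawCubeError(
                f"{len(keys)} key rows but {values.shape[0]} value rows"
            )
        self.keys = keys.reset_index(drop=True)
        self.values = values

    # -- construction -----------------------------------------------------

    @classmethod
    def from_scalar(cls, keys: pd.DataFrame, scalar: float, n_draws: int) -> "DrawCube":
        return cls(keys, np.full((len(keys), n_draws), float(scalar)))

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        key_cols: Sequence[str],
        draw_col: str = "draw",
        value_col: str = "value",
    ) -> "DrawCube":
        wide = df.pivot_table(
            index=list(key_cols), columns=draw_col, values=value_col, sort=True
        )
        wide = wide.sort_index(axis=1)
        keys = wide.index.to_frame(index=False)
        return cls(keys, wide.to_numpy())

    def to_long(self, draw_col: str = "draw", value_col: str = "value") -> pd.DataFrame:
        n = self.n_draws
        rep = self.keys.loc[self.keys.index.repeat(n)].reset_index(drop=True)
        rep[draw_col] = np.tile(np.arange(n), len(self.keys))
        rep[value_col] = self.values.ravel()
        return rep

    # -- basic properties --------------------------------------------------

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    @property
    def key_cols(self) -> list[str]:
        return list(self.keys.columns)

    def __len__(self) -> int:
        return len(self.keys)

    def copy(self) -> "DrawCube":
        return DrawCube(self.keys.copy(), self.values.copy())

    def _key_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.keys)

    # -- alignment ---------------------------------------------------------

    def align_to(self, other: "DrawCube") -> "DrawCube":
        """Reorder ``other`` to this cube's key order; error on mismatch."""
        if other.n_draws != self.n_draws:
            raise DrawCubeError(
                f"draw count mismatch: {self.n_draws} vs {other.n_draws}"
            )
        mine, theirs = self._key_index(), other._key_index()
        if mine.equals(theirs):
            return other
        indexer = theirs.get_indexer(mine)
        if (indexer < 0).any():
            missing = mine[indexer < 0][:3].tolist()
            raise DrawCubeError(f"keys missing from operand, e.g. {missing}")
        return DrawCube(self.keys, other.values[indexer])

    def _binop(self, other, fn) -> "DrawCube":
        if isinstance(other, DrawCube):
            other = self.align_to(other)
            return DrawCube(self.keys, fn(self.values, other.values))
        return DrawCube(self.keys, fn(self.values, other))

    def __add__(self, other):
        return self._binop(other, np.add)

    def __sub__(self, other):
        return self._binop(other, np.subtract)

    def __mul__(self, other):
        return self._binop(other, np.multiply)

    def __truediv__(self, other):
        return self._binop(other, np.divide)

    __radd__ = __add__
    __rmul__ = __mul__

    # -- keyed broadcasting ------------------------------------------------

    def mul_series(self, s: pd.Series | Mapping, level: str | Sequence[str]) -> "DrawCube":
        """Multiply each cell by a value looked up on a subset of key columns.

        ``level`` names the key column(s) used for lookup, e.g. multiplying
        age-specific rates by a population keyed on (location, year, sex,
        age_start).
        """
        levels = [level] if isinstance(level, str) else list(level)
        if not isinstance(s, pd.Series):
            s = pd.Series(dict(s))
        if len(levels) == 1:
            lookup = self.keys[levels[0]].map(s)
        else:
            idx = pd.MultiIndex.from_frame(self.keys[levels])
            lookup = pd.Series(s.reindex(idx).to_numpy(), index=self.keys.index)
        if lookup.isna().any():
            bad = self.keys.loc[lookup.isna(), levels].drop_duplicates().head(3)
            raise DrawCubeError(f"no lookup value for keys:\n{bad}")
        return DrawCube(self.keys, self.values * lookup.to_numpy()[:, None])

    # -- selection and aggregation ----------------------------------------

    def select(self, **conditions) -> "DrawCube":
        mask = np.ones(len(self.keys), dtype=bool)
        for col, val in conditions.items():
            if isinstance(val, (list, tuple, set, np.ndarray)):
                mask &= self.keys[col].isin(list(val)).to_numpy()
            else:
                mask &= (self.keys[col] == val).to_numpy()
        return DrawCube(self.keys[mask], self.values[mask])

    def sum_over(self, drop: str | Iterable[str]) -> "DrawCube":
        """Sum draws over one or more key columns (draw-wise)."""
        drop = [drop] if isinstance(drop, str) else list(drop)
        keep = [c for c in self.keys.columns if c not in drop]
        if not keep:
            total = self.values.sum(axis=0, keepdims=True)
            return DrawCube(pd.DataFrame({"all": ["all"]}), total)
        df = self.keys[keep].copy()
        grouped = {}
        order = []
        for key, idx in df.groupby(keep, sort=False).groups.items():
            grouped[key] = self.values[np.asarray(idx)].sum(axis=0)
            order.append(key)
        keys_out = pd.DataFrame(order, columns=keep)
        return DrawCube(keys_out, np.vstack([grouped[k] for k in order]))

    def total(self) -> np.ndarray:
        """Draw-wise grand total across all cells."""
        return self.values.sum(axis=0)
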