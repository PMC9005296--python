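"""Dinucleotide physicochemical property tables.

A property index (e.g. "Shift", "Slide", "Twist") assigns one real value to
each of the 16 dinucleotides over {A,C,G,T}, describing local DNA geometry or
energetics. Collections of such indices drive the dinucleotide auto-cross
covariance descriptors; published compilations (~148 indices) contain exact
duplicates that are collapsed before clustering.

Values are used exactly as supplied. Many published tables are pre-normalized
(z-scored across the 16 dinucleotides); an optional standardization flag is
provided but defaults off so published worked examples reproduce bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import DINUCLEOTIDES, ConfigError


class PropertyTableError(ValueError):
    """Schema or content problem in a property table."""


@dataclass(frozen=True)
class PropertyTable:
    """Ordered property names with a (n_properties, 16) value matrix.

    Columns follow the canonical lexicographic dinucleotide order
    AA, AC, AG, AT, CA, ..., TT.
    """

    names: tuple[str, ...]
    values: np.ndarray  # shape (len(names), 16), float64

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.names), 16):
            raise PropertyTableError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.names)} properties x 16 dinucleotides"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise PropertyTableError(
                f"non-finite value for property {self.names[bad[0]]!r}, "
                f"dinucleotide {DINUCLEOTIDES[bad[1]]}"
            )
        if len(set(self.names)) != len(self.names):
            seen: set[str] = set()
            dupes = []
            for n in self.names:
                if n in seen:
                    dupes.append(n)
                seen.add(n)
            raise PropertyTableError(f"duplicate property names: {sorted(set(dupes))}")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def vector(self, name: str) -> np.ndarray:
        """The 16-value vector of one property, canonical dinucleotide order."""
        try:
            return self.values[self.names.index(name)]
        except ValueError:
            raise KeyError(f"property {name!r} not in table") from None

    def value(self, name: str, dinucleotide: str) -> float:
        return float(self.vector(name)[DINUCLEOTIDES.index(dinucleotide)])

    def select(self, names: list[str] | tuple[str, ...]) -> "PropertyTable":
        return PropertyTable(tuple(names), np.vstack([self.vector(n) for n in names]))

    def standardized(self) -> "PropertyTable":
        """Z-score each property across its 16 dinucleotide values."""
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return PropertyTable(self.names, (self.values - mu) / sd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names), columns=list(DINUCLEOTIDES))


def load_property_table(path: str | Path, standardize: bool = False) -> PropertyTable:
    """Load a property table from CSV/TSV, auto-detecting the orientation.

    Accepted layouts: one row per property with 16 dinucleotide columns, or
    the transpose (one row per dinucleotide with one column per property).
    Missing dinucleotides, non-numeric cells and duplicate property names are
    rejected with coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]

    dinuc_set = set(DINUCLEOTIDES)
    if dinuc_set.issubset(df.columns):
        oriented = df
    elif dinuc_set.issubset(df.index):
        oriented = df.T
    else:
        cols_missing = sorted(dinuc_set - set(df.columns))
        raise PropertyTableError(
            f"{path}: missing dinucleotide column(s) {cols_missing[:4]} "
            "(in either orientation)"
        )
    extra = [c for c in oriented.columns if c not in dinuc_set]
    if extra:
        raise PropertyTableError(f"{path}: unexpected columns {extra}")
    oriented = oriented[list(DINUCLEOTIDES)]
    if oriented.isna().any().any():
        row, col = next(
            (r, c) for r in oriented.index for c in oriented.columns
            if pd.isna(oriented.at[r, c])
        )
        raise PropertyTableError(f"{path}: missing value at property {row!r}, column {col}")
    try:
        values = oriented.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for r in oriented.index:
            for c in oriented.columns:
                try:
                    float(oriented.at[r, c])
                except (TypeError, ValueError):
                    raise PropertyTableError(
                        f"{path}: non-numeric value {oriented.at[r, c]!r} "
                        f"at property {r!r}, column {c}"
                    ) from None
        raise
    table = PropertyTable(tuple(oriented.index), values)
    return table.standardized() if standardize else table


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    df = table.to_frame()
    df.index.name = "property"
    df.to_csv(Path(path))


def example_shift_slide_table() -> PropertyTable:
    """The bundled two-property fixture table (Shift and Slide).

    Holds the printed values for the six dinucleotides of the worked-example
    sequence TACATTCA; the remaining ten dinucleotides are zero-filled. This
    is a fixture for worked examples and tests, not a published compilation.
    """
    with resources.as_file(
        resources.files("enhkit.data").joinpath("shift_slide_example.csv")
    ) as p:
        return load_property_table(p)


def deduplicate_properties(
    table: PropertyTable, tolerance: float = 0.0, seed: int = 0
) -> PropertyTable:
    """Collapse groups of equivalent properties, keeping one random member.

    Two properties are equivalent when their 16-value vectors agree pairwise
    within ``tolerance`` (exact equality at the default 0). Groups are the
    connected components of the pairwise-equivalence graph; one member per
    group is kept, chosen uniformly at random under ``seed``. Output preserves
    the input order of the kept members, so the retained count is
    seed-independent even though the retained identities are not.
    """
    if tolerance < 0:
        raise ConfigError(f"tolerance must be non-negative, got {tolerance}")
    n = len(table)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.all(np.abs(table.values[i] - table.values[j]) <= tolerance):
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    rng = np.random.default_rng(seed)
    kept = sorted(
        int(members[rng.integers(len(members))]) for members in groups.values()
    )
    return table.select([table.names[i] for i in kept])
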