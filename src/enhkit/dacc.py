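"""Dinucleotide-based auto covariance and cross covariance descriptors.

A DNA sequence of length L has L-1 overlapping dinucleotides. Given a
physicochemical property index phi that maps each dinucleotide to a number,
the sequence becomes a numeric profile; DAC is the lagged auto-covariance of
one property's mean-centered profile, DCC the lagged cross-covariance of two
different properties' profiles:

    DAC(phi, lag)        = sum_{i=1}^{L-lag-1} (P_phi(i) - mean_phi)
                           * (P_phi(i+lag) - mean_phi) / (L - lag - 1)
    DCC(phi1, phi2, lag) = sum_{i=1}^{L-lag-1} (P_phi1(i) - mean_phi1)
                           * (P_phi2(i+lag) - mean_phi2) / (L - lag - 1)

where P_phi(i) is the property value of the dinucleotide starting at position
i (1-based) and mean_phi averages P_phi over all L-1 dinucleotides, repeats
counted with multiplicity. The denominator L - lag - 1 equals the number of
summands. DCC is ordered: phi1 leads, phi2 lags; DCC(phi, phi, lag) reduces
to DAC(phi, lag).

The combined DACC vector concatenates the DAC block (every property x lag,
lag fastest-varying) and the DCC block (every ordered pair of distinct
properties x lag), for N^2 * LAG features from N properties at maximum lag
LAG — 11,045 features for the canonical 47 properties at LAG = 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .property_index import PropertyTable
from .sequence_io import ALPHABET, DnaSequence, LabeledDataset, SequenceError, ConfigError

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class DaccConfig:
    """properties: ordered property names (the N of the dimension formula);
    lag: maximum lag LAG (features use lag = 1 .. LAG)."""

    properties: tuple[str, ...]
    lag: int = 5

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ConfigError(f"LAG must be >= 1, got {self.lag}")
        if not self.properties:
            raise ConfigError("at least one property is required")
        object.__setattr__(self, "properties", tuple(self.properties))

    @property
    def dimension(self) -> int:
        n = len(self.properties)
        return n * n * self.lag


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ConfigError("feature values and labels misaligned")


def _dinucleotide_indices(seq: DnaSequence) -> np.ndarray:
    """Map the L-1 overlapping dinucleotides to indices 0..15 (AA..TT)."""
    codes = np.array([_BASE_INDEX[b] for b in seq.residues], dtype=np.int64)
    if len(codes) < 2:
        raise SequenceError(f"sequence {seq.id!r}: length {len(codes)} < 2")
    return codes[:-1] * 4 + codes[1:]


def _profiles(seq: DnaSequence, names: tuple[str, ...], table: PropertyTable) -> np.ndarray:
    """(L-1, N) matrix of per-position property values."""
    dinucs = _dinucleotide_indices(seq)
    rows = np.vstack([table.vector(name) for name in names])  # (N, 16)
    return rows[:, dinucs].T


def _check_lag(seq: DnaSequence, lag: int) -> None:
    if lag < 1:
        raise ConfigError(f"lag must be >= 1, got {lag}")
    if len(seq) - lag - 1 < 1:
        raise SequenceError(
            f"sequence {seq.id!r}: length {len(seq)} too short for lag {lag} "
            f"(minimum length is {lag + 2})"
        )


def property_mean(seq: DnaSequence, name: str, table: PropertyTable) -> float:
    """Mean property value over the sequence's L-1 dinucleotides."""
    return float(_profiles(seq, (name,), table).mean())


def dac(seq: DnaSequence, name: str, lag: int, table: PropertyTable) -> float:
    """Auto covariance of one property at the given lag."""
    _check_lag(seq, lag)
    p = _profiles(seq, (name,), table)[:, 0]
    d = p - p.mean()
    return float(d[:-lag] @ d[lag:] / (len(seq) - lag - 1))


def dcc(
    seq: DnaSequence, name1: str, name2: str, lag: int, table: PropertyTable
) -> float:
    """Cross covariance: property ``name1`` leads, ``name2`` lags."""
    _check_lag(seq, lag)
    p = _profiles(seq, (name1, name2), table)
    d = p - p.mean(axis=0)
    return float(d[:-lag, 0] @ d[lag:, 1] / (len(seq) - lag - 1))


def feature_labels(config: DaccConfig) -> tuple[str, ...]:
    """Column labels: "DAC|phi|lag" block then "DCC|phi1|phi2|lag" block."""
    labels = [
        f"DAC|{phi}|{lag}"
        for phi in config.properties
        for lag in range(1, config.lag + 1)
    ]
    labels += [
        f"DCC|{phi1}|{phi2}|{lag}"
        for phi1 in config.properties
        for phi2 in config.properties
        if phi1 != phi2
        for lag in range(1, config.lag + 1)
    ]
    return tuple(labels)


def dacc_vector(
    seq: DnaSequence, config: DaccConfig, table: PropertyTable
) -> FeatureVector:
    """The full N^2 * LAG descriptor vector of one sequence.

    Computed in one pass: the (L-1, N) centered profile matrix V yields, for
    each lag, the N x N covariance block V[:-lag].T @ V[lag:] / (L-lag-1)
    whose diagonal is the DAC terms and off-diagonal the ordered DCC terms.
    """
    _check_lag(seq, config.lag)
    p = _profiles(seq, config.properties, table)
    d = p - p.mean(axis=0)
    n = len(config.properties)
    length = len(seq)
    # blocks[lag-1][a, b] = lagged covariance with property a leading, b lagging
    blocks = np.stack(
        [d[:-lag].T @ d[lag:] / (length - lag - 1) for lag in range(1, config.lag + 1)]
    )
    dac_part = blocks[:, np.arange(n), np.arange(n)].T.ravel()  # (N, LAG) -> flat
    off = [(a, b) for a in range(n) for b in range(n) if a != b]
    if off:
        rows, cols = zip(*off)
        dcc_part = blocks[:, rows, cols].T.ravel()
    else:
        dcc_part = np.empty(0)
    return FeatureVector(np.concatenate([dac_part, dcc_part]), feature_labels(config))


def dacc_matrix(
    dataset: LabeledDataset, config: DaccConfig, table: PropertyTable
) -> pd.DataFrame:
    """One descriptor row per sequence; index = sequence ids, columns = labels.

    Per-sequence failures (too-short sequences) are collected and reported
    together rather than aborting on the first.
    """
    labels = feature_labels(config)
    rows, ids, failures = [], [], []
    for seq in dataset.sequences:
        try:
            rows.append(dacc_vector(seq, config, table).values)
            ids.append(seq.id)
        except (SequenceError, ConfigError) as exc:
            failures.append(str(exc))
    if failures:
        raise SequenceError(
            f"{len(failures)} sequence(s) failed DACC extraction:\n  "
            + "\n  ".join(failures)
        )
    data = np.vstack(rows) if rows else np.empty((0, len(labels)))
    return pd.DataFrame(data, index=ids, columns=list(labels))


def write_feature_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(Path(path), index_label="id")


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), index_col="id")
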