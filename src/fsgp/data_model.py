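"""Feature tables for two-class EEG-style classification.

A :class:`FeatureTable` holds a samples-by-features numeric matrix with
named columns and a binary label per row (positive / negative emotion by
default).  CSV input/output, stratified hold-out splitting and z-score
standardization live here; everything downstream (the GP classifier, the
feature-selection driver, the synthetic generator) works on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SplitPair",
    "DataError",
    "FormatError",
    "SchemaError",
    "DEFAULT_CHANNELS",
    "DEFAULT_BANDS",
    "default_feature_names",
    "read_feature_table",
    "write_feature_table",
    "holdout_split",
    "standardize",
]

#: 14 scalp electrode names of the consumer EEG headset layout.
DEFAULT_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Five per-channel spectral band-power summaries (a naming convention;
#: the algorithm only relies on column identity).
DEFAULT_BANDS = ("theta", "alpha", "betaL", "betaH", "gamma")


class DataError(ValueError):
    """Input data violates a contract (bad labels, empty table, ...)."""


class FormatError(ValueError):
    """Malformed input file (missing columns, non-numeric cells, ...)."""


class SchemaError(ValueError):
    """Two tables that must share a schema do not."""


def default_feature_names(channels=DEFAULT_CHANNELS, bands=DEFAULT_BANDS) -> list[str]:
    """``"<channel>_<band>"`` names, channel-major: 14 x 5 = 70 by default."""
    return [f"{ch}_{band}" for ch in channels for band in bands]


@dataclass
class FeatureTable:
    """Named numeric feature matrix plus binary labels.

    ``labels`` is an int array with 1 for the positive class and 0 for the
    negative class; ``class_names`` maps the codes back to the original
    label strings as ``(negative_name, positive_name)``.
    """

    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, str] = ("negative", "positive")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise DataError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataError("duplicate feature names")
        if self.labels.shape != (self.values.shape[0],):
            raise DataError("labels length must equal number of rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise DataError("labels must be encoded 0/1")
        if not np.isfinite(self.values).all():
            raise DataError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_index(self) -> dict[str, int]:
        return {name: j for j, name in enumerate(self.feature_names)}

    def label_strings(self) -> list[str]:
        return [self.class_names[code] for code in self.labels]

    def subset(self, row_indices: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            list(self.feature_names),
            self.values[row_indices],
            self.labels[row_indices],
            self.class_names,
        )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[label_column] = self.label_strings()
        return df


@dataclass
class SplitPair:
    """Disjoint, exhaustive train/test partition of one FeatureTable."""

    train: FeatureTable
    test: FeatureTable
    train_fraction: float
    train_indices: np.ndarray = field(default=None, repr=False)
    test_indices: np.ndarray = field(default=None, repr=False)


def _encode_labels(raw: pd.Series, positive_label: str | None) -> tuple[np.ndarray, tuple[str, str]]:
    strings = raw.astype(str).str.strip()
    distinct = sorted(strings.unique())
    if len(distinct) != 2:
        raise DataError(
            f"label column must contain exactly 2 classes, found {len(distinct)}: "
            f"{distinct[:5]}"
        )
    if positive_label is None:
        if set(distinct) == {"positive", "negative"}:
            positive = "positive"
        else:
            # deterministic fallback: the lexicographically larger label is positive
            positive = distinct[1]
    else:
        positive = str(positive_label)
        if positive not in distinct:
            raise DataError(f"positive label {positive!r} not among classes {distinct}")
    negative = distinct[0] if distinct[1] == positive else distinct[1]
    codes = (strings == positive).to_numpy().astype(int)
    return codes, (negative, positive)


def read_feature_table(
    path,
    label_column: str = "label",
    positive_label: str | None = None,
    delimiter: str = ",",
) -> FeatureTable:
    """Load a delimited text file (header row required) into a FeatureTable.

    Every non-label column is a feature; column order is preserved.  The two
    distinct label values are mapped to classes 1 (positive) / 0 (negative);
    by default the literal strings ``positive``/``negative`` are recognised,
    otherwise the lexicographically larger value is taken as positive unless
    ``positive_label`` overrides it.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    if label_column not in df.columns:
        raise FormatError(f"label column {label_column!r} not found in {path}")
    labels, class_names = _encode_labels(df[label_column], positive_label)
    feats = df.drop(columns=[label_column])
    feature_names = [str(c) for c in feats.columns]
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise FormatError(
            f"non-numeric or missing feature value at row {row}, column {col!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"non-finite feature value at row {int(i)}, column {feature_names[int(j)]!r}"
        )
    return FeatureTable(feature_names, values, labels, class_names)


def write_feature_table(table: FeatureTable, path, label_column: str = "label") -> None:
    """Write the table as CSV with full float precision (round-trip safe)."""
    table.to_dataframe(label_column).to_csv(path, index=False, float_format="%.17g")


def _train_size(n: int, fraction: float) -> int:
    # fixed rounding rule: floor(f*n + 0.5)
    return int(np.floor(fraction * n + 0.5))


def holdout_split(
    table: FeatureTable,
    train_fraction: float = 0.8,
    stratified: bool = True,
    seed: int = 0,
) -> SplitPair:
    """Random hold-out split, stratified by class by default.

    The train size is ``floor(train_fraction * n + 0.5)``; under
    stratification the per-class train counts use the same rule and are then
    adjusted (largest fractional remainder first) so the total is preserved,
    keeping per-class proportions within one sample of ``train_fraction``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = table.n_samples
    n_train = _train_size(n, train_fraction)
    rng = np.random.default_rng(seed)

    if not stratified:
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        class_idx = {c: np.flatnonzero(table.labels == c) for c in (0, 1)}
        for c, idx in class_idx.items():
            if len(idx) < 2:
                raise DataError(
                    f"class {table.class_names[c]!r} has {len(idx)} sample(s); "
                    "stratified split needs at least 2 per class"
                )
        exact = {c: train_fraction * len(idx) for c, idx in class_idx.items()}
        take = {c: _train_size(len(idx), train_fraction) for c, idx in class_idx.items()}
        # reconcile the per-class roundings with the global train size
        order = sorted(class_idx, key=lambda c: exact[c] - np.floor(exact[c]), reverse=True)
        k = 0
        while sum(take.values()) > n_train:
            c = order[k % 2]
            if take[c] > 0:
                take[c] -= 1
            k += 1
        while sum(take.values()) < n_train:
            c = order[k % 2]
            if take[c] < len(class_idx[c]):
                take[c] += 1
            k += 1
        train_parts, test_parts = [], []
        for c in (0, 1):
            perm = rng.permutation(class_idx[c])
            train_parts.append(perm[: take[c]])
            test_parts.append(perm[take[c]:])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts))

    return SplitPair(
        train=table.subset(train_idx),
        test=table.subset(test_idx),
        train_fraction=train_fraction,
        train_indices=train_idx,
        test_indices=test_idx,
    )


def standardize(table: FeatureTable, reference: FeatureTable) -> FeatureTable:
    """Z-score each column of ``table`` using ``reference`` (training) stats.

    Constant reference columns map to all-zero columns rather than dividing
    by zero.  ``reference`` and ``table`` must share feature names.
    """
    if table.feature_names != reference.feature_names:
        raise SchemaError("feature names of table and reference differ")
    mean = reference.values.mean(axis=0)
    sd = reference.values.std(axis=0, ddof=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (table.values - mean) / safe_sd
    z[:, sd == 0] = 0.0
    return FeatureTable(list(table.feature_names), z, table.labels, table.class_names)
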