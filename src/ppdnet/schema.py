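"""Questionnaire schema, CSV I/O and stratified train/test splitting.

The postpartum-depression screening questionnaire is a 10-attribute
instrument: nine ordinal symptom/demographic items plus a binary target
("Feeling anxious").  Responses are integer-coded; for the target,
code 1 means "yes" (anxious, the PPD-positive class) and code 2 means
"no".  Internally labels are stored as {0, 1} with 1 = positive, the
usual confusion-matrix orientation; the CSV dialect keeps the original
1/2 codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSchema",
    "Dataset",
    "SplitConfig",
    "default_schema",
    "read_dataset",
    "write_dataset",
    "split",
    "SchemaError",
    "ValidationError",
]


class SchemaError(ValueError):
    """The CSV header or schema definition does not match expectations."""


class ValidationError(ValueError):
    """A cell value violates the schema's allowed code sets."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered attribute definitions with their integer code sets.

    ``attributes`` maps each attribute name to a dict of
    ``{code: meaning}``; the last entry plays no special role — the
    target is named explicitly.  ``positive_code`` is the target code
    meaning "yes".
    """

    attributes: tuple[tuple[str, dict[int, str]], ...]
    target_name: str
    positive_code: int = 1

    def __post_init__(self) -> None:
        names = [name for name, _ in self.attributes]
        if len(names) != len(set(names)):
            raise SchemaError("duplicate attribute names")
        if self.target_name not in names:
            raise SchemaError(f"target {self.target_name!r} not among attributes")
        if len(self.attributes) != 10:
            raise SchemaError("schema must have exactly 10 attributes")
        target_codes = dict(self.attributes)[self.target_name]
        if len(target_codes) != 2:
            raise SchemaError("target must have exactly 2 allowed codes")
        if self.positive_code not in target_codes:
            raise SchemaError("positive_code not an allowed target code")

    @property
    def feature_names(self) -> list[str]:
        return [n for n, _ in self.attributes if n != self.target_name]

    @property
    def feature_codes(self) -> list[set[int]]:
        return [set(c) for n, c in self.attributes if n != self.target_name]

    @property
    def negative_code(self) -> int:
        (neg,) = [c for c in dict(self.attributes)[self.target_name] if c != self.positive_code]
        return neg

    def to_dict(self) -> dict:
        """Plain-dict form suitable for YAML/JSON config files."""
        return {
            "attributes": [
                {"name": name, "codes": {int(c): m for c, m in codes.items()}}
                for name, codes in self.attributes
            ],
            "target_name": self.target_name,
            "positive_code": self.positive_code,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        attrs = tuple(
            (a["name"], {int(c): m for c, m in a["codes"].items()}) for a in d["attributes"]
        )
        return cls(attrs, d["target_name"], int(d.get("positive_code", 1)))


# Table-of-record attribute set for the questionnaire: age in five bands,
# eight three-level symptom items, binary anxiety target.
_AGE_CODES = {1: "25-30", 2: "30-35", 3: "35-40", 4: "40-45", 5: "45-50"}
_SYMPTOM_ITEMS: tuple[tuple[str, dict[int, str]], ...] = (
    ("Feeling sad or Tearful", {1: "yes", 2: "sometimes", 3: "no"}),
    ("Irritable towards baby and partner", {1: "yes", 2: "sometimes", 3: "no"}),
    ("Trouble sleeping at night", {1: "yes", 2: "two or more days a week", 3: "no"}),
    ("Problems concentrating or making decision", {1: "yes", 2: "often", 3: "no"}),
    ("Overeating or loss of appetite", {1: "yes", 2: "not at all", 3: "no"}),
    ("Suicide attempt", {1: "yes", 2: "not interested to say", 3: "no"}),
    ("Feeling of guilt", {1: "yes", 2: "maybe", 3: "no"}),
    ("Problems of bonding with baby", {1: "yes", 2: "sometimes", 3: "no"}),
)


def default_schema() -> FeatureSchema:
    """The standard 10-attribute PPD questionnaire schema."""
    attrs = (
        ("Age", _AGE_CODES),
        *_SYMPTOM_ITEMS,
        ("Feeling anxious", {1: "yes", 2: "no"}),
    )
    return FeatureSchema(attributes=attrs, target_name="Feeling anxious", positive_code=1)


@dataclass(frozen=True)
class Dataset:
    """An integer-coded feature matrix ``X`` (n x 9) and binary labels ``y``.

    ``y`` uses 1 = positive (anxious / PPD-positive), 0 = negative.
    """

    X: np.ndarray
    y: np.ndarray
    schema: FeatureSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.int64)
        y = np.asarray(self.y, dtype=np.int64)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or X.shape[1] != len(self.schema.feature_names):
            raise ValidationError(
                f"X must be n x {len(self.schema.feature_names)}, got {X.shape}"
            )
        if y.shape != (X.shape[0],):
            raise ValidationError("y length must match X rows")
        if X.shape[0] < 1:
            raise ValidationError("dataset must contain at least one record")
        for j, allowed in enumerate(self.schema.feature_codes):
            bad = ~np.isin(X[:, j], sorted(allowed))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"row {row}, column {self.schema.feature_names[j]!r}: "
                    f"code {X[row, j]} not in {sorted(allowed)}"
                )
        if not np.isin(y, [0, 1]).all():
            row = int(np.flatnonzero(~np.isin(y, [0, 1]))[0])
            raise ValidationError(f"row {row}: label {y[row]} not in {{0, 1}}")

    @property
    def n(self) -> int:
        return int(self.X.shape[0])

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.X[idx], self.y[idx], self.schema)

    def to_frame(self) -> pd.DataFrame:
        """Encoded DataFrame in the CSV dialect (target back to 1/2 codes)."""
        df = pd.DataFrame(self.X, columns=self.schema.feature_names)
        target = np.where(self.y == 1, self.schema.positive_code, self.schema.negative_code)
        df[self.schema.target_name] = target
        return df


def _normalize(name: str) -> str:
    return " ".join(name.strip().lower().split())


def read_dataset(path, schema: FeatureSchema | None = None) -> Dataset:
    """Read an encoded CSV into a validated :class:`Dataset`.

    Header matching is order-, case- and whitespace-insensitive.  Columns
    outside the schema are dropped by name; a missing schema column is an
    error.  The target codes are mapped positive→1, negative→0.
    """
    schema = schema or default_schema()
    df = pd.read_csv(path)
    lookup = {_normalize(c): c for c in df.columns}
    wanted = [name for name, _ in schema.attributes]
    missing = [w for w in wanted if _normalize(w) not in lookup]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df[[lookup[_normalize(w)] for w in wanted]]
    df.columns = wanted

    for col in wanted:
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"row {row}, column {col!r}: non-integer cell {series.iloc[row]!r}")
    df = df.astype(np.int64)

    target_codes = df[schema.target_name].to_numpy()
    allowed_target = set(dict(schema.attributes)[schema.target_name])
    bad = ~np.isin(target_codes, sorted(allowed_target))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"row {row}, column {schema.target_name!r}: code {target_codes[row]} "
            f"not in {sorted(allowed_target)}"
        )
    y = (target_codes == schema.positive_code).astype(np.int64)
    X = df[schema.feature_names].to_numpy()
    return Dataset(X, y, schema)


def write_dataset(data: Dataset, path) -> None:
    """Write a Dataset to CSV in the encoded dialect (round-trips exactly)."""
    data.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SplitConfig:
    """Train/test split parameters.

    ``train_fraction`` in (0, 1); the test size is ``round(n * (1 -
    train_fraction))`` with ties rounding half away from zero, so the
    split sizes depend only on ``n`` and the fraction, never the seed.
    Stratification (default) preserves the 65/35 class balance, which
    keeps 9:1 splits stable.
    """

    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split(data: Dataset, cfg: SplitConfig) -> tuple[Dataset, Dataset]:
    """Partition a dataset into disjoint, exhaustive train/test subsets."""
    n = data.n
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_test = _round_half_away(n * (1.0 - cfg.train_fraction))
    n_test = min(max(n_test, 1), n - 1)  # both sides non-empty
    rng = np.random.default_rng(cfg.seed)

    if not cfg.stratified:
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
    else:
        classes = [np.flatnonzero(data.y == c) for c in (0, 1)]
        if any(len(c) == 0 for c in classes):
            raise ValueError("stratified split needs at least one record per class")
        # largest-remainder apportionment of the test quota across classes
        quotas = [len(c) * n_test / n for c in classes]
        base = [int(math.floor(q)) for q in quotas]
        short = n_test - sum(base)
        order = np.argsort([base[i] - quotas[i] for i in range(2)])  # largest remainder first
        for i in order[:short]:
            base[i] += 1
        test_parts, train_parts = [], []
        for cls_idx, k in zip(classes, base):
            k = min(k, len(cls_idx) - 1) if len(cls_idx) > 1 else k
            perm = rng.permutation(cls_idx)
            test_parts.append(perm[:k])
            train_parts.append(perm[k:])
        test_idx = np.concatenate(test_parts)
        train_idx = np.concatenate(train_parts)
        # apportionment clipping can leave the quota short by at most one
        if len(test_idx) < n_test:
            mover = train_idx[-1]
            train_idx, test_idx = train_idx[:-1], np.append(test_idx, mover)

    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("degenerate split: one side is empty")
    return data.subset(np.sort(train_idx)), data.subset(np.sort(test_idx))
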