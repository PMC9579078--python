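"""Response-matrix container and validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


@dataclass(frozen=True)
class ResponseMatrix:
    """An N x J integer response matrix.

    ``values[i, j]`` is the response of person ``i`` to item ``j``, coded
    ``0..K_j`` where ``K_j + 1 = n_categories[j]`` (``K_j = 1`` for a
    dichotomous item). Missing responses are rejected at construction.
    """

    values: np.ndarray
    n_categories: np.ndarray
    person_ids: tuple = field(default=None)
    item_names: tuple = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise DataError("responses must form a 2-d matrix")
        n, j = values.shape
        if n < 2 or j < 2:
            raise DataError(f"need at least 2 persons and 2 items, got {n} x {j}")
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("responses must be numeric")
        fv = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(fv)):
            bad = np.argwhere(~np.isfinite(fv))[0]
            raise DataError(f"missing/non-finite response at row {bad[0]}, column {bad[1]}")
        iv = fv.astype(np.int64)
        if not np.array_equal(iv, fv):
            bad = np.argwhere(iv != fv)[0]
            raise DataError(f"non-integer response at row {bad[0]}, column {bad[1]}")
        ncat = np.asarray(self.n_categories, dtype=np.int64)
        if ncat.shape != (j,):
            raise DataError("n_categories must give one category count per item")
        if np.any(ncat < 2):
            raise DataError("every item needs at least 2 categories")
        if np.any(iv < 0) or np.any(iv >= ncat[None, :]):
            bad = np.argwhere((iv < 0) | (iv >= ncat[None, :]))[0]
            raise DataError(
                f"response out of range at row {bad[0]}, column {bad[1]}: "
                f"value {iv[bad[0], bad[1]]} not in 0..{ncat[bad[1]] - 1}"
            )
        object.__setattr__(self, "values", iv)
        object.__setattr__(self, "n_categories", ncat)
        pid = self.person_ids
        object.__setattr__(
            self, "person_ids", tuple(pid) if pid is not None else tuple(range(n))
        )
        names = self.item_names
        object.__setattr__(
            self,
            "item_names",
            tuple(names) if names is not None else tuple(f"item{k + 1:02d}" for k in range(j)),
        )
        if len(self.person_ids) != n:
            raise DataError("person_ids length does not match the number of rows")
        if len(self.item_names) != j:
            raise DataError("item_names length does not match the number of columns")

    @classmethod
    def from_array(cls, values, n_categories=None, person_ids=None, item_names=None):
        """Build a ResponseMatrix, inferring per-item category counts if omitted.

        Inference uses ``max + 1`` per column (at least 2 categories).
        """
        values = np.asarray(values)
        if n_categories is None:
            n_categories = np.maximum(values.max(axis=0), 1) + 1
        return cls(values, n_categories, person_ids, item_names)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def is_dichotomous(self) -> bool:
        return bool(np.all(self.n_categories == 2))

    def raw_scores(self) -> np.ndarray:
        """Per-person sum score."""
        return self.values.sum(axis=1)
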