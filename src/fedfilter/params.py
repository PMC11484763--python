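"""Named parameter collections with element-wise arithmetic.

Model parameters, filter parameters and their gradients/deltas are all held
as ordered ``name -> ndarray`` maps.  The federation layer only ever needs
element-wise add / subtract / scale and exact copies, which is what this
container provides; it is deliberately dumb so that every model family and
the filtering module can share it.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterator, Mapping

import numpy as np

__all__ = ["ParamDict"]


class ParamDict(Mapping[str, np.ndarray]):
    """Immutable-keyed, ordered mapping of named float64 arrays."""

    def __init__(self, arrays: Mapping[str, np.ndarray] | None = None):
        self._d: "OrderedDict[str, np.ndarray]" = OrderedDict()
        if arrays is not None:
            for k, v in arrays.items():
                self._d[k] = np.asarray(v, dtype=np.float64)

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> np.ndarray:
        return self._d[key]

    def __setitem__(self, key: str, value: np.ndarray) -> None:
        self._d[key] = np.asarray(value, dtype=np.float64)

    def __iter__(self) -> Iterator[str]:
        return iter(self._d)

    def __len__(self) -> int:
        return len(self._d)

    def __repr__(self) -> str:
        shapes = ", ".join(f"{k}:{v.shape}" for k, v in self._d.items())
        return f"ParamDict({shapes})"

    # -- arithmetic (shape- and key-checked) ------------------------------
    def _check_keys(self, other: "ParamDict") -> None:
        if list(self._d) != list(other._d):
            raise ValueError(
                f"parameter name mismatch: {list(self._d)} vs {list(other._d)}"
            )

    def __add__(self, other: "ParamDict") -> "ParamDict":
        self._check_keys(other)
        return ParamDict({k: self._d[k] + other._d[k] for k in self._d})

    def __sub__(self, other: "ParamDict") -> "ParamDict":
        self._check_keys(other)
        return ParamDict({k: self._d[k] - other._d[k] for k in self._d})

    def scale(self, factor: float) -> "ParamDict":
        return ParamDict({k: self._d[k] * factor for k in self._d})

    def copy(self) -> "ParamDict":
        return ParamDict({k: self._d[k].copy() for k in self._d})

    def zeros_like(self) -> "ParamDict":
        return ParamDict({k: np.zeros_like(self._d[k]) for k in self._d})

    # -- reductions / checks ----------------------------------------------
    def all_finite(self) -> bool:
        return all(np.all(np.isfinite(v)) for v in self._d.values())

    def max_abs(self) -> float:
        return max((float(np.max(np.abs(v))) if v.size else 0.0) for v in self._d.values())

    def n_elements(self) -> int:
        return int(sum(v.size for v in self._d.values()))

    def allclose(self, other: "ParamDict", rtol: float = 0.0, atol: float = 0.0) -> bool:
        self._check_keys(other)
        return all(
            np.allclose(self._d[k], other._d[k], rtol=rtol, atol=atol) for k in self._d
        )

    def equals(self, other: "ParamDict") -> bool:
        """Bit-exact equality of every array."""
        self._check_keys(other)
        return all(np.array_equal(self._d[k], other._d[k]) for k in self._d)

    # -- (de)serialisation -------------------------------------------------
    def to_arrays(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, v.copy()) for k, v in self._d.items())


def mean_paramdicts(dicts: list[ParamDict]) -> ParamDict:
    """Unweighted element-wise mean of a non-empty list of ParamDicts."""
    if not dicts:
        raise ValueError("cannot average an empty list of parameter sets")
    acc = dicts[0].copy()
    for d in dicts[1:]:
        acc = acc + d
    return acc.scale(1.0 / len(dicts))
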