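"""Outcome containers shared across the selection pipeline.

The pipeline handles three outcome kinds: right-censored survival
(time + 0/1 event indicator), binary, and continuous.  ``OutcomeSpec`` is a
small validated container that every stage accepts; helpers coerce common
array layouts (e.g. a 2-column ``[time, event]`` array or a scikit-survival
structured array) into it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["OutcomeSpec", "as_outcome"]

_KINDS = ("survival", "binary", "continuous")


@dataclass(frozen=True)
class OutcomeSpec:
    """A validated outcome vector for one cohort.

    Exactly one of the three layouts is populated:

    - ``survival``: ``time`` (non-negative) and ``event`` (0/1);
    - ``binary``: ``event`` (0/1);
    - ``continuous``: ``value`` (finite reals).
    """

    kind: str
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    value: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "survival":
            t = np.asarray(self.time, dtype=float)
            e = np.asarray(self.event)
            if t.ndim != 1 or e.shape != t.shape:
                raise ValueError("time and event must be 1-d and equal length")
            if np.any(t < 0) or not np.all(np.isfinite(t)):
                raise ValueError("survival times must be finite and >= 0")
            e = _as01(e, "event")
            object.__setattr__(self, "time", t)
            object.__setattr__(self, "event", e)
        elif self.kind == "binary":
            e = _as01(np.asarray(self.event), "binary outcome")
            object.__setattr__(self, "event", e)
        else:
            v = np.asarray(self.value, dtype=float)
            if v.ndim != 1 or not np.all(np.isfinite(v)):
                raise ValueError("continuous outcome must be finite and 1-d")
            object.__setattr__(self, "value", v)

    # ---- constructors -------------------------------------------------
    @classmethod
    def survival(cls, time, event) -> "OutcomeSpec":
        return cls("survival", time=time, event=event)

    @classmethod
    def binary(cls, y) -> "OutcomeSpec":
        return cls("binary", event=y)

    @classmethod
    def continuous(cls, y) -> "OutcomeSpec":
        return cls("continuous", value=y)

    # ---- basic protocol ----------------------------------------------
    @property
    def n(self) -> int:
        for arr in (self.time, self.event, self.value):
            if arr is not None:
                return int(arr.size)
        raise AssertionError("unreachable")

    def __len__(self) -> int:
        return self.n

    @property
    def n_events(self) -> int | None:
        return int(self.event.sum()) if self.event is not None else None

    @property
    def event_mask(self) -> np.ndarray:
        """Mask used for event-stratified splitting.

        For a continuous outcome there is no event structure; the mask splits
        at the median so splits stay balanced on outcome level.
        """
        if self.kind == "continuous":
            return self.value > np.median(self.value)
        return self.event.astype(bool)

    def subset(self, idx) -> "OutcomeSpec":
        idx = np.asarray(idx)
        if self.kind == "survival":
            return OutcomeSpec.survival(self.time[idx], self.event[idx])
        if self.kind == "binary":
            return OutcomeSpec.binary(self.event[idx])
        return OutcomeSpec.continuous(self.value[idx])


def _as01(arr: np.ndarray, what: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.dtype == bool:
        a = a.astype(int)
    a = a.astype(float)
    if a.ndim != 1 or not np.all(np.isin(a, (0.0, 1.0))):
        raise ValueError(f"{what} must be a 1-d 0/1 vector")
    return a.astype(int)


def as_outcome(y, kind: str | None = None) -> OutcomeSpec:
    """Coerce ``y`` into an :class:`OutcomeSpec`.

    Accepted layouts: an ``OutcomeSpec`` (returned as is); a tuple
    ``(time, event)``; a structured array with ``event``/``time`` fields
    (scikit-survival convention, in either field order); a 2-column array
    ``[time, event]``; a plain 0/1 vector (binary) or real vector
    (continuous).  ``kind`` disambiguates plain vectors when given.
    """
    if isinstance(y, OutcomeSpec):
        return y
    if isinstance(y, tuple) and len(y) == 2:
        return OutcomeSpec.survival(*y)
    arr = np.asarray(y)
    if arr.dtype.names:
        names = arr.dtype.names
        tname = next(n for n in names if n.lower().startswith(("time", "futime", "t")))
        ename = next(n for n in names if n != tname)
        return OutcomeSpec.survival(arr[tname].astype(float), arr[ename])
    if arr.ndim == 2 and arr.shape[1] == 2:
        return OutcomeSpec.survival(arr[:, 0], arr[:, 1])
    if kind == "binary" or (
        kind is None and np.all(np.isin(arr.astype(float), (0.0, 1.0)))
    ):
        return OutcomeSpec.binary(arr)
    return OutcomeSpec.continuous(arr)
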