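"""Small fixed-size rolling windows used by the half-day engine."""

from __future__ import annotations

__all__ = ["RollingSum", "TrendWindow"]


class RollingSum:
    """Fixed-length circular buffer with an O(1) running sum."""

    __slots__ = ("size", "data", "i", "total")

    def __init__(self, size: int, fill: float = 0.0):
        if size < 1:
            raise ValueError("window size must be >= 1")
        self.size = size
        self.data = [float(fill)] * size
        self.i = 0
        self.total = float(fill) * size

    def push(self, value: float) -> float:
        """Insert a value, evicting the oldest; returns the evicted value."""
        i = self.i
        old = self.data[i]
        self.data[i] = value
        self.total += value - old
        self.i = (i + 1) % self.size
        return old

    def mean(self) -> float:
        return self.total / self.size


class TrendWindow:
    """Recent-half minus older-half mean over a 2*half window.

    New values enter the recent half; values it evicts cascade into the
    older half.  ``trend()`` is positive when the recent mean exceeds the
    older mean — the monthly up/down signal behind the trust stock.
    """

    __slots__ = ("recent", "older")

    def __init__(self, half: int, fill: float = 0.0):
        self.recent = RollingSum(half, fill)
        self.older = RollingSum(half, fill)

    def push(self, value: float) -> None:
        evicted = self.recent.push(value)
        self.older.push(evicted)

    def trend(self) -> float:
        return self.recent.mean() - self.older.mean()
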