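"""Transcript frequency spectra.

The frequency spectrum is the central summary statistic of the package: for
``n`` samples it counts, for every ``k`` in ``1..n``, the number of orthogroups
whose transcripts were observed in exactly ``k`` samples.  The empirical
spectrum is integer-valued; the model's expectation is real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FrequencySpectrum", "TheoreticalSpectrum"]


@dataclass(frozen=True)
class FrequencySpectrum:
    """Empirical spectrum ``d_1..d_n`` over ``n`` samples.

    ``d[k-1]`` is the number of orthogroups present in exactly ``k`` samples;
    the sum of ``d`` is the total number of orthogroups observed.
    """

    n: int
    d: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"need at least one sample, got n={self.n}")
        if len(self.d) != self.n:
            raise ValueError(f"spectrum length {len(self.d)} != n={self.n}")
        if any(x < 0 for x in self.d):
            raise ValueError("spectrum counts must be non-negative")
        object.__setattr__(self, "d", tuple(int(x) for x in self.d))

    @property
    def total(self) -> int:
        return int(sum(self.d))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.d, dtype=float)

    @classmethod
    def from_counts(cls, occupancies, n: int) -> "FrequencySpectrum":
        """Build from an iterable of per-orthogroup occupancies in ``1..n``."""
        d = [0] * n
        for k in occupancies:
            if not 1 <= k <= n:
                raise ValueError(f"occupancy {k} outside 1..{n}")
            d[k - 1] += 1
        return cls(n=n, d=tuple(d))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": np.arange(1, self.n + 1), "d_k": self.d})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FrequencySpectrum":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("k")
        n = int(df["k"].max())
        d = [0] * n
        for k, dk in zip(df["k"], df["d_k"]):
            d[int(k) - 1] = int(dk)
        return cls(n=n, d=tuple(d))


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """Model expectation ``t_1..t_n`` of the frequency spectrum."""

    n: int
    t: tuple[float, ...] = field()

    def __post_init__(self) -> None:
        if len(self.t) != self.n:
            raise ValueError(f"spectrum length {len(self.t)} != n={self.n}")
        if any(x < 0 for x in self.t):
            raise ValueError("expected counts must be non-negative")
        object.__setattr__(self, "t", tuple(float(x) for x in self.t))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.t, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": np.arange(1, self.n + 1), "t_k": self.t})
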