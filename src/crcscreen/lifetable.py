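"""Other-cause (non-CRC) mortality via an annual life table.

The default table renders a Gompertz–Makeham hazard mu(x) = A + B*exp(theta*x)
to annual death probabilities, with parameters chosen so that remaining life
expectancy at age 45 is close to a modern US cohort (~37 years).  Any table
can be supplied as a CSV with header ``age,q``; the last row must have q = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Gompertz–Makeham defaults (fitted so e(45) ~= 37 years; see docs/methods.md)
GM_MAKEHAM = 3.4e-4
GM_B = 2.4e-5
GM_THETA = 0.094
MAX_AGE = 100


@dataclass(frozen=True)
class LifeTable:
    """Annual probabilities ``q`` of non-CRC death at integer ``ages``."""

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.ndim != 1 or ages.size == 0 or q.shape != ages.shape:
            raise ConfigurationError("life table: ages and q must be equal-length 1-D")
        if not np.all(np.diff(ages) == 1):
            raise ConfigurationError("life table: ages must be contiguous integers")
        if np.any((q < 0) | (q > 1)):
            raise ConfigurationError("life table: q must lie in [0, 1]")
        if q[-1] != 1.0:
            raise ConfigurationError("life table: final age must have q = 1")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def _index(self, age: int) -> int:
        if age < self.ages[0] or age > self.ages[-1]:
            raise ConfigurationError(f"life table: age {age} outside table range")
        return int(age - self.ages[0])

    def survival_from(self, age: int) -> np.ndarray:
        """S(x) for x = age..max_age+1, conditional on being alive at `age`."""
        i = self._index(age)
        s = np.concatenate([[1.0], np.cumprod(1.0 - self.q[i:])])
        return s

    def expected_death_age(self, age: int) -> float:
        """Closed-form E[death age | alive at `age`], deaths uniform in-year."""
        i = self._index(age)
        s = self.survival_from(age)[:-1]          # S at start of each year
        pdie = s * self.q[i:]                     # mass of death in each year
        years = np.arange(age, self.ages[-1] + 1)
        return float(np.sum(pdie * (years + 0.5)) / np.sum(pdie))

    def sample_death_age(self, age: int, u: float) -> float:
        """Inverse-CDF draw of the death age conditional on being alive at `age`.

        The within-year position reuses the residual of the same uniform, so a
        single U(0,1) determines the death age.
        """
        i = self._index(age)
        s = self.survival_from(age)               # length m+1, s[0]=1, s[-1]=0
        # death occurs in year j where s[j+1] <= 1-u < s[j]
        target = 1.0 - u
        j = int(np.searchsorted(-s, -target, side="right")) - 1
        j = min(max(j, 0), s.size - 2)
        lo, hi = s[j + 1], s[j]
        frac = (hi - target) / (hi - lo) if hi > lo else 0.5
        return float(age + j + frac)

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "q": self.q}).to_csv(path, index=False)


def load_life_table_csv(path) -> LifeTable:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["age", "q"]:
        raise ConfigurationError("life table CSV must have header 'age,q'")
    return LifeTable(df["age"].to_numpy(), df["q"].to_numpy())


def gompertz_makeham_table(
    makeham: float = GM_MAKEHAM,
    b: float = GM_B,
    theta: float = GM_THETA,
    max_age: int = MAX_AGE,
) -> LifeTable:
    """Render the GM hazard to an annual life table with q(max_age) = 1."""
    ages = np.arange(0, max_age + 1)
    # integral of the hazard over [x, x+1]
    cumh = makeham + (b / theta) * np.exp(theta * ages) * (np.exp(theta) - 1.0)
    q = 1.0 - np.exp(-cumh)
    q[-1] = 1.0
    return LifeTable(ages, q)


DEFAULT_LIFE_TABLE = gompertz_makeham_table()
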