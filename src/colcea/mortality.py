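"""Background all-cause mortality and its combination with disease mortality.

The cohort model needs an annual probability of death from any cause at each
attained age.  That probability has two components: the age-specific
background probability read from a national life table, and the
disease-specific probability estimated by regimen and time in state.  The two
are combined under independent competing risks,

    q_combined = 1 - (1 - q_disease) (1 - q_background),

which always yields a valid probability no lower than either component.  An
additive-capped policy (``min(q_d + q_b, 1)``) is also provided so the effect
of the convention can be examined.

Life tables are abridged: each record gives the annual death probability that
applies from a band-start age up to the next band.  Lookup is a step function
(no interpolation).  :func:`band_to_annual` converts a published multi-year
band probability to the constant annual probability with the same cumulative
survival.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "LifeTable",
    "annual_background_q",
    "band_to_annual",
    "combine_mortality",
    "load_life_table",
]


@dataclass(frozen=True)
class LifeTable:
    """Ordered (band-start age, annual death probability) records.

    ``max_age`` is the last age the table claims to cover; lookups beyond it
    are a range error rather than a silent extrapolation.
    """

    ages: np.ndarray       # band start ages, strictly increasing
    q_annual: np.ndarray   # annual probability applying from that age
    max_age: float = 100.0

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        q = np.asarray(self.q_annual, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)
        if ages.ndim != 1 or ages.shape != q.shape or ages.size == 0:
            raise ValueError("life table needs matching 1-d age and q arrays")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("band start ages must be strictly increasing")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("annual death probabilities must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path: str | Path, max_age: float | None = None) -> "LifeTable":
        """Read a two-column delimited file: age, annual death probability.

        Lines starting with ``#`` are comments.  ``max_age`` defaults to the
        last band-start age (the final band is one year wide by default).
        """
        rows = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                if parts[0].lower() in ("age", "age_start"):
                    continue
                rows.append((float(parts[0]), float(parts[1])))
        if not rows:
            raise ValueError(f"no life-table records in {path}")
        ages = np.array([r[0] for r in rows])
        q = np.array([r[1] for r in rows])
        return cls(ages, q, max_age=float(max_age) if max_age is not None
                   else float(ages[-1]))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("age,q_annual\n")
            for a, q in zip(self.ages, self.q_annual):
                fh.write(f"{a:g},{q:.6g}\n")


def annual_background_q(table: LifeTable, age: float) -> float:
    """Annual background death probability at an attained age (step lookup)."""
    if age < table.ages[0] or age > table.max_age:
        raise ValueError(
            f"age {age} outside life-table coverage "
            f"[{table.ages[0]:g}, {table.max_age:g}]"
        )
    idx = int(np.searchsorted(table.ages, age, side="right")) - 1
    return float(table.q_annual[idx])


def band_to_annual(q_band: float, band_width: float) -> float:
    """Annual probability equivalent to a multi-year band probability.

    Solves (1 - q_annual)^band_width = 1 - q_band.
    """
    if not 0.0 <= q_band <= 1.0:
        raise ValueError("band probability must lie in [0, 1]")
    if band_width < 1:
        raise ValueError("band width must be at least 1 year")
    return 1.0 - (1.0 - q_band) ** (1.0 / band_width)


def combine_mortality(p_disease: float, p_background: float,
                      policy: str = "product") -> float:
    """Combine disease-specific and background annual death probabilities.

    ``product`` is the independent-competing-risk form
    1 - (1 - p_d)(1 - p_b); ``additive`` is min(p_d + p_b, 1).
    """
    if not 0.0 <= p_disease <= 1.0 or not 0.0 <= p_background <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    if policy == "product":
        return 1.0 - (1.0 - p_disease) * (1.0 - p_background)
    if policy == "additive":
        return min(p_disease + p_background, 1.0)
    raise ValueError(f"unknown combination policy {policy!r}")


def load_life_table(name: str = "tha_2019") -> LifeTable:
    """Load a bundled life table: ``tha_2019`` or ``stylized``."""
    fname = {"tha_2019": "lifetable_tha_2019.csv",
             "stylized": "lifetable_stylized.csv"}.get(name)
    if fname is None:
        raise ValueError(f"unknown bundled life table {name!r}")
    ref = resources.files("colcea.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return LifeTable.from_csv(path)
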