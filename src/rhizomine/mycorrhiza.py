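"""Trouvelot-style quantification of arbuscular mycorrhizal colonization.

Root segments (typically 60 per plant) are scored under the microscope
on two ordinal scales: a colonization class 0-5 (fraction of the
segment occupied by fungal structures) and an arbuscule class A0-A3
(abundance of arbuscules within the colonized cortex).  Five summary
percentages follow:

* ``F``  mycorrhizal frequency: % of segments with any colonization;
* ``M``  colonization intensity over the whole root system;
* ``m``  intensity restricted to colonized segments;
* ``a``  arbuscule abundance within colonized segments;
* ``A``  arbuscule abundance over the whole root system (= a*M/100).

Class midpoints (95, 70, 30, 5, 1 for classes 5..1) and arbuscule
weights (100, 50, 10 for A3..A1) follow the standard visual-estimation
convention; both are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

#: percentage contribution of colonization classes 0..5
CLASS_COEFFICIENTS = (0.0, 1.0, 5.0, 30.0, 70.0, 95.0)

#: weight of arbuscule classes A0..A3 in the ``a`` parameter
ARBUSCULE_WEIGHTS = (0.0, 10.0, 50.0, 100.0)


@dataclass(frozen=True)
class SegmentScore:
    """One root segment's microscopy scores."""

    colonization_class: int
    arbuscule_class: int = 0

    def __post_init__(self):
        if not 0 <= self.colonization_class <= 5:
            raise ValueError(
                f"colonization class {self.colonization_class} outside 0-5"
            )
        if not 0 <= self.arbuscule_class <= 3:
            raise ValueError(f"arbuscule class {self.arbuscule_class} outside 0-3")
        if self.colonization_class == 0 and self.arbuscule_class != 0:
            raise ValueError("an uncolonized segment cannot carry arbuscules")


@dataclass(frozen=True)
class ColonizationParams:
    """The five Trouvelot percentages, all in [0, 100]."""

    F: float
    M: float
    m: float
    a: float
    A: float


def trouvelot(
    scores: Sequence[SegmentScore],
    class_coefficients: Sequence[float] = CLASS_COEFFICIENTS,
    arbuscule_weights: Sequence[float] = ARBUSCULE_WEIGHTS,
) -> ColonizationParams:
    """Compute F, M, m, a, A from per-segment scores.

    With ``N`` segments of which ``n0`` are uncolonized and ``c(s)``
    the class midpoint of segment ``s``:

    * ``F = 100 (N - n0)/N``
    * ``M = sum c(s) / N``
    * ``m = M N / (N - n0)`` (0 when nothing is colonized)
    * ``a = sum_i w_i * mA_i / 100`` where ``mA_i`` is the percentage
      of the colonized intensity contributed by segments of arbuscule
      class ``i``
    * ``A = a M / 100``
    """
    if not scores:
        raise ValueError("no segment scores given")
    n = len(scores)
    n0 = sum(1 for s in scores if s.colonization_class == 0)
    f = 100.0 * (n - n0) / n
    intensity = sum(class_coefficients[s.colonization_class] for s in scores)
    m_big = intensity / n
    if n == n0:
        return ColonizationParams(F=0.0, M=0.0, m=0.0, a=0.0, A=0.0)
    m_small = m_big * n / (n - n0)

    # share of colonized intensity contributed by each arbuscule class
    a = 0.0
    for arb_class in (1, 2, 3):
        contrib = sum(
            class_coefficients[s.colonization_class]
            for s in scores
            if s.arbuscule_class == arb_class
        )
        m_a = contrib / (n - n0)  # intensity share of this arbuscule class
        a += arbuscule_weights[arb_class] * (100.0 * m_a / m_small) / 100.0
    big_a = a * m_big / 100.0
    return ColonizationParams(F=f, M=m_big, m=m_small, a=a, A=big_a)


def trouvelot_by_plant(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-plant parameters from a long table.

    Expects columns ``plant``, ``colonization_class`` and (optionally)
    ``arbuscule_class``; returns one row per plant with F, M, m, a, A.
    """
    required = {"plant", "colonization_class"}
    if not required <= set(scores.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    rows = {}
    for plant, group in scores.groupby("plant", sort=True):
        segs = [
            SegmentScore(
                colonization_class=int(r.colonization_class),
                arbuscule_class=int(getattr(r, "arbuscule_class", 0) or 0),
            )
            for r in group.itertuples()
        ]
        params = trouvelot(segs)
        rows[plant] = {
            "F": params.F,
            "M": params.M,
            "m": params.m,
            "a": params.a,
            "A": params.A,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "plant"
    return out
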