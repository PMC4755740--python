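"""PSI estimation from cassette-exon junction counts and differential
splicing between conditions.

A cassette event is quantified from its three junction classes: I1 and I2,
the upstream- and downstream-inclusion junction reads, and E, the skipping
(exclusion) junction reads.  With m = (I1 + I2) / 2, percent spliced in is

    PSI = 100 * m / (m + E)

Replicates are pooled per condition before estimation; differential events
are those with a two-sided exact-test p < 0.05 and |dPSI| >= 15 percent
points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

P_CUTOFF = 0.05
DPSI_CUTOFF = 15.0


@dataclass(frozen=True)
class JunctionCounts:
    event_id: str
    condition: str
    replicate: int
    inclusion_upstream: int
    inclusion_downstream: int
    exclusion: int

    def __post_init__(self) -> None:
        for v in (self.inclusion_upstream, self.inclusion_downstream, self.exclusion):
            if v < 0 or int(v) != v:
                raise ValueError(f"event {self.event_id}: junction counts must be non-negative integers")


@dataclass(frozen=True)
class PsiEstimate:
    event_id: str
    condition: str
    psi: float  # percent, in [0, 100]
    support: int  # I1 + I2 + E after pooling


@dataclass(frozen=True)
class DiffSpliceResult:
    event_id: str
    psi_a: float
    psi_b: float
    delta_psi: float  # psi_b - psi_a, percent points
    p_value: float
    passes: bool
    regulation_class: str  # repressed_target | activated_target | unchanged


def _pool(counts: Iterable[JunctionCounts]) -> tuple[str, str, int, int, int]:
    counts = list(counts)
    if not counts:
        raise ValueError("no junction counts to pool")
    ids = {c.event_id for c in counts}
    conds = {c.condition for c in counts}
    if len(ids) != 1 or len(conds) != 1:
        raise ValueError(f"pooling requires a single event/condition, got {ids}/{conds}")
    i1 = sum(c.inclusion_upstream for c in counts)
    i2 = sum(c.inclusion_downstream for c in counts)
    e = sum(c.exclusion for c in counts)
    return ids.pop(), conds.pop(), i1, i2, e


def estimate_psi(counts: Sequence[JunctionCounts]) -> PsiEstimate | None:
    """Pool replicates of one event/condition and estimate PSI.

    Returns ``None`` when the pooled support I1 + I2 + E is zero (the event
    cannot be evaluated in this condition).
    """
    event_id, condition, i1, i2, e = _pool(counts)
    support = i1 + i2 + e
    if support == 0:
        return None
    m = (i1 + i2) / 2.0
    psi = 100.0 * m / (m + e)
    return PsiEstimate(event_id=event_id, condition=condition, psi=psi, support=support)


def diff_splice(
    counts_a: Sequence[JunctionCounts],
    counts_b: Sequence[JunctionCounts],
    p_cutoff: float = P_CUTOFF,
    dpsi_cutoff: float = DPSI_CUTOFF,
) -> DiffSpliceResult | None:
    """Differential splicing of one event between two conditions.

    dPSI = PSI(b) - PSI(a) in percent points, from replicate-pooled counts.
    The p-value is a two-sided Fisher exact test on the 2x2 table of rounded
    inclusion evidence m = (I1 + I2) / 2 versus exclusion E for the two
    conditions.  ``passes`` requires p < ``p_cutoff`` and
    |dPSI| >= ``dpsi_cutoff``; passing events are classed ``repressed_target``
    (dPSI > 0: the regulator was repressing inclusion) or
    ``activated_target`` (dPSI < 0).

    Returns ``None`` when either condition has zero support; such events are
    excluded from downstream tallies.
    """
    est_a = estimate_psi(counts_a)
    est_b = estimate_psi(counts_b)
    if est_a is None or est_b is None:
        return None
    _, _, i1a, i2a, ea = _pool(counts_a)
    _, _, i1b, i2b, eb = _pool(counts_b)
    table = [
        [round((i1a + i2a) / 2.0), ea],
        [round((i1b + i2b) / 2.0), eb],
    ]
    p_value = float(sps.fisher_exact(table, alternative="two-sided")[1])
    delta = est_b.psi - est_a.psi
    passes = p_value < p_cutoff and abs(delta) >= dpsi_cutoff
    if passes:
        regulation_class = "repressed_target" if delta > 0 else "activated_target"
    else:
        regulation_class = "unchanged"
    return DiffSpliceResult(
        event_id=est_a.event_id,
        psi_a=est_a.psi,
        psi_b=est_b.psi,
        delta_psi=delta,
        p_value=p_value,
        passes=passes,
        regulation_class=regulation_class,
    )


def classify_quadrant(
    kd_result: DiffSpliceResult,
    diff_result: DiffSpliceResult,
    dpsi_cutoff: float = DPSI_CUTOFF,
) -> str:
    """Quadrant class of an exon in the knockdown-vs-differentiation plane.

    Sign conventions: kd dPSI = knockdown - control; diff dPSI =
    differentiated - progenitor.  ``repressed_neuronal`` exons gain inclusion
    both on regulator knockdown and during differentiation (both >= +cutoff);
    ``activated_neuronal`` exons lose it in both (both <= -cutoff); anything
    else is ``other``.
    """
    kd, diff = kd_result.delta_psi, diff_result.delta_psi
    if kd >= dpsi_cutoff and diff >= dpsi_cutoff:
        return "repressed_neuronal"
    if kd <= -dpsi_cutoff and diff <= -dpsi_cutoff:
        return "activated_neuronal"
    return "other"


def psi_concordance(psi_x: Sequence[float], psi_y: Sequence[float]) -> float:
    """Squared Pearson correlation (R^2) of paired PSI vectors.

    Undefined (NaN) when either vector is constant; requires length >= 3.
    """
    x = np.asarray(psi_x, dtype=float)
    y = np.asarray(psi_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("psi_concordance needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
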