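"""The three theoretical epidemic-threshold predictors.

All thresholds are expressed in the effective spreading rate λ = β/γ with the
γ = 1 convention:

* MFL (mean-field-like / heterogeneous mean-field): λ_c = ⟨k⟩ / (⟨k²⟩ − ⟨k⟩),
  degree distribution only.
* QMF (quenched mean-field): λ_c = 1 / Λ_A, adjacency spectral radius.
* DMP (dynamical message passing): λ_c = 1 / Λ_M, non-backtracking leading
  eigenvalue.  Undefined on trees; flagged when Λ_M ≤ 1 since no transition
  is reachable with β ≤ 1.

On any cyclic connected graph Λ_M ≤ Λ_A, hence λ_c^QMF ≤ λ_c^DMP; on
uncorrelated configuration networks Λ_M → ⟨k²⟩/⟨k⟩ − 1 and the MFL and DMP
predictions coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .netio import DegreeStats, degree_stats
from .network import Network
from .spectral import NoCycleError, adjacency_leading, nb_leading

__all__ = [
    "ThresholdSet",
    "UndefinedThresholdError",
    "mfl_threshold",
    "qmf_threshold",
    "dmp_threshold",
    "threshold_set",
]


class UndefinedThresholdError(ValueError):
    """The predictor has no finite positive value on this graph."""


@dataclass(frozen=True)
class ThresholdSet:
    mfl: float
    qmf: float
    dmp: Optional[float]  # None when the graph is a tree
    dmp_flag: bool = False  # True when λ_c^DMP ≥ 1 (no admissible transition)


def mfl_threshold(stats: DegreeStats) -> float:
    """λ_c^MFL = ⟨k⟩ / (⟨k²⟩ − ⟨k⟩)."""
    if stats.mean_k2 <= stats.mean_k:
        raise UndefinedThresholdError(
            "MFL threshold undefined: <k^2> <= <k> (no excess degree)"
        )
    return stats.mean_k / (stats.mean_k2 - stats.mean_k)


def qmf_threshold(lambda_A: float) -> float:
    """λ_c^QMF = 1 / Λ_A."""
    if lambda_A <= 0:
        raise UndefinedThresholdError("QMF threshold needs Lambda_A > 0")
    return 1.0 / lambda_A


def dmp_threshold(lambda_M: float) -> tuple[float, bool]:
    """λ_c^DMP = 1 / Λ_M, with a flag when Λ_M ≤ 1.

    With γ = 1 the admissible range is λ = β ≤ 1, so Λ_M ≤ 1 means the
    predicted transition cannot be reached by the dynamics.
    """
    if lambda_M <= 0:
        raise UndefinedThresholdError("DMP threshold needs Lambda_M > 0")
    return 1.0 / lambda_M, lambda_M <= 1.0 + 1e-9


def threshold_set(net: Network, stats: DegreeStats | None = None) -> ThresholdSet:
    """All three predictors on one network (tree → ``dmp=None``)."""
    if stats is None:
        stats = degree_stats(net)
    mfl = mfl_threshold(stats)
    qmf = qmf_threshold(adjacency_leading(net).leading_eigenvalue)
    try:
        dmp, flag = dmp_threshold(nb_leading(net).leading_eigenvalue)
    except NoCycleError:
        dmp, flag = None, False
    return ThresholdSet(mfl=mfl, qmf=qmf, dmp=dmp, dmp_flag=flag)
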