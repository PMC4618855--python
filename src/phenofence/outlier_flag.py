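"""Intra-cluster Tukey-fence screening of onset dates.

Within each contextually homogeneous cluster, the onset day-of-year values
are summarized by a Tukey boxplot: quartiles are computed as Tukey hinges
(medians of the lower and upper halves of the sorted data, the overall median
included in both halves when n is odd) and the fences sit 1.5 interquartile
ranges beyond the hinges.  Observations below the lower fence are flagged as
inconsistently early, above the upper fence as inconsistently late.  Under a
normal distribution about 0.7% of points fall outside the fences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Observation
from .gmm_cluster import ClusterAssignments

__all__ = [
    "TukeyFences",
    "ConsistencyFlag",
    "UndersizedClusterError",
    "tukey_fences",
    "flag_intra_cluster",
    "summarize_flags",
]

MIN_CLUSTER_SIZE = 5


class UndersizedClusterError(ValueError):
    """Too few values to compute stable quartiles (default minimum 5)."""


@dataclass(frozen=True)
class TukeyFences:
    q1: float
    median: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr

    def is_outlier(self, value: float) -> bool:
        return value < self.lower or value > self.upper


@dataclass(frozen=True)
class ConsistencyFlag:
    """Per-observation verdict from the intra-cluster screen."""

    obs_id: str
    verdict: str  # consistent | inconsistent_early | inconsistent_late | unresolved
    cluster: int  # -1 for unresolved points outside any retained cluster
    uncertainty: float
    distance_to_fence: float  # days beyond the violated fence; 0 if consistent


def tukey_fences(values: Sequence[float], min_n: int = MIN_CLUSTER_SIZE) -> TukeyFences:
    """Tukey hinges and 1.5*IQR fences for a sample of onset DOYs."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < min_n:
        raise UndersizedClusterError(f"need at least {min_n} values, got {n}")
    half = n // 2 + (n % 2)  # include the median in both halves when n is odd
    q1 = float(np.median(x[:half]))
    q3 = float(np.median(x[n - half:]))
    return TukeyFences(q1=q1, median=float(np.median(x)), q3=q3)


def flag_intra_cluster(
    observations: Sequence[Observation],
    assignments: ClusterAssignments,
    retained: np.ndarray,
    ignored: np.ndarray,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
) -> list[ConsistencyFlag]:
    """Screen every observation's onset DOY against its cluster's fences.

    ``retained``/``ignored`` are index arrays from the uncertainty filter.
    Ignored points and members of clusters smaller than ``min_cluster_size``
    receive the verdict "unresolved"; no fence is attempted for them.
    """
    if len(assignments) != len(observations):
        raise ValueError("assignments do not cover all observations")
    n = len(observations)
    doys = np.array([o.onset_doy for o in observations], dtype=float)
    labels = assignments.labels
    unc = assignments.uncertainty
    retained_mask = np.zeros(n, dtype=bool)
    retained_mask[retained] = True

    fences: dict[int, TukeyFences | None] = {}
    for lab in np.unique(labels[retained_mask]):
        members = doys[retained_mask & (labels == lab)]
        try:
            fences[int(lab)] = tukey_fences(members, min_n=min_cluster_size)
        except UndersizedClusterError:
            fences[int(lab)] = None

    flags: list[ConsistencyFlag] = []
    for i, obs in enumerate(observations):
        lab = int(labels[i])
        if not retained_mask[i] or fences.get(lab) is None:
            flags.append(
                ConsistencyFlag(obs.obs_id, "unresolved", lab if retained_mask[i] else -1,
                                float(unc[i]), 0.0)
            )
            continue
        f = fences[lab]
        if doys[i] < f.lower:
            verdict, dist = "inconsistent_early", f.lower - doys[i]
        elif doys[i] > f.upper:
            verdict, dist = "inconsistent_late", doys[i] - f.upper
        else:
            verdict, dist = "consistent", 0.0
        flags.append(ConsistencyFlag(obs.obs_id, verdict, lab, float(unc[i]), dist))
    return flags


def summarize_flags(
    flags: Sequence[ConsistencyFlag],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Counts and rates per verdict, per cluster and overall.

    Rates are reported against two denominators: all observations, and the
    resolved observations only (n minus unresolved) — the latter matches
    counting inconsistency only among records that received a verdict.  When
    everything is unresolved the resolved-denominator rates are NaN.
    """
    df = pd.DataFrame(
        {
            "cluster": [f.cluster for f in flags],
            "verdict": [f.verdict for f in flags],
        }
    )
    per_cluster = (
        df.groupby("cluster")["verdict"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(
            columns=["consistent", "inconsistent_early", "inconsistent_late", "unresolved"],
            fill_value=0,
        )
        .reset_index()
    )
    n = len(flags)
    n_unres = int((df["verdict"] == "unresolved").sum())
    n_incon = int(df["verdict"].str.startswith("inconsistent").sum())
    n_cons = int((df["verdict"] == "consistent").sum())
    resolved = n - n_unres
    overall = {
        "n": n,
        "n_consistent": n_cons,
        "n_inconsistent": n_incon,
        "n_unresolved": n_unres,
        "inconsistent_rate_all": n_incon / n if n else float("nan"),
        "inconsistent_rate_resolved": n_incon / resolved if resolved else float("nan"),
        "consistent_rate_resolved": n_cons / resolved if resolved else float("nan"),
    }
    return per_cluster, overall
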