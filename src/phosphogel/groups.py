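"""Group-level spot-count and rank statistics.

Counts phospho-positive, shared and group-unique spots between the two
sample groups and provides the two conventional tests used alongside them:
a two-tailed Fisher exact test on phospho-positive proportions and a
two-tailed Mann-Whitney U test on mean-PR columns. Both tests are standard
procedures and are delegated to :mod:`scipy.stats`; the package's tests
cross-check them against exact enumeration on small inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .tables import spots_present

#: largest combined sample size for which the Mann-Whitney P is computed by
#: exact enumeration (only possible without ties)
MANN_WHITNEY_EXACT_MAX_N = 12


@dataclass(frozen=True)
class GroupSpotCounts:
    """Reproducible / phospho-positive / shared / unique spot counts."""

    n_reproducible_treated: int
    n_reproducible_control: int
    n_phospho_treated: int
    n_phospho_control: int
    n_shared_phospho: int

    def __post_init__(self):
        assert self.n_unique_treated >= 0 and self.n_unique_control >= 0
        assert self.n_phospho_treated <= self.n_reproducible_treated
        assert self.n_phospho_control <= self.n_reproducible_control

    @property
    def n_unique_treated(self) -> int:
        return self.n_phospho_treated - self.n_shared_phospho

    @property
    def n_unique_control(self) -> int:
        return self.n_phospho_control - self.n_shared_phospho

    def as_dict(self) -> dict:
        return {
            "n_reproducible_treated": self.n_reproducible_treated,
            "n_reproducible_control": self.n_reproducible_control,
            "n_phospho_treated": self.n_phospho_treated,
            "n_phospho_control": self.n_phospho_control,
            "n_shared_phospho": self.n_shared_phospho,
            "n_unique_treated": self.n_unique_treated,
            "n_unique_control": self.n_unique_control,
        }


def spot_group_counts(treated, control, min_reps: int = 2) -> GroupSpotCounts:
    """Count reproducible and phospho-positive spots per group.

    Expects reproducibility-filtered tables. A spot is reproducible when its
    total-protein signal appears in >= ``min_reps`` replicates of the group,
    and phospho-positive when additionally its phospho signal does.
    """
    (tg,) = treated["group"].unique()
    (cg,) = control["group"].unique()
    rep_t = spots_present(treated, tg, "total", min_reps)
    rep_c = spots_present(control, cg, "total", min_reps)
    pho_t = spots_present(treated, tg, "phospho", min_reps) & rep_t
    pho_c = spots_present(control, cg, "phospho", min_reps) & rep_c
    return GroupSpotCounts(
        n_reproducible_treated=len(rep_t),
        n_reproducible_control=len(rep_c),
        n_phospho_treated=len(pho_t),
        n_phospho_control=len(pho_c),
        n_shared_phospho=len(pho_t & pho_c),
    )


def phospho_percentage(k: int, n: int) -> float:
    """Percentage 100*k/n rounded to one decimal (report convention)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return round(100.0 * k / n, 1)


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact P for the 2x2 table ((a, b), (c, d)).

    Uses the dominant two-sided convention: the sum of hypergeometric
    probabilities of all tables with the observed margins that are no more
    probable than the observed table. Degenerate margins give P = 1 with a
    warning.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); P = 1")
        return 1.0
    return float(scipy.stats.fisher_exact(table, alternative="two-sided").pvalue)


def mann_whitney_two_tailed(x, y, exact_max_n: int = MANN_WHITNEY_EXACT_MAX_N):
    """Two-tailed Mann-Whitney U test; returns ``(U, P)``.

    ``U`` is the statistic of the first sample with midrank handling of
    ties. The P-value is exact (full enumeration of rank arrangements) when
    ``len(x) + len(y) <= exact_max_n`` and there are no ties, otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) \
        else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
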