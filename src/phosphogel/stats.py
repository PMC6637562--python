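"""Core phosphorylation statistics.

The quantitative unit is the phosphorylation rate ``PR = P/T`` of a 2-DE
spot, the ratio of its phospho-stain (Pro-Q Diamond) volume to its
total-protein (SYPRO Ruby) volume on the same gel. Per spot and sample
group, the mean PR over biological replicates is summarized with a
simultaneous confidence interval obtained by the bias-corrected (BC)
percentile bootstrap at a Bonferroni-adjusted confidence level.

Between-group change is expressed two ways:

* fold change ``FC = PR_treated / PR_control``, with ratios below one
  reported as their negative reciprocal, so |FC| >= 1 always and group-unique
  spots take the values +inf / -inf;
* relative change ``RC = DPR / |DPR_max|`` where ``DPR`` is the between-group
  difference of mean PR and ``DPR_max`` its maximum over the analyzed spots.
  RC is bounded in [-1, +1] for shared and group-unique spots alike, which is
  what makes it usable where FC degenerates to +-inf.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .exceptions import UndefinedFoldChangeError, UndefinedPRError
from .tables import spot_sort_key, spots_present, validate_spot_table

logger = logging.getLogger(__name__)

#: PR above this triggers a warning: a spot's phospho volume should rarely
#: exceed 1.5x its total-protein volume even across stain sensitivities.
PR_WARN_THRESHOLD = 1.5

DEFAULT_N_BOOT = 20_000


@dataclass
class PRSummary:
    """Per spot x group phosphorylation-rate summary.

    ``ci_lower``/``ci_upper`` are ``None`` (printed as N/A) for a group with
    no detected phospho signal, whose mean PR is 0 by convention.
    """

    spot_id: str
    group: str
    pr_values: list[float] = field(default_factory=list)
    mean_pr: float = 0.0
    se_pr: float = 0.0
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_boot: int = 0
    conf_adjusted: float | None = None

    @property
    def has_signal(self) -> bool:
        return self.ci_lower is not None


@dataclass
class DifferentialRecord:
    """Per-spot between-group change: DPR, FC, RC and the significance call."""

    spot_id: str
    pr_treated: float
    pr_control: float
    dpr: float
    fc: float  # may be +-inf
    rc: float | None = None
    significant: str = "no"  # one of {"yes", "no", "not_evaluable"}


def phosphorylation_rate(p_volume: float, t_volume: float) -> float:
    """PR = P/T for one spot on one replicate gel.

    Values above 1 are legitimate (the two stains have unrelated response
    factors) but values above :data:`PR_WARN_THRESHOLD` are logged as
    suspicious. A zero total volume leaves PR undefined.
    """
    if t_volume == 0:
        raise UndefinedPRError("total-stain volume is zero; PR undefined")
    if p_volume < 0 or t_volume < 0:
        raise ValueError("volumes must be non-negative")
    pr = p_volume / t_volume
    if pr > PR_WARN_THRESHOLD:
        logger.warning("PR = %.3f exceeds %.1f; check spot matching/volumes",
                       pr, PR_WARN_THRESHOLD)
    return pr


def bc_bootstrap_ci(values, conf: float = 0.95, n_boot: int = DEFAULT_N_BOOT,
                    seed=None, rng: np.random.Generator | None = None):
    """Bias-corrected percentile bootstrap CI for the mean of ``values``.

    ``n_boot`` resamples of size ``N = len(values)`` are drawn with
    replacement and their means collected. The bias-correction term
    ``z0 = Phi^-1(p)`` uses ``p``, the proportion of bootstrap means strictly
    below the observed mean (ties are not half-counted), clamped to
    ``[1/(2 n_boot), 1 - 1/(2 n_boot)]`` so z0 stays finite for degenerate
    resampling distributions. The bounds are the empirical quantiles of the
    bootstrap means at ``Phi(2 z0 -+ z_(1+conf)/2)``.

    All-identical input returns the degenerate interval ``(v, v)``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least 2 values for a bootstrap CI")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    if np.ptp(v) == 0:
        return float(v[0]), float(v[0])
    if rng is None:
        rng = np.random.default_rng(seed)
    n = v.size
    idx = rng.integers(0, n, size=(n_boot, n))
    means = v[idx].mean(axis=1)
    observed = v.mean()
    p = np.count_nonzero(means < observed) / n_boot
    clamp = 1.0 / (2 * n_boot)
    if p <= clamp or p >= 1 - clamp:
        logger.warning("bias-correction proportion clamped (p = %.5f)", p)
    p = min(max(p, clamp), 1 - clamp)
    z0 = ndtri(p)
    za = ndtri((1 + conf) / 2)
    a_lo = ndtr(2 * z0 - za)
    a_hi = ndtr(2 * z0 + za)
    return float(np.quantile(means, a_lo)), float(np.quantile(means, a_hi))


def bonferroni_conf(alpha: float = 0.05, m: int = 1) -> float:
    """Per-comparison confidence level 1 - alpha/m for m simultaneous CIs."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return 1 - alpha / m


def significance_call(summary_treated: PRSummary, summary_control: PRSummary) -> str:
    """Compare two adjusted per-group CIs for one spot.

    Rules (the simultaneous-CI analogue of a Bonferroni-corrected test):

    * neither group has phospho signal -> ``"not_evaluable"``;
    * exactly one group has signal -> ``"yes"`` iff that group's CI excludes
      zero (CL > 0);
    * both have signal -> ``"yes"`` iff the two CIs do not overlap.
    """
    if summary_treated.spot_id != summary_control.spot_id:
        raise ValueError("summaries are for different spots")
    t, c = summary_treated, summary_control
    if not t.has_signal and not c.has_signal:
        return "not_evaluable"
    if t.has_signal != c.has_signal:
        lone = t if t.has_signal else c
        return "yes" if lone.ci_lower > 0 else "no"
    return "yes" if (t.ci_lower > c.ci_upper or c.ci_lower > t.ci_upper) else "no"


def fold_change(pr_treated: float, pr_control: float) -> float:
    """FC = PR_treated/PR_control with the negative-reciprocal convention.

    Ratios below one are reported as -1/ratio so |FC| >= 1 always; a zero in
    exactly one group yields +-inf; both zero is undefined.
    """
    if pr_treated < 0 or pr_control < 0:
        raise ValueError("mean PRs must be non-negative")
    if pr_treated == 0 and pr_control == 0:
        raise UndefinedFoldChangeError("both group mean PRs are zero")
    if pr_control == 0:
        return math.inf
    if pr_treated == 0:
        return -math.inf
    r = pr_treated / pr_control
    return r if r >= 1 else -1.0 / r


def relative_change(records: list[DifferentialRecord]) -> list[DifferentialRecord]:
    """Fill ``rc`` on each record: RC = DPR / |DPR_max| over the supplied set.

    ``DPR_max`` is the maximum (signed) DPR over the records, so the argmax
    record gets RC = +1 exactly whenever ``DPR_max > 0``. If every DPR is
    zero all RCs are set to 0 with a warning.

    Boundedness in [-1, +1] is the point of the coefficient, so when the
    largest-magnitude change is negative (|DPR| of some record exceeds the
    signed maximum) the denominator falls back to max |DPR|, with a warning;
    signs are always preserved.
    """
    if not records:
        raise ValueError("no records supplied")
    dprs = np.array([r.dpr for r in records])
    dpr_max = dprs.max()
    if np.all(dprs == 0):
        warnings.warn("all DPR values are zero; RC set to 0 for every record")
        for r in records:
            r.rc = 0.0
        return records
    denom = abs(dpr_max)
    largest = float(np.abs(dprs).max())
    if denom < largest:
        denom = largest
        warnings.warn("|DPR_max| smaller than max |DPR|; scaling RC by "
                      "max |DPR| to keep RC within [-1, +1]")
    for r in records:
        r.rc = r.dpr / denom
    return records


def _pr_values_for_group(table: pd.DataFrame, spot_id: str, group: str,
                         min_reps: int) -> tuple[list[float], bool]:
    """Per-replicate PRs of one spot in one group.

    Replicates are those where the spot is present on the total channel; a
    replicate with no phospho signal contributes PR = 0. Returns the PR list
    and whether the group counts as phospho-positive (phospho signal in at
    least ``min_reps`` replicates).
    """
    sub = table[(table["spot_id"] == spot_id) & (table["group"] == group)
                & table["present"]]
    total = sub[sub["channel"] == "total"].set_index("replicate")["volume"]
    phospho = sub[sub["channel"] == "phospho"].set_index("replicate")["volume"]
    prs = []
    for rep, t in total.items():
        if t <= 0:
            logger.warning("spot %s %s rep %s: zero total volume; replicate "
                           "excluded from PR", spot_id, group, rep)
            continue
        p = phospho.get(rep, 0.0)
        prs.append(phosphorylation_rate(p, t))
    positive = int((phospho > 0).sum()) >= min_reps
    return prs, positive


def summarize_spot(table: pd.DataFrame, spot_id: str, group: str,
                   conf_adjusted: float, n_boot: int, min_reps: int,
                   rng: np.random.Generator) -> PRSummary:
    """Build the :class:`PRSummary` for one spot in one group."""
    prs, positive = _pr_values_for_group(table, spot_id, group, min_reps)
    if not positive or not prs:
        return PRSummary(spot_id=spot_id, group=group)
    arr = np.asarray(prs)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    if arr.size >= 2:
        cl, cu = bc_bootstrap_ci(arr, conf=conf_adjusted, n_boot=n_boot, rng=rng)
    else:
        cl = cu = float(arr[0])
    return PRSummary(spot_id=spot_id, group=group, pr_values=list(map(float, arr)),
                     mean_pr=float(arr.mean()), se_pr=se, ci_lower=cl, ci_upper=cu,
                     n_boot=n_boot, conf_adjusted=conf_adjusted)


def analyze_spot_set(treated: pd.DataFrame, control: pd.DataFrame,
                     alpha: float = 0.05, n_boot: int = DEFAULT_N_BOOT,
                     seed=None, min_reps: int = 2, bonferroni_m: int | None = None,
                     rc_universe: str = "significant"):
    """Run the per-spot differential phosphorylation analysis.

    Expects two already-normalized, reproducibility-filtered tables (one per
    group). The spot universe is the intersection of spots detected on the
    total channel in both groups; the Bonferroni family size ``m`` defaults
    to the number of universe spots with phospho signal in at least one
    group. RC is scaled over the significant spots by default
    (``rc_universe="all"`` uses every phospho-positive spot).

    Returns ``(summaries, records)``: a list of :class:`PRSummary` (two per
    analyzed spot, treated first) and a list of :class:`DifferentialRecord`,
    both sorted by spot id.
    """
    treated = validate_spot_table(treated.copy())
    control = validate_spot_table(control.copy())
    (t_group,) = treated["group"].unique()
    (c_group,) = control["group"].unique()
    if rc_universe not in ("significant", "all"):
        raise ValueError("rc_universe must be 'significant' or 'all'")

    universe = (spots_present(treated, t_group, "total", 1)
                & spots_present(control, c_group, "total", 1))
    if not universe:
        raise ValueError("no spot is present in both groups; nothing to compare")

    phospho_t = spots_present(treated, t_group, "phospho", min_reps)
    phospho_c = spots_present(control, c_group, "phospho", min_reps)
    analyzed = sorted((phospho_t | phospho_c) & universe, key=spot_sort_key)
    if not analyzed:
        raise ValueError("no phospho-positive spot in the common universe")

    m = bonferroni_m if bonferroni_m is not None else len(analyzed)
    conf = bonferroni_conf(alpha, m)
    rng = np.random.default_rng(seed)

    summaries: list[PRSummary] = []
    records: list[DifferentialRecord] = []
    for sid in analyzed:
        st = summarize_spot(treated, sid, t_group, conf, n_boot, min_reps, rng)
        sc = summarize_spot(control, sid, c_group, conf, n_boot, min_reps, rng)
        call = significance_call(st, sc)
        summaries.extend([st, sc])
        rec = DifferentialRecord(
            spot_id=sid, pr_treated=st.mean_pr, pr_control=sc.mean_pr,
            dpr=st.mean_pr - sc.mean_pr,
            fc=fold_change(st.mean_pr, sc.mean_pr),
            significant=call)
        records.append(rec)

    scaled = [r for r in records if r.significant == "yes"] \
        if rc_universe == "significant" else records
    if scaled:
        relative_change(scaled)
    return summaries, records


def records_from_means(mean_prs: pd.DataFrame, treated_col: str = "pr_treated",
                       control_col: str = "pr_control") -> list[DifferentialRecord]:
    """Build FC/RC records directly from a table of per-group mean PRs.

    Used to recompute change coefficients from published summary tables
    (``mean_prs`` indexed by spot_id). All supplied spots form the RC
    scaling universe.
    """
    records = []
    for sid, row in mean_prs.iterrows():
        pt, pc = float(row[treated_col]), float(row[control_col])
        records.append(DifferentialRecord(
            spot_id=str(sid), pr_treated=pt, pr_control=pc, dpr=pt - pc,
            fc=fold_change(pt, pc), significant="yes"))
    return relative_change(records)


def summaries_frame(summaries: list[PRSummary]) -> pd.DataFrame:
    """Long-format DataFrame view of PR summaries."""
    return pd.DataFrame([{
        "spot_id": s.spot_id, "group": s.group, "mean_pr": s.mean_pr,
        "se_pr": s.se_pr, "ci_lower": s.ci_lower, "ci_upper": s.ci_upper,
        "n_boot": s.n_boot, "conf_adjusted": s.conf_adjusted,
    } for s in summaries])


def records_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """DataFrame view of differential records (FC serialized as +-inf floats)."""
    return pd.DataFrame([{
        "spot_id": r.spot_id, "pr_treated": r.pr_treated,
        "pr_control": r.pr_control, "dpr": r.dpr, "fc": r.fc, "rc": r.rc,
        "significant": r.significant,
    } for r in records])
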