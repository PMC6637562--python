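"""Bundled reference dataset: the published DFD-vs-control phosphoproteome summary.

The packaged CSV holds the printed per-spot summary of a dual-stained 2-DE
comparison of DFD (dark, firm and dry) and control bovine *longissimus
thoracis* meat: for each of the 32 significantly changed phosphoprotein
spots, the group mean PRs with standard errors and Bonferroni-adjusted 95%
bias-corrected bootstrap CIs, plus the published FC and RC values. Raw
replicate volumes were never deposited, so this summary table is the
dataset against which the change statistics can be recomputed.

Published group-level counts of the same study are exposed as constants.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

#: reproducible spots (total-protein channel, >= 2 of 4 replicates)
REPRODUCIBLE_TREATED = 314
REPRODUCIBLE_CONTROL = 308
#: phospho-positive among reproducible spots
PHOSPHO_TREATED = 46
PHOSPHO_CONTROL = 41
SHARED_PHOSPHO = 28
#: spots analyzed quantitatively (phospho signal in at least one group)
ANALYZED_SPOTS = 59


def load_significant_spots() -> pd.DataFrame:
    """Load the 32-spot reference summary, indexed by spot id.

    Columns: ``protein``, ``pr_dfd_mean``, ``pr_dfd_se``, ``pr_dfd_cl``,
    ``pr_dfd_cu``, the control equivalents (NaN CI columns mean "N/A": no
    phospho signal in that group), and the published ``fc_printed`` (+-inf
    for group-unique spots) and ``rc_printed``.
    """
    with importlib.resources.files("phosphogel.data").joinpath(
            "dfd_significant_spots.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"spot_id": str})
    df["fc_printed"] = df["fc_printed"].astype(float)  # "+inf"/"-inf" -> inf
    return df.set_index("spot_id")
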