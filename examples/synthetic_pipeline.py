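"""Full pipeline on a synthetic dual-stain experiment with known truth.

Generates the paper_like scenario (two groups x 4 replicates, 320 spots,
46/41 phospho-positive with 28 shared), applies the 2-of-4 reproducibility
filter, runs the per-spot bootstrap analysis and reports how well the known
true changes were recovered.
"""

from phosphogel import (analyze_spot_set, generate_spot_table,
                        fisher_exact_two_tailed, phospho_percentage,
                        reproducibility_filter, scenario_preset,
                        spot_group_counts)

cfg = scenario_preset("paper_like", seed=42)
treated, control, truth = generate_spot_table(cfg)
treated = reproducibility_filter(treated)
control = reproducibility_filter(control)

counts = spot_group_counts(treated, control)
pct_t = phospho_percentage(counts.n_phospho_treated, counts.n_reproducible_treated)
pct_c = phospho_percentage(counts.n_phospho_control, counts.n_reproducible_control)
p = fisher_exact_two_tailed(
    counts.n_phospho_treated,
    counts.n_reproducible_treated - counts.n_phospho_treated,
    counts.n_phospho_control,
    counts.n_reproducible_control - counts.n_phospho_control)
print(f"reproducible spots: {counts.n_reproducible_treated} treated, "
      f"{counts.n_reproducible_control} control")
print(f"phospho-positive:   {counts.n_phospho_treated} ({pct_t}%) vs "
      f"{counts.n_phospho_control} ({pct_c}%), Fisher two-tailed P = {p:.2f}")
print(f"shared {counts.n_shared_phospho}, unique {counts.n_unique_treated} "
      f"and {counts.n_unique_control}")

summaries, records = analyze_spot_set(treated, control, alpha=0.05,
                                      n_boot=20_000, seed=42)
called = {r.spot_id for r in records if r.significant == "yes"}
frac = truth.per_group.pivot(index="spot_id", columns="group",
                             values="phospho_fraction")
diff = (frac["DFD"] - frac["control"]).abs()
true_change = set(frac.index[diff >= cfg.sig_threshold])
null_shared = set(frac.index[(diff == 0) & (frac["DFD"] > 0)])
tp = len(called & true_change)
fp_null = len(called & null_shared)
fp_sub = len(called - true_change - null_shared)
print(f"\nanalyzed {len(records)} phospho spots; {len(called)} called "
      f"significant (Bonferroni m = {len(records)}, n_boot = 20000)")
print(f"true changes (|delta fraction| >= {cfg.sig_threshold}): "
      f"{len(true_change)}; recovered {tp}")
print(f"false positives: {fp_null} of {len(null_shared)} shared null spots "
      "(the ~3% per-spot floor of range-limited N=4 bootstrap intervals), "
      f"plus {fp_sub} sub-threshold group-unique spot(s) with real but "
      "small signal")
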