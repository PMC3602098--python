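"""Contrast misclassification with and without near-index detection bias.

An index event such as a cancer diagnosis triggers a diagnostic workup that
surfaces previously undocumented conditions (claim intensity multiplied by
beta inside the bias window).  The biased cohort therefore accumulates more
false positive incident cases at every shortened lookback than a sham-date
cohort of the same size."""

from claims_lookback import ConditionCodebook, SimulationConfig, run_grid, simulate

codebook = ConditionCodebook.builtin()
N = 10_000

grids = {}
for style, seed in (("indexed", 31), ("sham", 32)):
    ds, _ = simulate(SimulationConfig(n_patients=N, cohort_style=style, seed=seed))
    grids[style] = run_grid(ds, codebook)


def pooled_fpf(grid):
    p = grid.groupby("lookback_months")[
        ["n_false_positive", "n_both", "n_prev_only"]
    ].sum()
    return (p["n_false_positive"] / (p["n_both"] + p["n_prev_only"])).sort_index()


fpf_indexed = pooled_fpf(grids["indexed"])
fpf_sham = pooled_fpf(grids["sham"])
print(f"pooled false positive fraction across the 12 conditions (n={N} per cohort)")
print(f"{'lookback':>9} {'indexed (beta=3)':>17} {'sham (beta=1)':>14}")
for L in fpf_indexed.index:
    print(f"{L:>7}mo {fpf_indexed[L]:>17.4f} {fpf_sham[L]:>14.4f}")
print(
    "\nFPF = false positives / conditions identified in the 36-month gold\n"
    "standard. It vanishes at the gold standard by definition and grows as\n"
    "the lookback shrinks; detection bias (beta=3 workup intensity) makes\n"
    "the indexed cohort uniformly worse, mirroring the cancer vs non-cancer\n"
    "contrast this kind of study design produces."
)
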