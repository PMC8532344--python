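"""The full two-genotype synthetic pipeline in one call.

Runs both experiment arms at reduced sizes (for a quick demonstration) and
prints the group comparisons from the summary: in vivo firing statistics and
SEP components, ex vivo excitability and morphometry. The same pipeline is
available from the shell as `pcsense run --config cfg.yaml --seed 7`.
"""

import tempfile

from pcsense import pipeline

config = pipeline.RunConfig(
    seed=7, out_dir=tempfile.mkdtemp(prefix="pcsense_demo_"),
    n_wt=5, n_ko=5, sep_trials=10,
    n_wt_cells=3, n_ko_cells=3, n_wt_trees=4, n_ko_trees=4,
    n_boot=2000,
)
summary = pipeline.run_pipeline(config)

print(f"report bundle written to {config.out_dir}\n")
for arm in ("in_vivo", "ex_vivo"):
    print(f"[{arm}]")
    for comp in summary[arm]["group_comparisons"]:
        print(f"  {comp['metric']:>22}: MD {comp['md_ko_minus_wt']:+.3g} "
              f"[{comp['ci95_lo']:.3g}, {comp['ci95_hi']:.3g}] "
              f"(WT {comp['mean_wt']:.3g}, KO {comp['mean_ko']:.3g})")
for genotype, comps in summary["in_vivo"]["sep_components"].items():
    lats = ", ".join(f"{c['latency_ms']:.2f} ms" for c in comps)
    print(f"  SEP {genotype}: components at {lats}")
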