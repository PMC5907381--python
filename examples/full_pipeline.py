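"""End-to-end pipeline run on a simulated two-arm experiment.

One call produces all report tables (peaks/PMI, LD-DD totals, free-run
parameters, group profiles) plus group comparisons and a JSON summary.
"""

from damrhythm import RunConfig, run

config = RunConfig(
    simulate={"males_alone": 32, "males_virgin_female": 32},
    seed=99,
    out_dir="scratch/demo_run",  # TSVs + summary.json land here
)
result = run(config)

print(result.peaks.head(4).to_string(index=False))
print()
for treatment, means in result.summary["group_means"].items():
    print(f"{treatment:22s} mean PMI {means['PMI']:+.2f}, mean tau {means['tau']:.2f} h")
pmi = result.summary["comparisons"]["PMI"]
print(
    f"\nPMI comparison: {pmi['test']}, p = {pmi['p_value']:.2e}, "
    f"letters = {pmi['letters']}"
)
# Distinct letters on PMI reproduce the headline contrast: males housed
# with a virgin female shift their main evening activity to the later
# peak, males alone do not.
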