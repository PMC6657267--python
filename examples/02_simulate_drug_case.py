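"""Simulate the two-driver drug case in ordered and unordered dynamics.

Runs the packaged case-2 scenario (drug kills every CTC with exactly two
driver mutations at t = 4) with 30-replicate ensembles and prints the mean
population per compartment before and after the drug.
"""

from metastasim import load_packaged, run_case

scenario = load_packaged("case2")
summary = run_case(scenario, out_dir="scratch/case2_report", replicates=30, seed=7)

print(f"scenario: {summary['scenario']}")
for variant, stats in summary["variants"].items():
    final = stats["final_counts_per_compartment"]
    seed_t = stats["first_bone_seeding_time"]
    print(
        f"  {variant:18s} final breast {final['breast']:6.1f}"
        f"  blood {final['circulatory']:5.1f}  bone {final['bone']:4.1f}"
        f"  first bone seeding: {seed_t}"
    )
print(
    "\nReading: the drug empties the two-driver CTC pool in both modes, but"
    " ordered dynamics retains wrong-order reservoirs (cells missing only"
    " EPCAM) that are immune to a blood-compartment drug and can still seed"
    " the bone; trajectories and a figure are written to scratch/case2_report."
)
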