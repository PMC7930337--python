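"""Regenerate the committed demo genotypes by running the two-stage search.

Stage 1 evolves the isolated unit until F1 > 0.99 (seed 4 of the default
configuration); stage 2 seeds an embodied population from that winner
and evolves F1*F2 for 25 generations (population 32, seed 11). The
products are written to src/wormcpg/data/ as named-slot JSON.

The stage-2 generation budget selects a solution that passes all three
worm-likeness filters (NMJ roles, body curvature, trajectory): letting
this lineage evolve further raises raw fitness but the later elites come
to rely on A-class neuromuscular junctions and fall out of the filtered
ensemble — evolved solutions are not automatically worm-like, which is
why the filters exist. Stage 2 takes roughly an hour of CPU.
"""
from pathlib import Path

from wormcpg.analysis import locomotion_filter_report
from wormcpg.evolution import GAConfig, evolve_stage1, evolve_stage2
from wormcpg.simulation import SimConfig

DATA = Path(__file__).resolve().parents[1] / "src" / "wormcpg" / "data"

stage1 = evolve_stage1(GAConfig(population_size=96, generations=300, seed=4,
                                mutation_prob=0.25, stop_at_threshold=True))
print(f"stage 1: best F1 = {stage1.best_fitness:.4f}")
stage1.best_genotype.to_json(DATA / "demo_oscillator.json")

stage2 = evolve_stage2(
    stage1.best_genotype,
    GAConfig(stage=2, population_size=32, generations=25, seed=11,
             mutation_prob=0.25, stop_at_threshold=True),
    SimConfig(duration=18.0, transient=3.0),
)
print(f"stage 2: best F1*F2 = {stage2.best_fitness:.4f}")
report = locomotion_filter_report(stage2.best_genotype)
print(f"filters: nmj={report.nmj_pass} curvature={report.curvature_pass} "
      f"trajectory={report.trajectory_pass}")
assert report.overall_pass, "stage-2 product must pass the worm-likeness filters"
stage2.best_genotype.to_json(DATA / "demo_locomotor.json")
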