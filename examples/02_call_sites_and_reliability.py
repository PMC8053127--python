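"""Call Nm sites at the 0.8 threshold and measure coverage reliability.

Simulates 20 fully methylated sites on a 2-kb RNA, then subsamples fragments
to a grid of average end counts (AEC).  Precision (TP/Positive) collapses at
low AEC — low coverage manufactures spurious high scores — while the
discovery rate (TP/True) stays flat, reproducing the rule of thumb that AEC
should exceed ~15 for trustworthy calls.
"""

import ribometh as rm

config = rm.SimulationConfig(seed=11, rna_length=2000, n_sites=20,
                             n_fragments_target=120_000)
scene = rm.make_scene(config)
fragments = rm.simulate_fragments(scene.references, scene.truth, config)
rna = scene.references[0]

track = rm.count_ends_arrays(rna.id, rna.length,
                             fragments.starts[rna.id], fragments.ends[rna.id])
calls = rm.call_sites(rm.methscore_track(track))
called = [c for c in calls if c.status == "called"]
truth = {t.position for t in scene.truth}
print(f"{len(called)} sites called at S >= 0.8; "
      f"{sum(c.position in truth for c in called)}/20 are planted sites")

curve = rm.subsample_reliability(
    fragments.starts[rna.id], fragments.ends[rna.id], rna.id, rna.length,
    scene.truth_sites(), aec_grid=[2, 5, 10, 15, 20, 30, 50], n_reps=10, seed=3)
print("\n AEC  discovery  precision")
for aec, d, p in zip(curve.aec_grid, curve.discovery, curve.precision):
    print(f"{aec:4.0f}  {d:9.2f}  {p:9.2f}")
print(f"\nminimal reliable AEC (precision >= 0.9): {rm.min_reliable_aec(curve)}")
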