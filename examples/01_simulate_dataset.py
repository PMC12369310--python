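"""Simulate one animal's optogenetic mapping session and write the bundle.

The generator plants 3 muscle synergies over 6 hindlimb muscles, drives
1-2 interneuron-like units with locus-tuned Poisson firing, and injects a
post-spike kernel into the EMG so the units' muscle fields are recoverable.
"""

from pathlib import Path

from synergy_state import SimConfig, generate_dataset, read_dataset

out = Path("scratch/example_bundle")
cfg = SimConfig(n_loci=8, trials_per_locus=5)
gt = generate_dataset(cfg, seed=42, out_dir=out)

rec, spikes, trials, _ = read_dataset(out)
print(f"bundle written to {out}")
print(f"EMG: {rec.n_muscles} muscles x {rec.n_samples} samples "
      f"@ {rec.fs:.0f} Hz ({rec.duration:.0f} s)")
for st in spikes:
    print(f"unit {st.unit_id}: {st.n_spikes} spikes, "
          f"type {gt.unit_type[st.unit_id]}, "
          f"preferred synergy {gt.preferred_true[st.unit_id] + 1}")
by_cond = {}
for tr in trials:
    by_cond[tr.condition] = by_cond.get(tr.condition, 0) + 1
print(f"trials per condition: {by_cond}")
print("Each unit's field is one planted synergy under SST and is rewired "
      "(merged / replaced / preserved) under SSAT and CoST.")
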