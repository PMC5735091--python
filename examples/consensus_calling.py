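"""Damage-aware consensus calling on simulated ancient-DNA reads.

Simulates short damaged fragments from a random 16 kb mitogenome-sized
sequence, then calls a consensus twice: with the deamination filter
(damage window d=5) and without (d=0), using permissive thresholds so the
effect of single damaged reads is visible.
"""

import numpy as np

import paleomt as pm

genome = "".join(np.random.default_rng(1).choice(list("ACGT"), size=16000))
reference = pm.SequenceRecord("mt", genome)

config = pm.SimulationConfig(
    seed=1,
    coverage=2.0,  # sparse data: the regime where damage filtering matters
    damage=pm.DamageParams(delta=0.3, lam=0.3, floor=0.01),
    sequencing_error=0.0,
)
reads, truth = pm.simulate_reads(reference, config)
print(f"simulated {truth.n_reads} fragments at {truth.realised_coverage:.1f}x; "
      f"{len(truth.damage_edits)} deamination edits")


def false_deamination_calls(result):
    return sum(1 for rec in result.ccf
               if (rec.ref_base == "C" and rec.call == "T")
               or (rec.ref_base == "G" and rec.call == "A"))


for d in (5, 0):
    params = pm.ConsensusParams(c_min=1, f_min=0.51, d=d)
    result = pm.generate_consensus(reads, reference, params=params)
    print(f"d={d}: completeness {100 * result.completeness:.1f}%, "
          f"false deamination-allele calls {false_deamination_calls(result)}")

print("-> removing C>T/G>A observations within 5 bases of the fragment ends")
print("   suppresses most false variant calls caused by post-mortem damage.")
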