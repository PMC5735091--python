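"""Terminal deamination profiling ("smiley plot" numbers).

Simulates reads with a known damage model, measures the positional C→T and
G→A misincorporation frequencies, and refits the exponential decay.
"""

import numpy as np

import paleomt as pm

genome = "".join(np.random.default_rng(2).choice(list("ACGT"), size=16000))
true = pm.DamageParams(delta=0.3, lam=0.3, floor=0.01)
config = pm.SimulationConfig(seed=2, coverage=100.0, damage=true,
                             sequencing_error=0.0)
reads, _ = pm.simulate_reads(genome, config)

profile = pm.compute_damage_profile(reads, genome, window=25)
print("pos  C>T(5')  G>A(3')")
for i in (0, 1, 2, 5, 10, 24):
    print(f"{i:3d}  {profile.ct5[i]:.4f}   {profile.ga3[i]:.4f}")

params, resid = pm.fit_exponential(profile)
print(f"fitted delta={params.delta:.3f} lam={params.lam:.3f} "
      f"floor={params.floor:.4f} (truth 0.300/0.300/0.0100)")
print("-> the terminal excess of C>T decaying into the fragment is the")
print("   classic signature used to authenticate ancient DNA.")
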