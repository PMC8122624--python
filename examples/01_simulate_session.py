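"""Generate one synthetic vigilance-task session and inspect it.

The generator emulates a ~10-channel ECoG recording during a sustained-
attention task: a latent fatigue state drifts upward across trials and
drives a rising incorrect-trial rate, and incorrect-trial delay periods
carry injected low-frequency power, wavelet-entropy and directed-coupling
effects.
"""

import numpy as np

import fatiguemark as fm

cfg = fm.GeneratorConfig(n_trials=120, seed=7)
session, events, truth = fm.generate_session(cfg)

n_incorrect = sum(e.outcome == "incorrect" for e in events)
delays = np.array([e.delay_ms for e in events])

print(f"session: {session.data.shape[0]} channels x {session.n_samples} samples "
      f"({session.duration_s / 60:.1f} min at {session.fs} Hz)")
print(f"trials: {len(events)} ({n_incorrect} incorrect)")
print(f"delay periods: mean {delays.mean():.0f} ms, SD {delays.std():.0f} ms "
      "(protocol: N(2500, 250) truncated at 500)")
print(f"latent fatigue drifted {truth.fatigue[0]:.2f} -> {truth.fatigue[-1]:.2f}; "
      "a higher value means a higher per-trial error probability")
print("injected effects and where a detector should find them:")
for mech, info in truth.effects.items():
    where = info.get("channels") or info.get("pairs")
    print(f"  {mech}: families {info['families']} on {where}")
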