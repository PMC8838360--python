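"""Cheyne-Stokes respiration: cyclic hyperpnea-hypopnea bounded by apneas.

Applies a five-cycle CSR envelope (48 s cycle, 25 % apnea) to a breath train
and shows that the quality-gated pipeline accepts breaths only in the
breathing part of each cycle — never inside an apnea.
"""

import numpy as np

import pulmosense as ps

train, truth = ps.make_breath_train(
    ps.BreathTrainParams(duration_s=240.0, rr_mean_bpm=22.0, seed=11))
csr = ps.CSRParams(cycle_length_s=48.0, apnea_fraction=0.25, n_cycles=5)
modulated, csr_truth = ps.apply_csr_envelope(train, truth, csr)

n_apnea = sum(b.in_apnea for b in csr_truth)
print(f"{len(csr_truth)} truth breaths, {n_apnea} overlap an apnea")

result = ps.process_ip_channel(modulated)
accepted = [b for b in result.breaths
            if b.quality == "good" and 4 <= 60 / b.ibi <= 60]
T, a = csr.cycle_length_s, csr.apnea_fraction * csr.cycle_length_s
in_apnea = [b for b in accepted
            if (b.onset % T) < a / 2 or (b.onset % T) > T - a / 2]
print(f"pipeline accepted {len(accepted)} breaths; "
      f"{len(in_apnea)} with onset inside an apnea")
amps = [result.preprocessed.value_at(b.peak)
        - result.preprocessed.value_at(b.onset) for b in accepted]
print(f"accepted breath amplitudes span {min(amps):.2f} to {max(amps):.2f} ohm "
      f"(waxing-waning envelope)")

# Silent apneic stretches produce no accepted breaths; the amplitude spread
# of the accepted breaths traces the crescendo-decrescendo cycle.
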