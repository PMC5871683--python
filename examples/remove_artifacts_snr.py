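"""Remove a classified blink IC and quantify the SNR change.

The EEG is rebuilt without the blink IC; around each cued blink the
amplitude SNR (20 log10 of artifact peak over preceding 200 ms baseline)
drops sharply, showing the artifact is gone while baseline brain activity
remains.
"""

import warnings

import numpy as np

from icfp import SimulationConfig, make_labeled_corpus, reconstruct_without, snr_change

cfg = SimulationConfig(montage_size=32, fs=256.0, duration_s=50.0, seed=0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    labeled, decomps, truths = make_labeled_corpus(8, cfg, seed=21, artifact_type="eyeblink")

ds = sorted(decomps)[0]
decomp, truth = decomps[ds], truths[ds]
mask = labeled.fingerprints["dataset_id"] == ds
blink_ics = labeled.fingerprints.loc[mask & (labeled.labels == 1), "ic_id"].tolist()

original = reconstruct_without(decomp, [])
cleaned = reconstruct_without(decomp, blink_ics)
frontal = decomp.montage.labels[int(np.argmax(np.abs(decomp.weights[:, blink_ics[0]])))]
report = snr_change(original, cleaned, frontal,
                    truth.event_times["eyeblink"], segment=(0.0, 10.0))

print(f"dataset {ds}: removing blink IC(s) {blink_ics} at channel {frontal}")
print(f"SNR before removal: {report.snr_db_original:6.2f} dB "
      f"({report.n_events} blink events in a 10 s segment)")
print(f"SNR after removal:  {report.snr_db_reconstructed:6.2f} dB")
print(f"change:             {report.snr_db_change:6.2f} dB")
print("-> a large negative change means the blink deflections no longer")
print("   rise above baseline: the artifact was removed, not the EEG.")
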