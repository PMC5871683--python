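"""Decompose a synthetic session into ICs and compute their fingerprints.

Each independent component gets a 14-value fingerprint spanning temporal
(K, MEV), spatial (SAD, SED), spectral (band powers, CIF, MIF) and
statistical (EF) domains plus template correlations (EM-CORR, EB-CORR).
A blink IC should stand out with maximal SAD, K and a delta-dominant
spectrum.
"""

import numpy as np

from icfp import SimulationConfig, bandpass_notch, decompose, fingerprint_dataset, simulate
from icfp.preprocess import fastica_unmixing
from icfp.simulate import match_ics_to_sources
from icfp.preprocess import bandpass_notch_array

cfg = SimulationConfig(montage_size=32, fs=256.0, duration_s=50.0,
                       artifact_types=("eyeblink",), seed=11)
rec, truth = simulate(cfg)
rec = bandpass_notch(rec, hi=100.0, notch=None)
decomp = decompose(rec, n_ics=20, seed=11, ica_fun=fastica_unmixing)

fingerprints = fingerprint_dataset(decomp)
matches = match_ics_to_sources(
    decomp, truth,
    source_transform=lambda x: bandpass_notch_array(x, cfg.fs, hi=100.0, notch=None),
)
blink_ic = next(ic for ic, src in matches.items()
                if truth.source_labels[src] == "eyeblink")

cols = ["ic_id", "K", "MEV", "SAD", "PSD_DELTA", "EB_CORR", "EF"]
print(fingerprints[cols].round(3).to_string(index=False))
row = fingerprints.iloc[blink_ic]
print(f"\nground-truth blink IC: {blink_ic}")
print(f"  SAD={row.SAD:.2f} (dataset max => 1.0), K={row.K:.2f}, "
      f"PSD_DELTA={row.PSD_DELTA:.2f}, EB_CORR={row.EB_CORR:.2f}")
print("-> frontal topography, spiky time course, delta-dominant spectrum and")
print("   high eyeblink-template correlation single this IC out as the blink.")
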