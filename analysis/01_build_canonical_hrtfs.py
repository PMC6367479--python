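#!/usr/bin/env python
"""Build the canonical HRTF set and verify its structural assumptions.

Generates the parametric HRTF bank (59 elevations x 0.5-20 kHz), writes
it to results/hrtf_table.csv and reports the two template priors the
observer model rests on: (i) each elevation's template correlates best
with itself over the 3-12 kHz analysis band, and (ii) the 25 stimulus
spectra correlate only weakly with any template.
"""

from pathlib import Path

import numpy as np

from specloc.hrtf import HRTFParams, make_canonical_hrtfs, uniqueness_report, write_hrtf_table
from specloc.stimulus import make_stimulus_matrix

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    hrtfs = make_canonical_hrtfs(HRTFParams())
    write_hrtf_table(hrtfs, OUT / "hrtf_table.csv")
    print(f"canonical HRTF set: {hrtfs.elevations.n} elevations x "
          f"{hrtfs.grid.n} frequency bins, gains in "
          f"[{hrtfs.gains.min():.1f}, {hrtfs.gains.max():.1f}] dB")

    res_band = hrtfs.gains[:, hrtfs.grid.band_mask(2.25, 2.75)]
    print(f"ear-canal resonance direction independence: max gain variance "
          f"across elevations in 2.25-2.75 kHz = {res_band.var(axis=0).max():.2e} dB^2")

    m = hrtfs.grid.band_mask(5.0, 11.0)
    f = hrtfs.grid.values[m]
    notch_freq = f[np.argmin(hrtfs.gains[:, m], axis=1)]
    print(f"primary notch sweeps {notch_freq[0]:.2f} -> {notch_freq[-1]:.2f} kHz "
          f"from -60 to +85 deg; monotone: "
          f"{bool(np.all(np.diff(notch_freq) >= -1e-9))}")

    rep = uniqueness_report(hrtfs, list(make_stimulus_matrix(hrtfs.grid)))
    print(f"template uniqueness margin (min self-corr minus best cross-corr): "
          f"{rep.min_diagonal_margin:.2e} (> 0 required)")
    print(f"max |stimulus-template correlation|: {rep.max_source_correlation:.3f} "
          f"(flat spectra correlate 0; high-contrast blocks deliberately "
          f"mimic template structure)")
    print(f"wrote {OUT / 'hrtf_table.csv'}")


if __name__ == "__main__":
    main()
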