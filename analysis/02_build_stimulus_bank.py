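#!/usr/bin/env python
"""Construct the 25 spectral-contrast stimuli and export their spectra.

Each stimulus sets the 6-9 kHz notch band to one level (NRI) and the
outer bands (0.5-6, 9-20 kHz) to another (ORI), both from
{29, 38, 47, 56, 65} dB SPL, with 120 dB/octave band edges.  The main
diagonal of the 5x5 matrix is flat noise at five overall levels; the
corners reach +/-36 dB of spectral contrast.
"""

from pathlib import Path

from specloc.stimulus import (
    STIMULUS_LEVELS_DB,
    export_stimulus_matrix,
    make_stimulus_matrix,
    spectral_contrast,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    matrix = make_stimulus_matrix()
    export_stimulus_matrix(matrix, OUT / "stimuli.csv")
    print(f"{len(matrix)} stimuli over levels {STIMULUS_LEVELS_DB} dB")
    print("contrast matrix (NRI rows x ORI columns, dB):")
    header = "        " + "  ".join(f"{o:5.0f}" for o in STIMULUS_LEVELS_DB)
    print(header)
    for nri in STIMULUS_LEVELS_DB:
        row = "  ".join(
            f"{spectral_contrast(matrix[(nri, ori)]):+5.0f}"
            for ori in STIMULUS_LEVELS_DB
        )
        print(f"  {nri:5.0f} {row}")
    contrasts = [spectral_contrast(s) for s in matrix]
    print(f"max |contrast| = {max(abs(c) for c in contrasts):.0f} dB; "
          f"{sum(c == 0 for c in contrasts)} flat spectra on the diagonal")
    print(f"wrote {OUT / 'stimuli.csv'}")


if __name__ == "__main__":
    main()
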