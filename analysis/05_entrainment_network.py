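"""Post hoc: how do the three entrainment measures relate to each other?

Pairwise partial correlations between head distance, hand distance and F0
mismatch, each controlling for the third variable, on complete-case real
pairs.  In the generator all three articulators share the same per-pair
coupling amplitude, so the kinematic measures should correlate positively
with each other while the prosodic measure stays near zero.

Writes results/entrainment_network.csv.
"""

from pathlib import Path

import pandas as pd

from qrentrain import inference, io_formats, pipeline

ROOT = Path(__file__).resolve().parents[1]
RECORDS = ROOT / "results" / "records.csv"
OUT = ROOT / "results" / "entrainment_network.csv"


def main() -> None:
    df = pipeline.attach_group(io_formats.read_records(RECORDS))
    real = df[df.condition == "real"]
    net = inference.partial_correlations(real)

    table = pd.DataFrame(net.partial_r, index=net.variables,
                         columns=net.variables)
    table.to_csv(OUT)
    print(f"wrote {OUT} (n = {net.n_obs} complete cases)")
    names = net.variables
    for a in range(3):
        for b in range(a + 1, 3):
            c = 3 - a - b
            print(f"  r({names[a]}, {names[b]} | {names[c]}) = "
                  f"{net.partial_r[a, b]:+.3f}")


if __name__ == "__main__":
    main()
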