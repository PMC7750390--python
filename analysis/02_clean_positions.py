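#!/usr/bin/env python
"""Clean the raw positions: region filter, stuck runs, smoothing, stationary days.

Reads results/data/positions_raw.csv, writes the cleaned table and the
per-stage removal accounting under results/.
"""

from pathlib import Path

from herdnet import io
from herdnet.geometry import BarnGeometry
from herdnet.preprocess import clean_pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    raw = io.read_positions(RESULTS / "data" / "positions_raw.csv")
    res = clean_pipeline(raw, BarnGeometry())
    io.write_positions(res.cleaned, RESULTS / "data" / "positions_clean.csv")
    with open(RESULTS / "cleaning_log.csv", "w") as fh:
        fh.write("stage,removed_count,removed_fraction\n")
        for stage, frac in res.stage_removed_fraction.items():
            count = res.stage_removed_count[stage]
            fh.write(f"{stage},{count},{frac:.6f}\n")
            print(f"{stage}: removed {count} records ({100 * frac:.2f}% of original)")
    print(
        f"total removed: {100 * res.total_removed_fraction:.2f}% "
        f"({res.original_count - len(res.cleaned)} of {res.original_count})"
    )


if __name__ == "__main__":
    main()
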