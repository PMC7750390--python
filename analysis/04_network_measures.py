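#!/usr/bin/env python
"""Basic network measures per day and zone: density, components, degree, clustering.

Also writes the mean-weight filtered matrices used for visualisation.
"""

from pathlib import Path

import pandas as pd

from herdnet import io
from herdnet.geometry import ZONES
from herdnet.netmetrics import (
    degree_and_clustering,
    filter_by_mean_degree,
    network_measures,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_DAYS = 3


def main() -> None:
    rows = []
    node_rows = []
    for day in range(N_DAYS):
        for zone in ZONES:
            m = io.read_matrix(RESULTS / "matrices" / f"day{day:02d}_{zone}.csv")
            meas = network_measures(m)
            rows.append({"day_index": day, "zone": zone, **meas})
            node = degree_and_clustering(m)
            node.insert(0, "zone", zone)
            node.insert(0, "day_index", day)
            node_rows.append(node)
            io.write_matrix(
                filter_by_mean_degree(m),
                RESULTS / "matrices" / f"day{day:02d}_{zone}_filtered.csv",
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "network_measures.csv", index=False, float_format="%.4f")
    pd.concat(node_rows, ignore_index=True).to_csv(
        RESULTS / "node_measures.csv", index=False, float_format="%.4f"
    )
    print(summary.to_string(index=False))
    by_zone = summary.groupby("zone")["edge_density"].mean()
    print("\nmean edge density by zone:")
    print(by_zone.to_string())


if __name__ == "__main__":
    main()
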