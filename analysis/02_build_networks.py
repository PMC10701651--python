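"""Build both per-class network representations and report descriptives.

Reads the cohort written by 01_generate_cohort.py, constructs the
message-based (web) and nomination-based directed weighted networks, and
writes edge lists plus per-class densities and mean weights to
results/networks/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from peerdiffusion import build_nomination_network, build_web_network, density
from peerdiffusion.network_builder import write_edge_lists
from peerdiffusion.synthetic_data import SyntheticDataset

OUT = Path("results/networks")


def main() -> None:
    dataset = SyntheticDataset.read("results/cohort")
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for source, builder, events in [
        ("web", build_web_network, dataset.messages),
        ("nomination", build_nomination_network, dataset.nominations),
    ]:
        nets = builder(events, dataset.roster)
        write_edge_lists(nets, OUT / f"edges_{source}.csv")
        for c, net in sorted(nets.items()):
            weights = [d["weight"] for *_e, d in net.graph.edges(data=True)]
            rows.append({
                "source": source, "class_id": c,
                "n_nodes": net.graph.number_of_nodes(),
                "n_edges": net.graph.number_of_edges(),
                "density": density(net),
                "mean_weight": float(np.mean(weights)) if weights else np.nan,
            })
    desc = pd.DataFrame(rows)
    desc.to_csv(OUT / "descriptives.csv", index=False)
    for source, grp in desc.groupby("source"):
        print(f"{source}: density {grp['density'].mean():.3f} (SD {grp['density'].std():.3f}), "
              f"mean weight {grp['mean_weight'].mean():.3f}, "
              f"{int(grp['n_edges'].sum())} edges")
    print(f"edge lists and descriptives in {OUT}/")


if __name__ == "__main__":
    main()
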