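"""Compare the two network representations and their influencer choices.

Per class: edge-set Jaccard similarity between the web and nomination
networks. Per strategy (in-degree, betweenness, closeness): the top-15%
influential peers selected in each representation and their overlap.
Writes results/comparison/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from peerdiffusion import (
    build_nomination_network,
    build_web_network,
    jaccard_similarity,
    select_cohort,
    selection_overlap,
)
from peerdiffusion.network_builder import pal_table
from peerdiffusion.sna_metrics import STRATEGIES, centrality_table
from peerdiffusion.synthetic_data import SyntheticDataset

SEED = 1
OUT = Path("results/comparison")


def main() -> None:
    dataset = SyntheticDataset.read("results/cohort")
    OUT.mkdir(parents=True, exist_ok=True)
    web = build_web_network(dataset.messages, dataset.roster)
    nom = build_nomination_network(dataset.nominations, dataset.roster)
    w5 = pal_table(dataset.steps, dataset.roster, [5])

    jac = pd.DataFrame({
        "class_id": sorted(web),
        "jaccard": [jaccard_similarity(web[c], nom[c]) for c in sorted(web)],
    })
    jac.to_csv(OUT / "jaccard.csv", index=False)
    print(f"network similarity (Jaccard): {jac['jaccard'].mean():.2f} "
          f"(SD {jac['jaccard'].std():.2f})")

    cent = pd.concat(
        [centrality_table(net).assign(source=src, class_id=c)
         for src, nets in (("web", web), ("nomination", nom))
         for c, net in sorted(nets.items())],
        ignore_index=True,
    )
    cent.to_csv(OUT / "centralities.csv", index=False)

    rows, sel_rows = [], []
    for strat in STRATEGIES:
        sel_web = select_cohort(web, w5, strat, rng=np.random.default_rng(SEED + 1))
        sel_nom = select_cohort(nom, w5, strat, rng=np.random.default_rng(SEED + 1))
        count, frac = selection_overlap(sel_web, sel_nom)
        total = sum(s.k for s in sel_web.values())
        rows.append({"strategy": strat, "n_selected": total,
                     "n_shared": count, "fraction_shared": frac})
        for src, sel in (("web", sel_web), ("nomination", sel_nom)):
            sel_rows += [
                {"source": src, "strategy": strat, "class_id": c, "participant_id": v}
                for c, s in sel.items() for v in s.selected
            ]
        print(f"{strat}: {count}/{total} influential peers shared ({100 * frac:.0f}%)")
    pd.DataFrame(rows).to_csv(OUT / "selection_overlap.csv", index=False)
    pd.DataFrame(sel_rows).to_csv(OUT / "selections.csv", index=False)
    print(f"comparison tables in {OUT}/")


if __name__ == "__main__":
    main()
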