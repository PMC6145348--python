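"""Build the 14-process lake reaction network and verify every reaction
balances exactly.

The two chemolithotrophic denitrification pathways are re-derived from
element/charge conservation alone (smallest positive integers) and
compared against the shipped network.  Writes results/network_report.tsv.
"""

from pathlib import Path

import pandas as pd

from lakeredox.reaction_network import (
    balance_minimal,
    check_balance,
    default_network,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main():
    net = default_network()
    rows = []
    for rxn in net.reactions:
        resid = check_balance(rxn, net.species)
        rows.append(
            {
                "id": rxn.id,
                "process": rxn.process_label,
                "stoichiometry": " + ".join(
                    f"{-c} {s}" for s, c in rxn.stoich.items() if c < 0
                )
                + " -> "
                + " + ".join(f"{c} {s}" for s, c in rxn.stoich.items() if c > 0),
                "k": rxn.rate_law.k,
                "balanced": all(v == 0 for v in resid.values()),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "network_report.tsv", sep="\t", index=False)
    print(f"{df['balanced'].sum()}/{len(df)} reactions balance exactly")

    reac, prod = balance_minimal(
        ["HS-", "NO3-", "H+"], ["SO42-", "N2", "H2O"], net.species
    )
    print(f"sulfide-driven denitrification, minimal integers: {reac} -> {prod}")
    reac, prod = balance_minimal(
        ["CH4", "NO3-", "H+"], ["CO2", "N2", "H2O"], net.species
    )
    print(f"methane-driven denitrification, minimal integers: {reac} -> {prod}")


if __name__ == "__main__":
    main()
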