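#!/usr/bin/env python
"""Emulate the random-mutagenesis screen's sequence-analysis step.

A toy wild-type ORF (112 codons, the five classic mutant sites pinned) is
mutagenized in silico: some clones carry one of the known single point
mutations, the rest are decoys (double mutants, nonsense mutants, wild-type
isolates, SHP-tail hits).  Paired forward/reverse reads are generated,
aligned back to the wild type, and the candidate filters applied: exactly
one strand-verified point mutation, no premature stop, outside the excluded
SHP-tail region.
"""

import argparse
from pathlib import Path

import pandas as pd

from derlintools.screen import evaluate_read_pair
from derlintools.synthetic import (
    design_orf,
    generate_screen_read_pair,
    write_read_pairs_fasta,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "screen"

FIXED_CODONS = {5: "TAC", 58: "TTT", 64: "CTG", 67: "AAA", 101: "CAA", 107: "TTC"}
KNOWN_MUTANTS = {
    "F58S": (172, "C"),
    "L64V": (189, "G"),
    "K67E": (198, "G"),
    "Q101R": (301, "G"),
    "F107S": (319, "C"),
}
EXCLUDED_SHP_TAIL = (330, 336)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--error-rate", type=float, default=0.0)
    args = parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    orf = design_orf(112, FIXED_CODONS)
    (OUT / "wild_type_orf.fasta").write_text(f">wt_orf\n{orf}\n")

    batch = {}
    for i, (label, (pos, alt)) in enumerate(KNOWN_MUTANTS.items()):
        batch[f"clone_{label}"] = generate_screen_read_pair(
            orf, [(pos, alt)], args.error_rate, seed=args.seed + i
        )
    batch["clone_double"] = generate_screen_read_pair(
        orf, [KNOWN_MUTANTS["F58S"], KNOWN_MUTANTS["Q101R"]],
        args.error_rate, seed=args.seed + 10,
    )
    stop_idx = next(
        i for i in range(3, 300, 3) if orf[i : i + 3] == "TAC"
    )
    batch["clone_nonsense"] = generate_screen_read_pair(
        orf, [(stop_idx + 2, "A")], args.error_rate, seed=args.seed + 11
    )
    batch["clone_wildtype"] = generate_screen_read_pair(
        orf, [], args.error_rate, seed=args.seed + 12
    )
    tail_alt = "C" if orf[331] != "C" else "G"
    batch["clone_shp_tail"] = generate_screen_read_pair(
        orf, [(331, tail_alt)], args.error_rate, seed=args.seed + 13
    )
    write_read_pairs_fasta(batch, OUT / "reads.fasta")

    rows = []
    for clone, pair in batch.items():
        verdict = evaluate_read_pair(pair, orf, excluded_region=EXCLUDED_SHP_TAIL)
        rows.append(
            {
                "clone": clone,
                "status": verdict.status,
                "reasons": ";".join(verdict.reasons),
                "aa_change": verdict.calls[0].aa_change
                if len(verdict.calls) == 1 else "",
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "screen_verdicts.csv", index=False)
    accepted = table[table.status == "accepted"]
    print(table.to_string(index=False))
    print(
        f"\n{len(accepted)}/{len(table)} clones accepted: "
        f"{', '.join(accepted.aa_change)}"
    )
    print(f"wrote FASTA inputs and verdicts under {OUT}")


if __name__ == "__main__":
    main()
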