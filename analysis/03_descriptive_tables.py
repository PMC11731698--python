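#!/usr/bin/env python
"""Descriptive summaries of the simulated community.

Reproduces the shape of the community's published descriptive tables on the
synthetic corpus: yearly activity, the persona distribution, and per-theme
dataset sizes of the exposure-model subset, with half-up one-decimal
percentage shares.  Written to results/tables/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from affilex import read_corpus, read_personas, summarize_corpus

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    corpus = read_corpus(ROOT / "data" / "corpus.csv")
    personas = read_personas(ROOT / "data" / "personas.csv")
    tables = summarize_corpus(corpus, personas)
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"summary_{name}.csv", index=False)
        print(f"--- {name} ---")
        print(df.to_string(index=False))
        print()
    print(f"wrote summary tables to {out}")


if __name__ == "__main__":
    main()
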