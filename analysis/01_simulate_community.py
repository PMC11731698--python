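#!/usr/bin/env python
"""Generate the synthetic ADA-like community used by the downstream analyses.

Writes a 529-user corpus (~57k messages, 2014-2021, multi-label themes and
speech acts) plus the users' templated signature strings under
results/data/.  Every later stage starts from these files, so the whole
analysis is reproducible from one seed.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import csv

from affilex import ada_like_config, generate_corpus, write_corpus, write_personas

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    syn = generate_corpus(ada_like_config(seed=SEED))
    write_corpus(syn.messages, OUT / "corpus.csv")
    write_personas(syn.personas, OUT / "personas_truth.csv")
    with (OUT / "signatures.csv").open("w", newline="") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_ALL)
        w.writerow(["user_id", "signature"])
        for p in syn.personas:
            w.writerow([p.user_id, p.signature_text or ""])
    syn.message_counts.rename_axis("user_id").to_csv(OUT / "engagement_truth.csv")

    years = sorted({m.year for m in syn.messages})
    print(f"simulated {len(syn.messages)} messages by {len(syn.personas)} users")
    print(f"window {years[0]}-{years[-1]}, "
          f"{len({m.topic_id for m in syn.messages})} topics")
    print(f"wrote corpus, signatures, personas to {OUT}")


if __name__ == "__main__":
    main()
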