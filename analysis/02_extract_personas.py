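#!/usr/bin/env python
"""Extract behavior personas from the simulated signatures and audit them.

Applies the rule-based lexicon extraction to results/data/signatures.csv and
compares against the generator's sampled truth — on clean templated
signatures the round trip should be essentially exact.
"""

import csv
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from affilex import extract_persona, read_personas, write_personas

DATA = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    with (DATA / "signatures.csv").open(newline="") as fh:
        personas = [
            extract_persona(row["signature"], row["user_id"])
            for row in csv.DictReader(fh)
        ]
    write_personas(personas, DATA / "personas.csv")

    truth = {p.user_id: p for p in read_personas(DATA / "personas_truth.csv")}
    agree = sum(
        (p.medication_status, p.diagnosis_status, p.lifestyle_status)
        == (t.medication_status, t.diagnosis_status, t.lifestyle_status)
        for p in personas
        for t in [truth[p.user_id]]
    )
    print(f"extracted {len(personas)} personas; "
          f"{agree}/{len(personas)} match the generator truth "
          f"({100 * agree / len(personas):.1f}%)")


if __name__ == "__main__":
    main()
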