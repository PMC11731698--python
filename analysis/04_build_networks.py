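#!/usr/bin/env python
"""Build the 12 theme-by-style affiliation networks and export them.

For each communication theme and communication style (push-in vs interactive
turn-taking) this builds the user-by-speech-act count matrix over the
signature users, binarizes at the median positive count, forms the
coaffiliation matrix, computes affiliation exposure, and exports an
attributed bipartite GEXF graph (persona coloring, engagement tiers) under
results/networks/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from affilex import (
    Theme,
    affiliation_exposure,
    binarize,
    build_count_matrix,
    coaffiliation,
    compute_engagement,
    export_network,
    read_corpus,
    read_personas,
    write_network,
)
from affilex.synth import STYLE_SUBSETS

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    corpus = read_corpus(ROOT / "data" / "corpus.csv")
    personas = read_personas(ROOT / "data" / "personas.csv")
    users = [p.user_id for p in personas]
    engagement = compute_engagement(corpus, users=users)
    out = ROOT / "networks"
    out.mkdir(parents=True, exist_ok=True)

    for theme in Theme:
        for style, subset in STYLE_SUBSETS.items():
            aff = build_count_matrix(corpus, theme, sa_subset=subset, users=users)
            binarize(aff)
            coaff = coaffiliation(aff)
            exposure = affiliation_exposure(coaff, engagement.reindex(aff.users))
            stem = f"{theme.value}_{style}"
            exposure.rename_axis("user_id").to_csv(out / f"{stem}_exposure.csv")
            G = export_network(aff, personas, engagement.reindex(aff.users))
            write_network(G, out / f"{stem}.gexf")
            print(
                f"{stem}: n={aff.n}, threshold={aff.threshold:g}, "
                f"isolates={int(coaff.isolates().sum())}, "
                f"mean exposure={exposure.mean():.1f}"
            )
    print(f"wrote exposure vectors and GEXF exports to {out}")


if __name__ == "__main__":
    main()
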