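#!/usr/bin/env python
"""Build the similarity maps comparing developmental stages.

Applies an ordinary PCA to the stacked per-image score distributions
of each component and reports how the stage centroids arrange along
the first axis.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, make_config, make_parser

from grainfluor.pipeline import load_manifest, stage_similarity


def main() -> None:
    args = make_parser(__doc__).parse_args()
    cfg = make_config(args)
    manifest = load_manifest(cfg)
    table = stage_similarity(cfg, manifest)
    table.to_csv(RESULTS / "similarity_map.csv", index=False)
    for comp, sub in table.groupby("component"):
        cent = sub.groupby("stage")["axis1"].mean()
        ordering = " > ".join(str(s) for s in
                              cent.sort_values(ascending=False).index)
        print(f"component {comp + 1}: axis-1 stage ordering {ordering} "
              f"(axis 1 explains {sub['explained1_pct'].iloc[0]:.1f}%)")


if __name__ == "__main__":
    main()
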