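#!/usr/bin/env python
"""Fit the series-wide streaming PCA and render score images.

Accumulates pixel counts, pseudo-spectrum sums and cross-product
matrices over the whole-section ROI of every cube, finalizes the
global eigendecomposition, and renders the leading score images on the
series-common 8-bit scale.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, make_config, make_parser

from grainfluor.pipeline import load_manifest, stage_pca


def main() -> None:
    args = make_parser(__doc__).parse_args()
    cfg = make_config(args)
    manifest = load_manifest(cfg)
    model = stage_pca(cfg, manifest)
    table = pd.DataFrame({
        "component": range(1, model.n_components + 1),
        "eigenvalue": model.eigenvalues,
        "explained_pct": model.explained,
    })
    table.to_csv(RESULTS / "explained_variance.csv", index=False)
    print(f"fitted on {model.n_pixels:,} ROI pixels of "
          f"{model.n_images} images")
    print("leading components (% variance):",
          ", ".join(f"{v:.2f}" for v in model.explained[:5]),
          f"| top-5 cumulative {model.explained[:5].sum():.2f}%")


if __name__ == "__main__":
    main()
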