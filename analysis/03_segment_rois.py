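#!/usr/bin/env python
"""Segment the two ROIs and measure section areas.

Whole-section masks come from the fixed threshold on the 8-bit
sum-of-intensity image plus square-element opening/closing; the
outer-tissue masks merge two Otsu thresholds and disk-element cleanup.
Writes the per-section area table and prints per-stage mean ± sd.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS, make_config, make_parser

from grainfluor.pipeline import load_manifest, stage_segment


def main() -> None:
    args = make_parser(__doc__).parse_args()
    cfg = make_config(args)
    manifest = load_manifest(cfg)
    areas = stage_segment(cfg, manifest)
    areas.to_csv(RESULTS / "section_areas.csv", index=False)
    print("section areas (mm^2) per stage:")
    for stage, sub in areas.groupby("stage"):
        print(f"  {stage} °DAF: {sub.area_mm2.mean():.2f} "
              f"± {sub.area_mm2.std():.2f}  (n={len(sub)})")


if __name__ == "__main__":
    main()
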