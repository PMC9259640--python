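"""Call linkage regions from the score tracks.

Applies the region rule - at least 3 consecutive markers passing the
threshold, with interior gaps allowed only while every in-between marker
stays above the suggestive level - at both the genome-wide significant
threshold (LOD 3.3, NPL 3.90) and the suggestive threshold (LOD 1.0,
NPL 2.15).  Suggestive regions feed the variant-selection step.  Writes
per-track region TSV/BED under results/regions/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pedlink.npl import (
    call_regions,
    lod_to_npl,
    read_track_tsv,
    regions_to_bed,
    regions_to_tsv,
)

LINK = Path(__file__).resolve().parents[1] / "results" / "linkage"
OUT = Path(__file__).resolve().parents[1] / "results" / "regions"
OUT.mkdir(parents=True, exist_ok=True)

LOD_HIGH, LOD_GAP = 3.3, 1.0
print(f"thresholds: significant LOD>={LOD_HIGH} (NPL>={lod_to_npl(LOD_HIGH):.2f}), "
      f"suggestive LOD>={LOD_GAP} (NPL>={lod_to_npl(LOD_GAP):.2f})")

n_sig = n_sug = 0
for track_path in sorted(LINK.glob("*_NPL_*.tsv")) + sorted(LINK.glob("*_LOD_*.tsv")):
    tr = read_track_tsv(track_path)
    if tr.kind.startswith("NPL"):
        high, gap = lod_to_npl(LOD_HIGH), lod_to_npl(LOD_GAP)
    else:
        high, gap = LOD_HIGH, LOD_GAP
    sig = call_regions(tr, high, gap)
    sug = call_regions(tr, gap, gap)
    n_sig += len(sig)
    n_sug += len(sug)
    stem = track_path.stem
    regions_to_tsv(sig, OUT / f"{stem}.significant.tsv")
    regions_to_tsv(sug, OUT / f"{stem}.suggestive.tsv")
    regions_to_bed(sug, OUT / f"{stem}.suggestive.bed")
    if sig or sug:
        print(f"{stem}: {len(sig)} significant, {len(sug)} suggestive regions")

print(f"\ntotal: {n_sig} significant and {n_sug} suggestive regions "
      f"across all families and statistics")
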