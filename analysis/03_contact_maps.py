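#!/usr/bin/env python
"""Contact-frequency maps per condition and the holo - apo difference map.

Contacts are heavy-atom pairs within 0.45 nm between residues of
different segments, counted over all pooled frames of a condition; maps
for rendering keep only pairs above 5% occupancy, while the difference
map uses raw frequencies.  Also writes per-residue contact profiles for
the two programmed interfaces (MBD5 vs A domain, MBD2 vs MBD3) and the
Cβ–Cβ 0.8 nm reference map of the starting structure.
"""

from pathlib import Path

import pandas as pd

from domaindyn import contacts
from domaindyn.domains import DomainMap
from domaindyn.ensembles import load_manifest, read_structure

BASE = Path(__file__).resolve().parents[1]
DATA = BASE / "scratch" / "data"
RESULTS = BASE / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    dmap = DomainMap.from_yaml(DATA / "domain_map.yaml")
    sets = load_manifest(DATA / "manifest.yaml")

    maps = {}
    for cond, rset in sets.items():
        cmap = contacts.contact_frequency(rset, dmap)
        maps[cond] = cmap
        contacts.threshold_map(cmap).to_csv(RESULTS / f"contacts_{cond}.csv")
        print(f"{cond}: {len(cmap.pairs(0.05))} inter-segment pairs above 5% "
              f"over {cmap.n_frames} frames")

    diff = contacts.difference_map(maps["holo"], maps["apo"])
    diff.pairs().to_csv(RESULTS / "contacts_difference.csv", index=False)
    top = diff.pairs().reindex(
        diff.pairs()["difference"].abs().sort_values(ascending=False).index).head(5)
    print("\nlargest holo - apo frequency changes:")
    for _, r in top.iterrows():
        print(f"  {dmap.segment_of(int(r.res_i))} {int(r.res_i)} – "
              f"{dmap.segment_of(int(r.res_j))} {int(r.res_j)}: {r.difference:+.2f}")

    for sa, sb in [("MBD5", "A domain"), ("MBD2", "MBD3")]:
        prof = contacts.residue_profile(diff, dmap, sa, sb)
        pd.concat(prof, axis=0).rename("difference").to_csv(
            RESULTS / f"profile_{sa.replace(' ', '')}_{sb.replace(' ', '')}.csv")

    start = read_structure(DATA / "structure.pdb")
    ref = contacts.cb_reference_map(start, dmap)
    ref.to_csv(RESULTS / "reference_cb_map.csv")
    print(f"\nstarting-structure Cβ map: {len(ref.pairs(0.5))} pairs within 0.8 nm")


if __name__ == "__main__":
    main()
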