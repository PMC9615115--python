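#!/usr/bin/env python
"""Generate the study's fixture systems and write them to disk.

Produces: a right-handed 12-water chiral helix, its mirror image, an
achiral planar ring, a strand-mimic template system over 60 waters, and
a small non-thermalized water slab.  All are pure functions of the
seeds below, so this script is reproducible byte for byte.
"""

from pathlib import Path

from chiralsfg import synthetic as syn
from chiralsfg.io import write_system

OUT = Path("results/fixtures")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    topo, frame = syn.build_chiral_water_helix(12, handedness=1)
    write_system(topo, [frame], OUT / "helix_right")
    _, mirror = syn.build_chiral_water_helix(12, handedness=-1)
    write_system(topo, [mirror], OUT / "helix_left")
    topo0, ring = syn.build_chiral_water_helix(12, handedness=0)
    write_system(topo0, [ring], OUT / "ring_achiral")

    strand = syn.TemplateStrand(n_residues=7)
    ttopo, tframes = syn.build_template_system(strand, n_waters=60, seed=SEED,
                                               n_frames=5)
    write_system(ttopo, tframes, OUT / "template")
    print(f"template: {strand.n_residues} residues, net charge "
          f"{strand.net_charge:+.1f} e, 60 waters, {len(tframes)} frames")

    stopo, sframes = syn.build_slab_fixture(120, thermalize=False, seed=SEED)
    write_system(stopo, sframes, OUT / "slab_static")
    print(f"wrote fixtures to {OUT}/")


if __name__ == "__main__":
    main()
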