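"""The 4-step family-based filtering approach (FBA) on a traceable fixture.

Steps: (1) keep rare variants (founder MAF < 0.01); (2) select three
distant relatives over age 31 with low SBP (the subset minimizing maximum
pairwise kinship); (3) keep variants carried by all three; (4) keep
variants with phastCons-44 conservation >= 220.  On the fixture -- five
rare variants, two shared by the selected cousin trio, one of those
conserved -- the counts telescope 5 -> 5 -> 2 -> 1.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "tests"))
from studyfactories import fba_fixture_bundle

from ngla.filters import fba_filter

bundle = fba_fixture_bundle()
rep = fba_filter(bundle, "F")

print("selected distant carriers:", rep.selected_individuals,
      "(first cousins: pairwise kinship 1/16)")
for s in rep.steps:
    print(f"  step {s.name:<18} {s.n_in:>2} -> {s.n_out:<2} "
          f"(removed: {', '.join(s.removed) if s.removed else '-'})")
print("final prioritized list:", rep.kept,
      "-- the one shared variant in a conserved element")
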