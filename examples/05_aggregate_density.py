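"""Aggregate several analyzed cells into bead histograms and density maps.

Beads pooled per row are binned over ~200-nm height segments and four
azimuth sectors (I = facing north, counted counterclockwise from the top);
the above-tip bin is folded into the top segment and counts are normalized
by segment surface area and cilia count, giving beads per um^2 per cilium —
the quantity that makes rows of different heights comparable.
"""

import tempfile
from pathlib import Path

import stereogold as sg

parent = Path(tempfile.mkdtemp()) / "All_Cells"
for k, seed in enumerate((7, 8), start=1):
    cell = parent / f"Cell{k}"
    sg.write_cell_folder(sg.BundleSpec(rng_seed=seed), cell)
    sg.analyze_cell(cell, sg.AnalysisConfig(resize_factor=1.0, rng_seed=seed),
                    make_figures=False)
    print(f"analyzed Cell{k}")

agg = sg.aggregate_results(parent)
print(f"\naggregated 2 cells -> {parent / 'Aggregated'}")
for row, a in sorted(agg.items()):
    n_seg = a.folded.counts.shape[0]
    print(f"\nrow {row}: {a.template.n_towers} cilia pooled, "
          f"avg height {a.template.avg_height:.2f} um -> {n_seg} segments "
          f"of {a.density.segment_height * 1000:.0f} nm")
    print(f"  folded counts per (segment x sector), total {a.folded.total}:")
    for s in range(n_seg - 1, -1, -1):
        print(f"    seg {s + 1:2d}: {a.folded.counts[s].tolist()}")
    print(f"  peak density {a.density.density.max():.2f} beads/um^2/cilium")
print()
print("With the validation pattern, each stereocilia row concentrates all "
      "its beads in a single cell: tall row at the tip in sector III, "
      "middle row mid-shaft in sector I, short row at the base in sector I.")
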