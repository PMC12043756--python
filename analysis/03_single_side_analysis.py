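"""Analyse the canonical right side in detail.

Extracts the foraminal aperture, scans the cheek entry line (1 mm grid,
bisected boundaries), simulates Härtel's trigeminal axis, and prints the
entry recommendation with and without the soft-tissue correction.  Writes the
per-height table to results/canonical_heights.csv.
"""

import json
from pathlib import Path

from transoval.phantom import canonical_config, generate_phantom
from transoval.trajectory import (
    TrajectoryContext,
    build_aperture,
    hartel_axis,
    recommend_entry,
    scan_entry_line,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scene = generate_phantom(canonical_config())
    aperture = build_aperture(scene)
    ctx = TrajectoryContext(scene, aperture)
    print(f"aperture: area {aperture.area:.1f} mm^2, "
          f"semi-axes {aperture.ellipse_axes[0]:.2f} (ML) x "
          f"{aperture.ellipse_axes[1]:.2f} (AP) mm")

    span = scan_entry_line(scene, aperture, context=ctx)
    print(f"extreme span: {span.lower_extreme:+.1f} .. {span.upper_extreme:+.1f} mm "
          f"(width {span.extreme_width:.1f} mm)")
    print(f"easy span:    {span.lower_easy:+.1f} .. {span.upper_easy:+.1f} mm "
          f"(width {span.easy_width:.1f} mm)")

    hx = hartel_axis(scene, aperture, context=ctx)
    print(f"Härtel Einstichpunkt: {hx.einstich_height:+.1f} mm relative to the "
          f"horizontal plane")
    for dz in (1.0, 2.0):
        hx2 = hartel_axis(scene, aperture, context=ctx,
                          origin_offset=dz * scene.horizontal_plane.normal)
        print(f"  axis origin raised {dz:.0f} mm -> exit at "
              f"{hx2.einstich_height:+.1f} mm")

    for offset in (0.0, 5.0):
        rec = recommend_entry(span, soft_tissue_offset=offset)
        print(f"recommended entry (soft-tissue offset {offset:.0f} mm): "
              f"{rec.height:+.1f} mm")

    (ROOT / "results").mkdir(exist_ok=True)
    span.table.to_csv(ROOT / "results" / "canonical_heights.csv", index=False)
    summary = {
        "aperture_area_mm2": aperture.area,
        "lower_extreme_mm": span.lower_extreme,
        "upper_extreme_mm": span.upper_extreme,
        "lower_easy_mm": span.lower_easy,
        "upper_easy_mm": span.upper_easy,
        "einstich_height_mm": hx.einstich_height,
    }
    (ROOT / "results" / "canonical_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
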