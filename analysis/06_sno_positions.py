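"""Binding-event positions along snoRNA copies relative to the boxes.

Computes each event's relative center on its snoRNA copy, the
per-group position histograms, and the fraction of centers in ASE2 /
C / C' / D-D' regions — group-III centers should concentrate in ASE2
(the guide element upstream of the D' box) while SNORD115 centers
spread uniformly.
"""

from pathlib import Path

import snordtarget as st
from snordtarget import io as sio

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "tables"


def main() -> None:
    events = sio.read_tsv(OUT / "events.tsv")
    locus = st.build_locus_fixture()
    profile = st.relative_centers(events, locus)
    sio.write_tsv(profile.events, OUT / "event_positions.tsv")
    sio.write_tsv(profile.box_track, OUT / "box_track.tsv")
    for group in ("I", "II", "III"):
        sio.write_tsv(profile.histogram(group=group),
                      OUT / f"position_hist_group{group}.tsv")

    for label, sel in [("group I", profile.events["group"] == "I"),
                       ("group II", profile.events["group"] == "II"),
                       ("group III", profile.events["group"] == "III"),
                       ("SNORD115", profile.events["family"] == "SNORD115")]:
        sub = profile.events[sel]
        if sub.empty:
            continue
        frac = st.region_fractions(
            st.PositionProfile(events=sub, box_track=profile.box_track), locus)
        print(f"{label}: ase2 {frac['ase2']:.2f}, C {frac['C']:.2f}, "
              f"C' {frac['Cp']:.2f}, D/D' {frac['DDp']:.2f}, "
              f"other {frac['other']:.2f}  (n={len(sub)})")


if __name__ == "__main__":
    main()
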