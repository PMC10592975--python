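"""Consolidate sliding-window predictions into binding events.

Applies the >= 3 consecutive windows at score >= 0.98 filter, writes
the merged events (TSV + BED6) and the per-copy / per-group event
counts across the SNORD116 groups and the SNORD115 control family.
"""

from pathlib import Path

import snordtarget as st
from snordtarget import io as sio

BASE = Path(__file__).resolve().parents[1] / "results"
DATA, OUT = BASE / "data", BASE / "tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    windows = sio.read_windows(DATA / "windows.tsv")
    locus = st.build_locus_fixture()
    events = st.merge_consecutive(windows, t=0.98, w=3)
    print(f"{len(windows)} windows -> {len(events)} merged binding events")
    sio.write_tsv(events, OUT / "events.tsv")
    sio.write_bed6(events, OUT / "events.bed")

    per_copy, per_group = st.events_per_copy(events, locus)
    sio.write_tsv(per_copy, OUT / "events_per_copy.tsv")
    sio.write_tsv(per_group, OUT / "events_per_group.tsv")
    print(per_group.to_string(index=False))


if __name__ == "__main__":
    main()
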