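"""Where on the snoRNA do predicted interactions fall?

C/D box snoRNAs pair with their targets through antisense elements
immediately 5' of the D and D' boxes, so the distribution of
binding-event centers along the snoRNA body is diagnostic: guide-like
binding concentrates upstream of D/D' (ASE1/ASE2), while spurious
prediction tends to pile onto the conserved C/C' boxes themselves.
Event centers are expressed relative to copy length (0 = 5' end,
1 = 3' end) so copies of different lengths are comparable, and the
box track is scaled the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .locus import LocusModel

HISTOGRAM_BIN_WIDTH = 0.01


@dataclass
class PositionProfile:
    """Per-event relative centers plus the scaled box track per copy."""

    events: pd.DataFrame  # sno_id, family, group, center, rel_center
    box_track: pd.DataFrame  # copy_id, region, rel_start, rel_end

    def histogram(self, group: str | None = None,
                  family: str | None = None) -> pd.DataFrame:
        """Fixed-width histogram of relative centers (bin width 0.01)."""
        ev = self.events
        if group is not None:
            ev = ev[ev["group"] == group]
        if family is not None:
            ev = ev[ev["family"] == family]
        import numpy as np

        edges = np.arange(0, 1 + HISTOGRAM_BIN_WIDTH, HISTOGRAM_BIN_WIDTH)
        counts, _ = np.histogram(ev["rel_center"], bins=edges)
        return pd.DataFrame(
            dict(bin_start=edges[:-1].round(2), bin_end=edges[1:].round(2),
                 count=counts)
        )


def event_center(sno_start: int, sno_end: int) -> int:
    """Center of a span; even lengths take the left-of-middle base."""
    return (int(sno_start) + int(sno_end) - 1) // 2


def relative_centers(events: pd.DataFrame, locus: LocusModel) -> PositionProfile:
    """Relative binding-event centers and the scaled box/ASE2 track.

    The center of each event's snoRNA span (left-of-middle for even
    spans) is divided by the copy length. Events whose snoRNA span
    exceeds the copy length are rejected.
    """
    rows = []
    for _, ev in events.iterrows():
        copy = locus.get_copy(ev["sno_id"])
        s, e = int(ev["sno_start"]), int(ev["sno_end"])
        if s < 0 or e > copy.length:
            raise ValueError(
                f"event snoRNA span [{s}, {e}) exceeds {copy.copy_id} "
                f"length {copy.length}"
            )
        center = event_center(s, e)
        rows.append(
            dict(sno_id=copy.copy_id, family=copy.family, group=copy.group,
                 center=center, rel_center=center / copy.length)
        )
    track = []
    for copy in locus.copies:
        regions = {**copy.boxes, "ase2": copy.ase2}
        for name, iv in regions.items():
            track.append(
                dict(copy_id=copy.copy_id, region=name,
                     rel_start=iv.start / copy.length,
                     rel_end=iv.end / copy.length)
            )
    return PositionProfile(
        events=pd.DataFrame(
            rows, columns=["sno_id", "family", "group", "center", "rel_center"]
        ),
        box_track=pd.DataFrame(track),
    )


REGION_ORDER = ("ase2", "C", "Cp", "DDp", "other")


def region_fractions(profile: PositionProfile, locus: LocusModel) -> pd.Series:
    """Fraction of event centers in ASE2, C box, C' box, D/D' boxes, other.

    Uses copy-coordinate centers against each copy's own box intervals;
    fractions sum to 1 exactly. Empty profiles are an error (silent
    zeros would read as a uniform-null result).
    """
    if profile.events.empty:
        raise ValueError("empty position profile")
    counts = dict.fromkeys(REGION_ORDER, 0)
    for _, ev in profile.events.iterrows():
        copy = locus.get_copy(ev["sno_id"])
        c = ev["center"]
        if copy.ase2.contains(c):
            counts["ase2"] += 1
        elif copy.boxes["C"].contains(c):
            counts["C"] += 1
        elif copy.boxes["Cp"].contains(c):
            counts["Cp"] += 1
        elif copy.boxes["D"].contains(c) or copy.boxes["Dp"].contains(c):
            counts["DDp"] += 1
        else:
            counts["other"] += 1
    n = len(profile.events)
    return pd.Series({k: counts[k] / n for k in REGION_ORDER}, name="fraction")


# ---------------------------------------------------------------------------
# Box motif scanning (for user-supplied copies without curated boxes)
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "N": "ACGT",
}

C_BOX = "RTGATGA"  # RUGAUGA
D_BOX = "CTGA"  # CUGA


def _matches(seq: str, pos: int, motif: str, max_mismatch: int = 0) -> bool:
    if pos + len(motif) > len(seq):
        return False
    mm = 0
    for i, m in enumerate(motif):
        if seq[pos + i] not in _IUPAC[m]:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def _find_all(seq: str, motif: str, max_mismatch: int = 0) -> list[int]:
    return [p for p in range(len(seq) - len(motif) + 1)
            if _matches(seq, p, motif, max_mismatch)]


def scan_boxes(sequence: str) -> dict[str, list[tuple[int, int]]]:
    """Candidate C/D'/C'/D box intervals in one snoRNA sequence.

    Accepts RNA or DNA. C candidates match RUGAUGA near the 5' end;
    D candidates match CUGA near the 3' end; D' is an internal CUGA and
    C' an internal RUGAUGA with up to one mismatch. Candidates are
    ranked by positional plausibility (C earliest, D latest, D' before
    C'). An empty list for a box is a valid result, not a failure.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    c_hits = [p for p in _find_all(seq, C_BOX) if p < max(n // 3, 12)]
    c_hits.sort()
    d_hits = [p for p in _find_all(seq, D_BOX) if p >= n - max(n // 4, 12)]
    d_hits.sort(reverse=True)
    c_end = c_hits[0] + len(C_BOX) if c_hits else max(n // 6, 8)
    d_start = d_hits[0] if d_hits else n - 8
    internal_d = [p for p in _find_all(seq, D_BOX) if c_end <= p < d_start]
    mid = n / 2
    internal_d.sort(key=lambda p: abs(p - mid))
    dp = internal_d[0] if internal_d else None
    cp_lo = (dp + len(D_BOX)) if dp is not None else c_end
    internal_c = [
        p for p in _find_all(seq, C_BOX, max_mismatch=1) if cp_lo <= p < d_start
    ]
    internal_c.sort(key=lambda p: abs(p - (cp_lo + d_start) / 2))
    return {
        "C": [(p, p + len(C_BOX)) for p in c_hits],
        "Dp": [(p, p + len(D_BOX)) for p in internal_d],
        "Cp": [(p, p + len(C_BOX)) for p in internal_c],
        "D": [(p, p + len(D_BOX)) for p in d_hits],
    }
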