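"""Model of the imprinted chr15q11-q13 snoRNA cluster locus.

The Prader-Willi region carries two tandem arrays of orphan C/D box
snoRNAs inside the SNHG14 host transcript: 30 copies of SNORD116
(conventionally split into groups I, II and III) and 48 copies of
SNORD115, flanked by the imprinted protein-coding genes MKRN3, MAGEL2,
NDN and SNURF-SNRPN and by the noncoding IPW and UBE3A. Two engineered
deletions are modelled: ``smDEL`` removes the SNORD116 array alone and
``lgDEL`` additionally removes SNURF and the SNRPN promoter region.

Coordinates are synthetic (a pseudo-chromosome ``chrPWS_sim``), laid out
with the genes in their real relative order; they are NOT hg38
positions. All intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHROM = "chrPWS_sim"

N_SNORD116 = 30
N_SNORD115 = 48

#: group boundaries of the SNORD116 array (copy numbers, inclusive)
SNORD116_GROUPS = {"I": (1, 9), "II": (10, 24), "III": (25, 30)}

#: default width (nt) of the second antisense element, immediately 5' of D'
ASE2_WIDTH = 15

_FIXTURE_SEED = 20_150_411  # fixed internal seed; the fixture takes no RNG


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: float) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class SnoCopy:
    """One snoRNA copy with its box architecture.

    ``boxes`` maps box names C, Dp (D'), Cp (C') and D to intervals in
    copy coordinates (0-based half-open); ``ase2`` is the second
    antisense element, abutting the 5' side of the D' box.
    """

    copy_id: str
    family: str  # SNORD116 | SNORD115
    group: str  # I | II | III | NA
    length: int
    boxes: dict[str, Interval]
    ase2: Interval
    sequence: str
    genomic_start: int = 0

    def __post_init__(self) -> None:
        order = [self.boxes[k].start for k in ("C", "Dp", "Cp", "D")]
        if order != sorted(order):
            raise ValueError(f"{self.copy_id}: boxes out of C < D' < C' < D order")
        for a, b in zip(("C", "Dp", "Cp"), ("Dp", "Cp", "D")):
            if self.boxes[a].end > self.boxes[b].start:
                raise ValueError(f"{self.copy_id}: overlapping {a}/{b} boxes")
        if self.ase2.end != self.boxes["Dp"].start:
            raise ValueError(f"{self.copy_id}: ase2 must abut the D' box")
        for name, iv in {**self.boxes, "ase2": self.ase2}.items():
            if iv.start < 0 or iv.end > self.length:
                raise ValueError(f"{self.copy_id}: {name} outside [0, {self.length})")
        if len(self.sequence) != self.length:
            raise ValueError(f"{self.copy_id}: sequence length mismatch")

    @property
    def copy_number(self) -> int:
        return int(self.copy_id.rsplit("-", 1)[1])


@dataclass(frozen=True)
class FlankingGene:
    gene_id: str
    start: int
    end: int
    protein_coding: bool


@dataclass(frozen=True)
class LocusModel:
    copies: tuple[SnoCopy, ...]
    flanking_genes: tuple[FlankingGene, ...]
    deletion_intervals: dict[str, Interval] = field(default_factory=dict)
    chrom: str = CHROM

    def family(self, family: str) -> list[SnoCopy]:
        return [c for c in self.copies if c.family == family]

    def group(self, group: str) -> list[SnoCopy]:
        return [c for c in self.copies if c.family == "SNORD116" and c.group == group]

    def get_copy(self, copy_id: str) -> SnoCopy:
        for c in self.copies:
            if c.copy_id == copy_id:
                return c
        raise KeyError(f"unknown snoRNA copy: {copy_id}")

    @property
    def copy_ids(self) -> list[str]:
        return [c.copy_id for c in self.copies]


def group_of_copy(copy_number: int) -> str:
    """Map a SNORD116 copy number (1-30) to its group I/II/III."""
    for g, (lo, hi) in SNORD116_GROUPS.items():
        if lo <= copy_number <= hi:
            return g
    raise ValueError(f"SNORD116 copy number out of range: {copy_number}")


def _plant(seq: list[str], motif: str, start: int) -> None:
    seq[start : start + len(motif)] = list(motif)


def _scrub_spurious_motifs(seq: list[str], protected: list[Interval]) -> None:
    """Mutate accidental CTGA / TGATGA occurrences outside planted boxes.

    Keeps the motif scanner's top-ranked hits on the curated boxes without
    biasing base composition much (a single substitution per hit).
    """
    s = "".join(seq)
    for motif in ("CTGA", "TGATGA"):
        pos = s.find(motif)
        while pos != -1:
            span = Interval(pos, pos + len(motif))
            if not any(span.overlaps(p) for p in protected):
                seq[pos + 1] = "C" if seq[pos + 1] != "C" else "A"
                s = "".join(seq)
            pos = s.find(motif, pos + 1)


def _make_copy(
    copy_id: str,
    family: str,
    group: str,
    length: int,
    rng: np.random.Generator,
    genomic_start: int,
    ase2_width: int = ASE2_WIDTH,
) -> SnoCopy:
    # canonical C/D architecture: C box near the 5' end, D box near the 3'
    # end, internal D' and C' boxes; ASE2 immediately upstream of D'.
    c = Interval(4, 11)  # RUGAUGA
    dp_start = length // 2 - 2
    dp = Interval(dp_start, dp_start + 4)  # CUGA
    cp_start = dp.end + 12
    cp = Interval(cp_start, cp_start + 7)
    d = Interval(length - 8, length - 4)  # CUGA
    ase2 = Interval(dp.start - ase2_width, dp.start)

    seq = list(rng.choice(list("ACGT"), size=length))
    _plant(seq, "GTGATGA", c.start)  # C box, R=G
    _plant(seq, "CTGA", dp.start)  # D' box
    _plant(seq, "GTGAGGA", cp.start)  # degenerate C' box (one mismatch)
    _plant(seq, "CTGA", d.start)
    _scrub_spurious_motifs(seq, [c, dp, cp, d])
    return SnoCopy(
        copy_id=copy_id,
        family=family,
        group=group,
        length=length,
        boxes={"C": c, "Dp": dp, "Cp": cp, "D": d},
        ase2=ase2,
        sequence="".join(seq),
        genomic_start=genomic_start,
    )


def build_locus_fixture(ase2_width: int = ASE2_WIDTH) -> LocusModel:
    """Deterministic synthetic model of the PWS snoRNA locus.

    Returns the same :class:`LocusModel` on every call: 30 SNORD116
    copies (groups I: 1-9, II: 10-24, III: 25-30), 48 SNORD115 copies,
    the flanking genes in locus order, and the smDEL / lgDEL deletion
    intervals.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)

    flank: list[FlankingGene] = []
    pos = 10_000
    for gid, width, coding in [
        ("MKRN3", 3_000, True),
        ("MAGEL2", 4_000, True),
        ("NDN", 2_000, True),
    ]:
        flank.append(FlankingGene(gid, pos, pos + width, coding))
        pos += width + 5_000

    snrpn_promoter = Interval(pos, pos + 1_500)
    pos += 1_500
    flank.append(FlankingGene("SNURF", pos, pos + 1_200, True))
    pos += 1_200
    flank.append(FlankingGene("SNRPN", pos, pos + 6_000, True))
    pos += 6_000 + 4_000

    sno116_start = pos
    copies: list[SnoCopy] = []
    for i in range(1, N_SNORD116 + 1):
        length = 94 + int(rng.integers(0, 7))
        copies.append(
            _make_copy(
                f"SNORD116-{i}", "SNORD116", group_of_copy(i), length, rng, pos,
                ase2_width,
            )
        )
        pos += length + 600
    sno116_end = pos - 600 + 0

    pos += 2_000
    flank.append(FlankingGene("IPW", pos, pos + 2_500, False))
    pos += 2_500 + 3_000

    for i in range(1, N_SNORD115 + 1):
        length = 80 + int(rng.integers(0, 7))
        copies.append(
            _make_copy(f"SNORD115-{i}", "SNORD115", "NA", length, rng, pos, ase2_width)
        )
        pos += length + 500

    pos += 3_000
    flank.append(FlankingGene("UBE3A", pos, pos + 8_000, True))

    deletions = {
        # smDEL removes the SNORD116 array only (margins stay clear of
        # SNRPN and IPW)
        "smDEL": Interval(sno116_start - 500, sno116_end + 500),
        # lgDEL extends from the SNRPN promoter region through SNORD116
        "lgDEL": Interval(snrpn_promoter.start, sno116_end + 500),
    }
    return LocusModel(
        copies=tuple(copies),
        flanking_genes=tuple(flank),
        deletion_intervals=deletions,
    )
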