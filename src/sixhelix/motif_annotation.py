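"""Sequence-level annotation of retroviral TM ectodomain features.

The segmentation is anchored on the CX6CC motif (Cys-x6-Cys-Cys), whose first
two cysteines form an intramotif disulfide and whose third links the TM to the
SU subunit in the full-length envelope protein:

- CR (chain reversal) region: from 6 residues before the first motif cysteine
  through the third cysteine.
- ISD (immunosuppressive domain): the 17-mer ending immediately before the
  first motif cysteine.
- tether: the 6 residues after the CR; HR2 runs from there to the construct
  end; HR1 is everything before the CR.

All positions are author (envelope-precursor) numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

REGION_NAMES = ("HR1", "CR", "tether", "HR2", "ISD", "CX6CC")
ISD_LENGTH = 17
TETHER_LENGTH = 6
CR_LEAD = 6  # CR starts this many residues before the first CX6CC cysteine


@dataclass(frozen=True)
class RegionAnnotation:
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(f"unknown region {self.name!r}")
        if self.start > self.end:
            raise ValueError("start must be <= end")

    def __contains__(self, number: int) -> bool:
        return self.start <= number <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


def _check_sequence(seq: str) -> None:
    if not seq or not seq.isupper() or not seq.isalpha():
        raise ValueError("sequence must be a nonempty uppercase amino-acid string")


def find_cx6cc(seq: str, start_number: int = 1) -> list[tuple[int, int]]:
    """All C-x(6)-C-C matches as (first Cys, third Cys) author-number pairs.

    ``start_number`` is the author number of the first sequence position.
    Overlapping matches are all reported.
    """
    _check_sequence(seq)
    hits = []
    for i in range(len(seq) - 8):
        if seq[i] == "C" and seq[i + 7] == "C" and seq[i + 8] == "C":
            hits.append((start_number + i, start_number + i + 8))
    return hits


def find_furin_sites(seq: str, start_number: int = 1) -> list[int]:
    """Polybasic furin-like sites R-x-[KR]-R; returns the author position of
    the final arginine (cleavage occurs after it). Overlaps all reported."""
    _check_sequence(seq)
    out = []
    for i in range(len(seq) - 3):
        if seq[i] == "R" and seq[i + 2] in "KR" and seq[i + 3] == "R":
            out.append(start_number + i + 3)
    return out


def annotate_regions(
    seq: str,
    cx6cc_hit: tuple[int, int] | None = None,
    start_number: int = 1,
    stutter_span: tuple[int, int] | None = None,
) -> list[RegionAnnotation]:
    """Segment a TM ectodomain construct into HR1 / CR / tether / HR2 (a tiling
    of the construct) plus the overlay regions ISD and CX6CC.

    Requires exactly one CX6CC motif (pass ``cx6cc_hit`` to override the scan).
    ``stutter_span`` is accepted for provenance but does not move boundaries.
    """
    _check_sequence(seq)
    if cx6cc_hit is None:
        hits = find_cx6cc(seq, start_number)
        if len(hits) != 1:
            raise ValueError(f"expected exactly one CX6CC motif, found {len(hits)}")
        cx6cc_hit = hits[0]
    first_cys, third_cys = cx6cc_hit
    if third_cys - first_cys != 8:
        raise ValueError("CX6CC hit must span 9 residues (C-x6-C-C)")
    construct_start = start_number
    construct_end = start_number + len(seq) - 1

    cr = RegionAnnotation("CR", first_cys - CR_LEAD, third_cys)
    tether = RegionAnnotation("tether", cr.end + 1, cr.end + TETHER_LENGTH)
    hr2 = RegionAnnotation("HR2", tether.end + 1, construct_end)
    hr1 = RegionAnnotation("HR1", construct_start, cr.start - 1)
    isd = RegionAnnotation("ISD", first_cys - ISD_LENGTH, first_cys - 1)
    cx = RegionAnnotation("CX6CC", first_cys, third_cys)
    if hr2.start > construct_end:
        raise ValueError("construct ends before HR2")
    for region in (cr, tether, isd):
        if region.start < construct_start or region.end > construct_end:
            raise ValueError(f"{region.name} extends outside the construct")
    return [hr1, cr, tether, hr2, isd, cx]


def tiling_regions(regions: list[RegionAnnotation]) -> list[RegionAnnotation]:
    """The subset {HR1, CR, tether, HR2} that tiles the construct."""
    order = {"HR1": 0, "CR": 1, "tether": 2, "HR2": 3}
    return sorted((r for r in regions if r.name in order), key=lambda r: order[r.name])


def to_bed(regions: list[RegionAnnotation], construct_start: int,
           name: str = "construct") -> str:
    """BED (0-based half-open, construct-local) text for the annotations, with
    the author-number conversion documented in the header."""
    lines = [
        f"# author residue number = start + {construct_start} (BED is 0-based half-open)"
    ]
    for r in regions:
        lines.append(
            f"{name}\t{r.start - construct_start}\t{r.end - construct_start + 1}\t{r.name}"
        )
    return "\n".join(lines) + "\n"
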