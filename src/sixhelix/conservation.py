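"""Per-site conservation from a multiple sequence alignment, mapped onto
structure residues and averaged over annotated regions.

The per-column score is a gap-aware Jensen-Shannon divergence between the
column's amino-acid composition and a background distribution, normalized by
the largest divergence a single-residue column can reach against that
background. An invariant column scores exactly 1; a column matching the
background scores 0. Scores are binned into nine grades mimicking the familiar
1-9 conservation scale, with grade 9 reserved for invariant columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = {"-", ".", "*"}


@dataclass
class Msa:
    ids: list[str]
    rows: list[str]
    reference: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError("ragged alignment")
        if self.reference not in self.ids:
            raise ValueError(f"reference {self.reference!r} not in alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference)]


def read_alignment(path: str | Path, fmt: str | None = None,
                   reference: str | None = None) -> Msa:
    """Read a FASTA or Clustal alignment (format inferred from content unless
    given); the reference defaults to the first row."""
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()
        fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    if len(aln) < 3:
        raise ValueError("alignment must have at least 3 rows")
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    return Msa(ids=ids, rows=rows, reference=reference or ids[0])


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, base 2."""
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def _background(background: np.ndarray | None) -> np.ndarray:
    if background is None:
        return np.full(len(AA20), 1.0 / len(AA20))
    bg = np.asarray(background, dtype=float)
    if bg.shape != (len(AA20),) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a length-20 probability vector")
    return bg


def column_score(column: str, background: np.ndarray | None = None,
                 max_gap_fraction: float = 0.5) -> float | None:
    """Normalized JSD conservation score in [0, 1] for one alignment column.

    Returns None (unscored) when more than ``max_gap_fraction`` of the column
    is gaps or unknown residues.
    """
    bg = _background(background)
    counts = np.zeros(len(AA20))
    n_valid = 0
    for ch in column.upper():
        k = AA20.find(ch)
        if k >= 0:
            counts[k] += 1
            n_valid += 1
    if n_valid == 0 or (len(column) - n_valid) / len(column) > max_gap_fraction:
        return None
    p = counts / n_valid
    jsd_max = max(_jsd(np.eye(len(AA20))[r], bg) for r in range(len(AA20)))
    return float(np.clip(_jsd(p, bg) / jsd_max, 0.0, 1.0))


def score_msa(msa: Msa, background: np.ndarray | None = None,
              max_gap_fraction: float = 0.5) -> list[float | None]:
    bg = _background(background)
    # the normalizer only depends on the background; hoist it
    jsd_max = max(_jsd(np.eye(len(AA20))[r], bg) for r in range(len(AA20)))
    out: list[float | None] = []
    for j in range(msa.width):
        col = msa.column(j)
        counts = np.zeros(len(AA20))
        n_valid = 0
        for ch in col:
            k = AA20.find(ch)
            if k >= 0:
                counts[k] += 1
                n_valid += 1
        if n_valid == 0 or (len(col) - n_valid) / len(col) > max_gap_fraction:
            out.append(None)
        else:
            out.append(float(np.clip(_jsd(counts / n_valid, bg) / jsd_max, 0, 1)))
    return out


def grade_scores(scores: list[float | None]) -> list[int | None]:
    """1-9 grades: 9 iff the column is invariant (score == 1); other scored
    columns are binned 1-8 by empirical quantile."""
    scored = [(i, s) for i, s in enumerate(scores) if s is not None]
    grades: list[int | None] = [None] * len(scores)
    variable = [(i, s) for i, s in scored if s < 1.0 - 1e-9]
    if variable:
        vals = np.array([s for _, s in variable])
        order = vals.argsort(kind="stable").argsort(kind="stable")
        q = order / len(vals)
        for (i, _), qi in zip(variable, q):
            grades[i] = 1 + min(7, int(qi * 8))
    for i, s in scored:
        if s >= 1.0 - 1e-9:
            grades[i] = 9
    return grades


@dataclass
class ConservationTrack:
    """Scores/grades keyed by the reference structure's author residue numbers."""

    scores: dict[int, float]
    grades: dict[int, int]


def map_to_structure(
    msa: Msa,
    residue_numbers: list[int],
    background: np.ndarray | None = None,
) -> ConservationTrack:
    """Map column scores onto structure residues: the k-th non-gap reference
    position corresponds to the k-th construct residue number."""
    ref = msa.reference_row()
    nongap_cols = [j for j, ch in enumerate(ref) if ch not in GAP_CHARS]
    if len(nongap_cols) != len(residue_numbers):
        raise ValueError(
            f"reference has {len(nongap_cols)} residues but the construct has "
            f"{len(residue_numbers)}"
        )
    scores = score_msa(msa, background)
    grades = grade_scores(scores)
    track_scores, track_grades = {}, {}
    for num, j in zip(residue_numbers, nongap_cols):
        if scores[j] is not None:
            track_scores[num] = scores[j]
            track_grades[num] = grades[j]
    return ConservationTrack(scores=track_scores, grades=track_grades)


def region_average(track: ConservationTrack, regions) -> pd.DataFrame:
    """Mean conservation grade of the scored residues in each annotated region."""
    rows = []
    for region in regions:
        vals = [g for num, g in track.grades.items() if num in region]
        if not vals:
            raise ValueError(f"region {region.name} has no graded residues")
        rows.append({"region": region.name, "mean_grade": float(np.mean(vals)),
                     "n_residues": len(vals)})
    return pd.DataFrame(rows)
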